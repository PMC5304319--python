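import numpy as np
import pytest
from scipy import stats

from minmaxfit import (
    FitnessVector,
    GrownNetwork,
    GrowthConfig,
    LognormalSpec,
    ValidationError,
    attachment_probabilities,
    degree_distribution,
    empirical_attachment_frequencies,
    grow_network,
)


def expected_edge_count(cfg: GrowthConfig) -> int:
    return cfg.m0 * (cfg.m0 - 1) // 2 + (cfg.n_final - cfg.m0) * cfg.m_edges


def grow_uniform_oracle(n_final, m_edges, m0, seed):
    """Independent uniform-attachment growth, oracle for degenerate kernels."""
    rng = np.random.default_rng(seed)
    degree = np.zeros(n_final, dtype=int)
    degree[:m0] = m0 - 1
    for new in range(m0, n_final):
        targets = rng.choice(new, size=m_edges, replace=False)
        degree[targets] += 1
        degree[new] += m_edges
    return degree


class TestAttachmentProbabilities:
    def test_degree_kernel(self):
        p = attachment_probabilities("degree", np.array([1, 3]), None)
        np.testing.assert_allclose(p.weights, [0.25, 0.75])

    def test_degree_fitness_kernel(self):
        p = attachment_probabilities(
            "degree_fitness", np.array([2, 2]), np.array([1.0, 3.0])
        )
        np.testing.assert_allclose(p.weights, [0.25, 0.75])

    def test_fitness_kernel(self):
        p = attachment_probabilities("fitness", None, np.array([1.0, 2.0, 3.0, 4.0]))
        np.testing.assert_allclose(p.weights, [0.1, 0.2, 0.3, 0.4])

    def test_candidate_subset(self):
        p = attachment_probabilities(
            "fitness", None, np.array([1.0, 2.0, 3.0, 4.0]), candidate_set=[1, 3]
        )
        np.testing.assert_allclose(p.weights, [1 / 3, 2 / 3])

    def test_all_zero_weights_rejected(self):
        with pytest.raises(ValidationError):
            attachment_probabilities("degree", np.array([0, 0]), None)

    def test_unknown_kernel(self):
        with pytest.raises(ValidationError):
            attachment_probabilities("uniform", None, None)


class TestGrowNetwork:
    def test_edge_count_formula(self):
        cfg = GrowthConfig(
            kernel="fitness", n_final=10, m_edges=2, m0=3,
            fitness_spec=LognormalSpec(0.0, 1.0, 10, 0), seed=0,
        )
        net = grow_network(cfg)
        assert net.n_edges == 17 == expected_edge_count(cfg)

    @pytest.mark.parametrize("kernel", ["degree", "degree_fitness", "fitness"])
    @pytest.mark.parametrize("m_edges,m0", [(1, 2), (2, 3), (3, 5)])
    def test_edge_count_all_kernels(self, kernel, m_edges, m0):
        spec = None if kernel == "degree" else LognormalSpec(0.0, 1.0, 1, 0)
        cfg = GrowthConfig(
            kernel=kernel, n_final=60, m_edges=m_edges, m0=m0,
            fitness_spec=spec, seed=2,
        )
        net = grow_network(cfg)
        assert net.n_edges == expected_edge_count(cfg)
        assert int(net.degree.sum()) == 2 * net.n_edges

    def test_reproducible(self):
        cfg = GrowthConfig(
            kernel="fitness", n_final=100, m_edges=2, m0=3,
            fitness_spec=LognormalSpec(0.0, 1.0, 1, 0), seed=9,
        )
        a, b = grow_network(cfg), grow_network(cfg)
        np.testing.assert_array_equal(a.edges, b.edges)
        np.testing.assert_array_equal(a.fitness, b.fitness)

    def test_seed_changes_network(self):
        mk = lambda s: grow_network(
            GrowthConfig(
                kernel="fitness", n_final=100, m_edges=2, m0=3,
                fitness_spec=LognormalSpec(0.0, 1.0, 1, 0), seed=s,
            )
        )
        assert not np.array_equal(mk(1).edges, mk(2).edges)

    def test_constant_fitness_degree_fitness_reduces_to_degree(self):
        # identical RNG schedule: same draws, identical edge lists
        const = FitnessVector.from_values(np.ones(200))
        base = dict(n_final=200, m_edges=2, m0=3, seed=4)
        net_df = grow_network(
            GrowthConfig(kernel="degree_fitness", fitness_spec=const, **base)
        )
        net_d = grow_network(GrowthConfig(kernel="degree", **base))
        np.testing.assert_array_equal(net_df.edges, net_d.edges)

    def test_constant_fitness_kernel_is_uniform_attachment(self):
        # degree distribution statistically indistinguishable from a
        # uniform-attachment run at matched parameters
        n = 2000
        const = FitnessVector.from_values(np.ones(n))
        net = grow_network(
            GrowthConfig(
                kernel="fitness", n_final=n, m_edges=2, m0=3,
                fitness_spec=const, seed=11,
            )
        )
        oracle = grow_uniform_oracle(n, 2, 3, seed=12)
        assert stats.ks_2samp(net.degree, oracle).pvalue > 0.01

    def test_invalid_configs(self):
        with pytest.raises(ValidationError):
            GrowthConfig(kernel="fitness", n_final=10)  # no fitness spec
        with pytest.raises(ValidationError):
            GrowthConfig(kernel="degree", n_final=3, m_edges=2, m0=5)
        with pytest.raises(ValidationError):
            GrowthConfig(kernel="degree", n_final=10, m_edges=3, m0=2)
        with pytest.raises(ValidationError):
            GrowthConfig(kernel="nope", n_final=10)
        with pytest.raises(ValidationError):
            GrowthConfig(kernel="degree", n_final=10, m_edges=1, m0=1)
        with pytest.raises(ValidationError):
            GrowthConfig(
                kernel="fitness", n_final=10,
                fitness_spec=FitnessVector.from_values([1.0] * 5),
            )


class TestGrownNetworkInvariants:
    def test_rejects_self_loop(self):
        with pytest.raises(ValidationError):
            GrownNetwork(
                edges=np.array([[0, 0]]),
                fitness=np.ones(2),
                arrival_order=np.arange(2),
                degree=np.array([2, 0]),
            )

    def test_rejects_duplicate_edge(self):
        with pytest.raises(ValidationError):
            GrownNetwork(
                edges=np.array([[0, 1], [1, 0]]),
                fitness=np.ones(2),
                arrival_order=np.arange(2),
                degree=np.array([2, 2]),
            )

    def test_rejects_inconsistent_degrees(self):
        with pytest.raises(ValidationError):
            GrownNetwork(
                edges=np.array([[0, 1]]),
                fitness=np.ones(2),
                arrival_order=np.arange(2),
                degree=np.array([1, 2]),
            )

    def test_to_networkx(self):
        cfg = GrowthConfig(
            kernel="fitness", n_final=30, m_edges=1, m0=2,
            fitness_spec=LognormalSpec(0.0, 1.0, 1, 0), seed=0,
        )
        net = grow_network(cfg)
        g = net.to_networkx()
        assert g.number_of_nodes() == 30
        assert g.number_of_edges() == net.n_edges
        assert g.nodes[0]["fitness"] == pytest.approx(net.fitness[0])


class TestEmpiricalFrequencies:
    def test_converges_to_closed_form(self):
        fv = FitnessVector.from_values([1.0, 3.0])
        freq = empirical_attachment_frequencies(fv, n_draws=100_000, seed=1)
        np.testing.assert_allclose(freq.weights, [0.25, 0.75], atol=0.01)

    def test_single_draw_one_hot(self):
        fv = FitnessVector.from_values([1.0, 2.0, 3.0])
        freq = empirical_attachment_frequencies(fv, n_draws=1, seed=0)
        assert sorted(freq.weights) == [0.0, 0.0, 1.0]

    def test_uniform_fitness_uniform_frequencies(self):
        fv = FitnessVector.from_values([2.0] * 5)
        freq = empirical_attachment_frequencies(fv, n_draws=200_000, seed=3)
        np.testing.assert_allclose(freq.weights, 0.2, atol=0.01)

    def test_binomial_error_scaling(self):
        # L1 error shrinks roughly like 1/sqrt(n_draws)
        fv = FitnessVector.from_values(np.linspace(1, 5, 10))
        p = fv.phi / fv.phi.sum()
        errs = []
        for n_draws in (1000, 100_000):
            freq = empirical_attachment_frequencies(fv, n_draws, seed=8)
            errs.append(np.abs(freq.weights - p).sum())
        assert errs[1] < errs[0]

    def test_invalid_draws(self):
        with pytest.raises(ValidationError):
            empirical_attachment_frequencies(
                FitnessVector.from_values([1.0]), n_draws=0
            )


class TestDegreeDistribution:
    def test_complete_seed_graph(self):
        # complete graph on 4 nodes: every degree equals 3
        edges = np.array([[u, v] for u in range(4) for v in range(u + 1, 4)])
        net = GrownNetwork(
            edges=edges, fitness=np.ones(4), arrival_order=np.arange(4),
            degree=np.full(4, 3),
        )
        dist = degree_distribution(net)
        np.testing.assert_array_equal(dist.values, [3])
        np.testing.assert_array_equal(dist.counts, [4])
        np.testing.assert_allclose(dist.ccdf, [1.0])

    def test_histogram_conservation(self):
        cfg = GrowthConfig(
            kernel="fitness", n_final=300, m_edges=2, m0=3,
            fitness_spec=LognormalSpec(0.0, 1.0, 1, 0), seed=5,
        )
        net = grow_network(cfg)
        dist = degree_distribution(net)
        assert dist.counts.sum() == net.n_nodes
        assert dist.ccdf[0] == pytest.approx(1.0)
        assert np.all(np.diff(dist.ccdf) <= 0)

    @pytest.mark.parametrize("seed", range(5))
    def test_heavy_tail_smoke(self, seed):
        # fitness-kernel growth with lognormal fitness: max degree at least an
        # order of magnitude above the median (descriptive, not a fit)
        cfg = GrowthConfig(
            kernel="fitness", n_final=5000, m_edges=2, m0=3,
            fitness_spec=LognormalSpec(0.0, 1.0, 1, 0), seed=seed,
        )
        net = grow_network(cfg)
        assert net.degree.max() >= 10 * np.median(net.degree)
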