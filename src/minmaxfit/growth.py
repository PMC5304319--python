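"""Fitness-driven network growth with pluggable attachment kernels.

Three kernels: ``degree`` (classic rich-get-richer), ``degree_fitness``
(attachment weight ``k_i * phi_i``), and ``fitness`` (weight ``phi_i`` alone,
the rule the minmax-exposure mechanism produces).  Growth starts from a
complete seed graph; each arriving node attaches to ``m_edges`` distinct
existing nodes drawn without replacement by sequential renormalisation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .errors import ValidationError
from .fitness import FitnessVector, LognormalSpec
from .homogeneous import SimplexDistribution

KERNELS = ("degree", "degree_fitness", "fitness")


@dataclass(frozen=True)
class GrowthConfig:
    """Configuration for one growth run.

    ``fitness_spec`` is either a :class:`LognormalSpec` (its ``scale_mu`` and
    ``shape_sigma`` are used; draws come from the run's own seeded stream) or
    an explicit :class:`FitnessVector` with at least ``n_final`` values,
    consumed in arrival order.
    """

    kernel: str
    n_final: int
    m_edges: int = 1
    m0: int | None = None
    fitness_spec: LognormalSpec | FitnessVector | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kernel not in KERNELS:
            raise ValidationError(
                f"unknown kernel {self.kernel!r}; expected one of {KERNELS}"
            )
        m0 = self.m_edges if self.m0 is None else self.m0
        object.__setattr__(self, "m0", int(m0))
        if self.m_edges < 1:
            raise ValidationError("m_edges must be >= 1")
        if self.m0 < self.m_edges:
            raise ValidationError("m0 must be >= m_edges")
        if self.n_final <= self.m0:
            raise ValidationError("n_final must exceed the seed size m0")
        if self.kernel != "fitness" and self.m0 < 2:
            raise ValidationError(
                "degree-based kernels need m0 >= 2 (a single seed node has "
                "degree zero and could never be attached to)"
            )
        if self.kernel != "degree" and self.fitness_spec is None:
            raise ValidationError(f"kernel {self.kernel!r} requires a fitness_spec")
        if (
            isinstance(self.fitness_spec, FitnessVector)
            and len(self.fitness_spec) < self.n_final
        ):
            raise ValidationError(
                "explicit fitness vector must cover all n_final nodes"
            )


@dataclass(frozen=True)
class GrownNetwork:
    """Result of a growth run: edges, per-node fitness, arrival order, degrees."""

    edges: np.ndarray  # (E, 2) int
    fitness: np.ndarray
    arrival_order: np.ndarray
    degree: np.ndarray

    def __post_init__(self) -> None:
        edges = np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)
        n = self.fitness.shape[0]
        if np.any(edges[:, 0] == edges[:, 1]):
            raise ValidationError("self-loop in edge list")
        canon = np.sort(edges, axis=1)
        if len({(int(u), int(v)) for u, v in canon}) != len(canon):
            raise ValidationError("duplicate edge in edge list")
        deg = np.bincount(edges.ravel(), minlength=n)
        if not np.array_equal(deg, self.degree):
            raise ValidationError("degree sequence inconsistent with edges")
        edges.setflags(write=False)
        object.__setattr__(self, "edges", edges)

    @property
    def n_nodes(self) -> int:
        return self.fitness.shape[0]

    @property
    def n_edges(self) -> int:
        return self.edges.shape[0]

    def to_networkx(self):
        """Export as a networkx Graph with fitness/arrival node attributes."""
        import networkx as nx

        g = nx.Graph()
        for i in range(self.n_nodes):
            g.add_node(
                i,
                fitness=float(self.fitness[i]),
                arrival_order=int(self.arrival_order[i]),
            )
        g.add_edges_from(map(tuple, self.edges))
        return g


def attachment_probabilities(
    kernel: str,
    degrees: np.ndarray | None,
    fitness: np.ndarray | None,
    candidate_set: np.ndarray | None = None,
) -> SimplexDistribution:
    """Normalised attachment weights over the candidate nodes.

    ``degree``: weight ``k_i``; ``degree_fitness``: ``k_i * phi_i``;
    ``fitness``: ``phi_i``.  ``candidate_set`` restricts (and orders) the
    nodes; by default all entries are candidates.
    """
    if kernel not in KERNELS:
        raise ValidationError(f"unknown kernel {kernel!r}")
    if kernel == "degree":
        w = np.asarray(degrees, dtype=np.float64)
    elif kernel == "fitness":
        w = np.asarray(fitness, dtype=np.float64)
    else:
        w = np.asarray(degrees, dtype=np.float64) * np.asarray(fitness, np.float64)
    if candidate_set is not None:
        w = w[np.asarray(candidate_set, dtype=np.int64)]
    if w.size == 0 or np.any(w < 0):
        raise ValidationError("attachment weights must be non-negative and non-empty")
    total = w.sum()
    if total <= 0:
        raise ValidationError("all attachment weights are zero")
    return SimplexDistribution(w / total)


def _draw_targets(
    rng: np.random.Generator, weights: np.ndarray, m: int
) -> np.ndarray:
    """m distinct indices, sampled sequentially with renormalisation."""
    w = weights.astype(np.float64).copy()
    out = np.empty(m, dtype=np.int64)
    for t in range(m):
        total = w.sum()
        if total <= 0:
            raise ValidationError("ran out of positive-weight candidates")
        out[t] = rng.choice(w.size, p=w / total)
        w[out[t]] = 0.0
    return out


def grow_network(config: GrowthConfig) -> GrownNetwork:
    """Grow a network to ``n_final`` nodes under the configured kernel.

    Starts from a complete graph on ``m0`` nodes; arrivals attach to
    ``m_edges`` distinct targets.  Fully deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n, m0, m = config.n_final, config.m0, config.m_edges

    if isinstance(config.fitness_spec, FitnessVector):
        phi = config.fitness_spec.phi[:n].copy()
    elif isinstance(config.fitness_spec, LognormalSpec):
        phi = rng.lognormal(
            mean=config.fitness_spec.scale_mu,
            sigma=config.fitness_spec.shape_sigma,
            size=n,
        )
    else:  # degree kernel without fitness
        phi = np.ones(n)

    edges = [(u, v) for u in range(m0) for v in range(u + 1, m0)]
    degree = np.zeros(n, dtype=np.int64)
    degree[:m0] = m0 - 1  # seed-graph degrees; avoids zero-weight dead nodes

    for new in range(m0, n):
        probs = attachment_probabilities(
            config.kernel,
            degree[:new],
            phi[:new],
        )
        targets = _draw_targets(rng, probs.weights, m)
        for t in targets:
            edges.append((int(t), new))
            degree[t] += 1
            degree[new] += 1

    return GrownNetwork(
        edges=np.asarray(edges, dtype=np.int64),
        fitness=phi,
        arrival_order=np.arange(n),
        degree=degree,
    )


def empirical_attachment_frequencies(
    fv: FitnessVector, n_draws: int, seed: int = 0
) -> SimplexDistribution:
    """Monte-Carlo check of the fitness kernel: frequency of each node over
    ``n_draws`` independent single-attachment draws."""
    if n_draws < 1:
        raise ValidationError("n_draws must be >= 1")
    rng = np.random.default_rng(seed)
    p = fv.phi / fv.phi.sum()
    picks = rng.choice(len(fv), size=n_draws, p=p)
    counts = np.bincount(picks, minlength=len(fv))
    return SimplexDistribution(counts / n_draws)


class DegreeDistribution(NamedTuple):
    """Exact histogram and complementary CDF of a degree sequence."""

    values: np.ndarray  # sorted distinct degrees
    counts: np.ndarray  # nodes with each degree
    ccdf: np.ndarray  # P(K >= value), aligned with `values`


def degree_distribution(net: GrownNetwork) -> DegreeDistribution:
    """Degree histogram plus CCDF arrays (log-log plotting ready)."""
    values, counts = np.unique(net.degree, return_counts=True)
    n = net.n_nodes
    ccdf = counts[::-1].cumsum()[::-1] / n
    return DegreeDistribution(values=values, counts=counts, ccdf=ccdf)
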