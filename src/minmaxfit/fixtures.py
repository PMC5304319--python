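"""Seeded synthetic systems matching the reference experimental setups.

Two canonical configurations recur throughout the tests: a small homogeneous
set of 12 log-normal(0, 1) nodes, and a four-tier layered system whose tier
spreads shrink downstream (shape parameters 3, 1, 1, 0.1 — wide oligopoly
upstream, near-perfect competition downstream).  Larger variants use the same
shapes with more nodes.
"""

from __future__ import annotations

import numpy as np

from .fitness import FitnessVector, LognormalSpec, sample_lognormal_fitness
from .tiered import TieredSystem

#: Downstream-shrinking tier shape parameters (suppliers ... retailers).
TIER_SIGMAS = (3.0, 1.0, 1.0, 0.1)

TIER_LABELS = ("suppliers", "manufacturers", "distributors", "retailers")


def small_homogeneous_system(seed: int, n: int = 12, sigma: float = 1.0) -> FitnessVector:
    """12 log-normal(mu=0, sigma=1) fitness values, seed-deterministic."""
    return sample_lognormal_fitness(LognormalSpec(0.0, sigma, n, seed))


def large_homogeneous_system(seed: int, n: int = 100, sigma: float = 1.0) -> FitnessVector:
    """100-node variant of the homogeneous setup."""
    return sample_lognormal_fitness(LognormalSpec(0.0, sigma, n, seed))


def tiered_system(
    seed: int,
    n_per_tier: int = 25,
    sigmas: tuple[float, ...] = TIER_SIGMAS,
) -> TieredSystem:
    """Four equal tiers with complete adjacency; one independent seeded
    stream per run, tiers drawn in order."""
    rng = np.random.default_rng(seed)
    tiers = []
    for k, sigma in enumerate(sigmas):
        phi = rng.lognormal(mean=0.0, sigma=sigma, size=n_per_tier)
        tiers.append(
            FitnessVector(
                tuple(f"t{k + 1}n{j}" for j in range(n_per_tier)),
                phi,
            )
        )
    labels = TIER_LABELS if len(sigmas) == len(TIER_LABELS) else None
    return TieredSystem(tuple(tiers), labels=labels)


def small_tiered_system(seed: int) -> TieredSystem:
    """12 nodes in four equal tiers (3 per tier), same tier shapes."""
    return tiered_system(seed, n_per_tier=3)


def sparse_tiered_system(
    seed: int,
    n_per_tier: int = 4,
    n_tiers: int = 4,
    edge_prob: float = 0.5,
) -> TieredSystem:
    """Random sparse-adjacency system, guaranteed to keep one feasible path.

    Each inter-tier link is kept with probability ``edge_prob``; a random
    spine path is forced on afterwards so the system never becomes infeasible.
    """
    rng = np.random.default_rng(seed)
    tiers = tuple(
        FitnessVector(
            tuple(f"t{k + 1}n{j}" for j in range(n_per_tier)),
            rng.lognormal(0.0, 1.0, n_per_tier),
        )
        for k in range(n_tiers)
    )
    blocks = [
        rng.random((n_per_tier, n_per_tier)) < edge_prob
        for _ in range(n_tiers - 1)
    ]
    spine = rng.integers(0, n_per_tier, size=n_tiers)
    for k in range(n_tiers - 1):
        blocks[k][spine[k], spine[k + 1]] = True
    return TieredSystem(tiers, tuple(blocks))
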