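"""Node fitness vectors: sampling, composition, and unfitness transforms.

Fitness ``phi`` is a dimensionless, strictly positive attractiveness score per
node.  Its reciprocal, the *unfitness* ``U = 1/phi``, is the quantity whose
maximum expected exposure the solvers minimise.  Strict positivity is a hard
requirement (it guarantees strictly positive attachment probabilities at the
optimum), so values at or below a small floor are rejected, never clamped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import ValidationError

#: Default lower bound below which fitness values are rejected.
FITNESS_FLOOR = 1e-12


@dataclass(frozen=True)
class FitnessVector:
    """Ordered node identifiers with strictly positive fitness values.

    Parameters
    ----------
    node_ids
        Unique node identifiers, one per fitness value.
    phi
        Strictly positive, finite fitness values.
    floor
        Values at or below this bound are rejected (not clamped).
    """

    node_ids: tuple[str, ...]
    phi: np.ndarray
    floor: float = field(default=FITNESS_FLOOR, compare=False, repr=False)

    def __post_init__(self) -> None:
        ids = tuple(str(i) for i in self.node_ids)
        phi = np.asarray(self.phi, dtype=np.float64)
        if phi.ndim != 1 or phi.size == 0:
            raise ValidationError("fitness vector must be 1-D and non-empty")
        if len(ids) != phi.size:
            raise ValidationError(
                f"{len(ids)} node ids for {phi.size} fitness values"
            )
        if len(set(ids)) != len(ids):
            raise ValidationError("node ids must be unique")
        if not np.all(np.isfinite(phi)):
            raise ValidationError("fitness values must be finite")
        if np.any(phi <= self.floor):
            bad = int(np.argmax(phi <= self.floor))
            raise ValidationError(
                f"fitness must be > {self.floor:g}; node "
                f"{ids[bad]!r} has fitness {phi[bad]!r}"
            )
        phi.setflags(write=False)
        object.__setattr__(self, "node_ids", ids)
        object.__setattr__(self, "phi", phi)

    def __len__(self) -> int:
        return self.phi.size

    @property
    def unfitness(self) -> np.ndarray:
        """Elementwise reciprocal of fitness, ``U_j = 1/phi_j``."""
        return 1.0 / self.phi

    @classmethod
    def from_values(cls, phi: Iterable[float], prefix: str = "n") -> "FitnessVector":
        """Build a vector with auto-generated ids ``n0, n1, ...``."""
        arr = np.asarray(list(phi), dtype=np.float64)
        return cls(tuple(f"{prefix}{i}" for i in range(arr.size)), arr)


@dataclass(frozen=True)
class LognormalSpec:
    """Parameters of a log-normal fitness distribution.

    ``scale_mu`` and ``shape_sigma`` are the mean and standard deviation of
    ``log(phi)`` (the conventional "scale" and "shape" parameters).
    """

    scale_mu: float
    shape_sigma: float
    n: int
    seed: int = 0

    def __post_init__(self) -> None:
        if not np.isfinite(self.scale_mu):
            raise ValidationError("scale_mu must be finite")
        if not (self.shape_sigma > 0) or not np.isfinite(self.shape_sigma):
            raise ValidationError("shape_sigma must be a positive finite real")
        if int(self.n) < 1:
            raise ValidationError("n must be a positive integer")
        object.__setattr__(self, "n", int(self.n))
        object.__setattr__(self, "seed", int(self.seed))


def sample_lognormal_fitness(
    spec: LognormalSpec, rng: np.random.Generator | None = None
) -> FitnessVector:
    """Draw ``spec.n`` log-normal fitness values, deterministic given the seed.

    An explicit ``rng`` overrides ``spec.seed`` (used when a caller manages a
    single seeded stream across several sampling calls).
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    phi = rng.lognormal(mean=spec.scale_mu, sigma=spec.shape_sigma, size=spec.n)
    return FitnessVector.from_values(phi)


def compose_fitness(attribute_matrix: Sequence[Sequence[float]]) -> FitnessVector:
    """Combine per-node attribute values multiplicatively into fitness.

    ``phi_j`` is the product of node *j*'s attributes; with many independent
    positive attributes the result is approximately log-normal.  Rows may have
    different lengths.  Every attribute must be strictly positive.
    """
    rows = [np.asarray(row, dtype=np.float64) for row in attribute_matrix]
    if not rows:
        raise ValidationError("attribute matrix must be non-empty")
    phi = np.empty(len(rows))
    for j, row in enumerate(rows):
        if row.ndim != 1 or row.size == 0:
            raise ValidationError(f"node {j}: attribute row must be 1-D and non-empty")
        if not np.all(np.isfinite(row)) or np.any(row <= 0):
            raise ValidationError(
                f"node {j}: all attribute values must be strictly positive"
            )
        # product of logs avoids overflow for many attributes
        phi[j] = np.exp(np.sum(np.log(row)))
    return FitnessVector.from_values(phi)


def to_unfitness(values: "FitnessVector | np.ndarray") -> np.ndarray:
    """Elementwise reciprocal; accepts a FitnessVector or a raw array."""
    if isinstance(values, FitnessVector):
        return values.unfitness
    arr = np.asarray(values, dtype=np.float64)
    if np.any(arr <= 0):
        raise ValidationError("values must be strictly positive")
    return 1.0 / arr
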