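"""Minmax-exposure solvers for tiered (layered) systems.

Nodes live in ordered tiers (e.g. suppliers -> manufacturers -> distributors
-> retailers) and feasible selections are paths picking one node per tier.
Because every path crosses every tier, per-tier selection probabilities each
sum to one and the problem decouples into one homogeneous minmax-exposure
problem per tier: ``p_jk* = phi_jk / sum_tier(phi)`` with tier value
``V_k = 1 / sum_tier(phi)``.

The iterative algorithm couples the tiers through its best-response stage: at
each round the scheduler picks the *path* minimising the avoidance-weighted
unfitness ``sum_k q_jk U_jk`` (a shortest path on the layered DAG — no path
enumeration), then each tier's demon targets its most exposed node.  Under
complete adjacency the shortest path separates into per-tier argmins, which
the fast kernel exploits; sparse adjacency uses the dynamic-programming
routine :func:`shortest_path`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._kernels import _a1_loop_complete
from .errors import InfeasibleError, ValidationError
from .fitness import FitnessVector
from .homogeneous import (
    DEFAULT_MAX_ITER,
    DEFAULT_TOL,
    GameState,
    MinmaxSolution,
    SimplexDistribution,
    closed_form_attachment,
    minmax_value,
    solve_lp_p0,
    step_size,
)


@dataclass(frozen=True)
class TieredSystem:
    """Ordered tiers of fitness vectors with inter-tier adjacency.

    ``adjacency[k]`` is a boolean matrix of shape ``(len(tier k),
    len(tier k+1))``; ``adjacency=None`` means complete adjacency between all
    consecutive tiers.  At least one full path must be feasible.
    """

    tiers: tuple[FitnessVector, ...]
    adjacency: tuple[np.ndarray, ...] | None = None
    labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        tiers = tuple(self.tiers)
        if len(tiers) < 2:
            raise ValidationError("a tiered system needs at least 2 tiers")
        if self.labels is not None:
            labels = tuple(str(x) for x in self.labels)
            if len(labels) != len(tiers):
                raise ValidationError("need one label per tier")
            object.__setattr__(self, "labels", labels)
        for k, fv in enumerate(tiers):
            if not isinstance(fv, FitnessVector):
                raise ValidationError(f"tier {k} is not a FitnessVector")
        adj = self.adjacency
        if adj is not None:
            adj = tuple(np.asarray(a, dtype=bool) for a in adj)
            if len(adj) != len(tiers) - 1:
                raise ValidationError(
                    f"{len(adj)} adjacency blocks for {len(tiers)} tiers"
                )
            for k, a in enumerate(adj):
                want = (len(tiers[k]), len(tiers[k + 1]))
                if a.shape != want:
                    raise ValidationError(
                        f"adjacency block {k} has shape {a.shape}, expected {want}"
                    )
            for a in adj:
                a.setflags(write=False)
        object.__setattr__(self, "tiers", tiers)
        object.__setattr__(self, "adjacency", adj)
        if not self._has_feasible_path():
            raise InfeasibleError("no feasible path traverses all tiers")

    @property
    def n_tiers(self) -> int:
        return len(self.tiers)

    @property
    def is_complete(self) -> bool:
        return self.adjacency is None or all(a.all() for a in self.adjacency)

    def block(self, k: int) -> np.ndarray:
        """Boolean adjacency between tier k and tier k+1."""
        if self.adjacency is None:
            return np.ones((len(self.tiers[k]), len(self.tiers[k + 1])), dtype=bool)
        return self.adjacency[k]

    def _has_feasible_path(self) -> bool:
        reach = np.ones(len(self.tiers[0]), dtype=bool)
        for k in range(self.n_tiers - 1):
            reach = self.block(k).T @ reach > 0
            if not reach.any():
                return False
        return True


@dataclass(frozen=True)
class PathSelection:
    """One node index per tier, consecutive picks adjacent in the system."""

    indices: tuple[int, ...]
    cost: float = field(default=np.nan, compare=False)

    @staticmethod
    def validate(indices, ts: TieredSystem) -> "PathSelection":
        idx = tuple(int(i) for i in indices)
        if len(idx) != ts.n_tiers:
            raise ValidationError("path must pick exactly one node per tier")
        for k, i in enumerate(idx):
            if not 0 <= i < len(ts.tiers[k]):
                raise ValidationError(f"tier {k}: index {i} out of range")
        for k in range(ts.n_tiers - 1):
            if not ts.block(k)[idx[k], idx[k + 1]]:
                raise ValidationError(
                    f"nodes {idx[k]} (tier {k}) and {idx[k + 1]} (tier {k + 1}) "
                    "are not adjacent"
                )
        return PathSelection(idx)


@dataclass
class TieredGameState:
    """Per-tier game iterates sharing one iteration counter."""

    iteration: int
    p: list[SimplexDistribution]
    q: list[SimplexDistribution]
    upper_bounds: np.ndarray
    lower_bounds: np.ndarray
    trace: list = field(default_factory=list)
    converged: tuple[bool, ...] = ()

    @property
    def duality_gaps(self) -> np.ndarray:
        return self.upper_bounds - self.lower_bounds

    @classmethod
    def initial(cls, ts: TieredSystem) -> "TieredGameState":
        p = [SimplexDistribution.uniform(len(fv)) for fv in ts.tiers]
        K = ts.n_tiers
        return cls(
            iteration=1,
            p=p,
            q=list(p),
            upper_bounds=np.full(K, np.inf),
            lower_bounds=np.full(K, -np.inf),
            converged=(False,) * K,
        )


def per_tier_closed_form(ts: TieredSystem) -> list[SimplexDistribution]:
    """Fitness-proportional selection within each tier."""
    return [closed_form_attachment(fv) for fv in ts.tiers]


def tier_minmax_values(ts: TieredSystem) -> list[float]:
    """Minmax expected unfitness per tier, ``V_k = 1 / sum_tier(phi)``."""
    return [minmax_value(fv) for fv in ts.tiers]


def solve_lp_p2(
    ts: TieredSystem,
) -> tuple[list[SimplexDistribution], list[SimplexDistribution], list[float]]:
    """Solve each tier's minmax program independently via the LP oracle.

    Returns per-tier primal ``p``, dual ``q``, and tier values ``V_k``.
    """
    sols = [solve_lp_p0(fv) for fv in ts.tiers]
    return (
        [s.p for s in sols],
        [s.q for s in sols],
        [s.value for s in sols],
    )


def shortest_path(
    ts: TieredSystem, q: list[SimplexDistribution] | list[np.ndarray]
) -> PathSelection:
    """Minimum avoidance-weighted-unfitness path through the layered DAG.

    Node weights are ``q_jk * U_jk``; the path cost is their sum over the
    picked nodes.  Dynamic programming, one pass per tier; ties break to the
    lowest node index (lexicographically from the downstream end via the
    backtrack, which matches independent lowest-index argmins when the
    adjacency is complete).
    """
    K = ts.n_tiers
    if len(q) != K:
        raise ValidationError("need one weight vector per tier")
    weights = []
    for k, qk in enumerate(q):
        w = qk.weights if isinstance(qk, SimplexDistribution) else np.asarray(qk, float)
        if w.shape != (len(ts.tiers[k]),):
            raise ValidationError(f"tier {k}: weight vector has wrong length")
        weights.append(w * ts.tiers[k].unfitness)
    cost = weights[0].copy()
    preds: list[np.ndarray] = []
    for k in range(1, K):
        blk = ts.block(k - 1)  # (n_{k-1}, n_k)
        upstream = np.where(blk, cost[:, None], np.inf)
        best_pred = np.argmin(upstream, axis=0)  # first (lowest) index on ties
        best_cost = upstream[best_pred, np.arange(blk.shape[1])]
        cost = best_cost + weights[k]
        cost[~np.isfinite(best_cost)] = np.inf
        preds.append(best_pred)
    if not np.isfinite(cost).any():
        raise InfeasibleError("no feasible path traverses all tiers")
    idx = np.empty(K, dtype=int)
    idx[-1] = int(np.argmin(cost))
    total = float(cost[idx[-1]])
    for k in range(K - 2, -1, -1):
        idx[k] = preds[k][idx[k + 1]]
    return PathSelection(tuple(int(i) for i in idx), cost=total)


def a1_step(state: TieredGameState, ts: TieredSystem) -> TieredGameState:
    """One round of the tiered game (reference implementation).

    The scheduler commits to the best path (unit auxiliary path probability),
    nudging each tier's ``p`` toward the path's node; each tier's demon then
    nudges ``q`` toward the node with the highest ``p_jk U_jk`` in its tier.
    """
    m = state.iteration
    alpha = step_size(m)
    path = shortest_path(ts, state.q)
    new_p, new_q = [], []
    ubs = np.empty(ts.n_tiers)
    lbs = np.empty(ts.n_tiers)
    for k, fv in enumerate(ts.tiers):
        U = fv.unfitness
        pk = (1.0 - alpha) * state.p[k].weights.copy()
        pk[path.indices[k]] += alpha
        i = int(np.argmax(pk * U))
        qk = (1.0 - alpha) * state.q[k].weights.copy()
        qk[i] += alpha
        ubs[k] = np.max(pk * U)
        lbs[k] = np.min(qk * U)
        new_p.append(SimplexDistribution(pk))
        new_q.append(SimplexDistribution(qk))
    return TieredGameState(
        iteration=m + 1,
        p=new_p,
        q=new_q,
        upper_bounds=ubs,
        lower_bounds=lbs,
        trace=state.trace + [(m + 1, ubs.copy(), lbs.copy())],
        converged=state.converged,
    )


def run_a1(
    ts: TieredSystem,
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float = DEFAULT_TOL,
    tol_rel: float = 0.0,
) -> tuple[list[MinmaxSolution], TieredGameState]:
    """Iterate the tiered game until every tier's duality gap passes.

    Stopping per tier: ``gap_k <= tol`` or, with ``tol_rel > 0``,
    ``gap_k <= tol_rel * lower_bound_k``.  Non-convergence is reported in the
    returned state's ``converged`` flags, never raised.  Complete-adjacency
    systems run on the compiled kernel; sparse ones fall back to the
    step-function (they are coupled through the path stage, so the per-tier
    shortcut would be wrong there).
    """
    if max_iter < 1:
        raise ValidationError("max_iter must be >= 1")
    if not (tol > 0):
        raise ValidationError("tol must be > 0")
    K = ts.n_tiers
    if ts.is_complete:
        U = np.concatenate([fv.unfitness for fv in ts.tiers])
        sizes = [len(fv) for fv in ts.tiers]
        offsets = np.concatenate([[0], np.cumsum(sizes)]).astype(np.int64)
        cp, cq, m, ubs, lbs, conv = _a1_loop_complete(
            np.ascontiguousarray(U), offsets, int(max_iter), float(tol),
            float(tol_rel),
        )
        p = [
            SimplexDistribution(cp[offsets[k]: offsets[k + 1]] / m)
            for k in range(K)
        ]
        q = [
            SimplexDistribution(cq[offsets[k]: offsets[k + 1]] / m)
            for k in range(K)
        ]
        gaps = ubs - lbs
        per_tier_ok = (gaps <= tol) | ((tol_rel > 0) & (gaps <= tol_rel * lbs))
        state = TieredGameState(
            iteration=int(m),
            p=p,
            q=q,
            upper_bounds=np.asarray(ubs, float),
            lower_bounds=np.asarray(lbs, float),
            converged=tuple(bool(b) for b in per_tier_ok),
        )
    else:
        state = TieredGameState.initial(ts)
        state.trace = []
        while state.iteration <= max_iter:
            gaps = state.duality_gaps
            ok = (gaps <= tol) | (
                (tol_rel > 0) & (gaps <= tol_rel * state.lower_bounds)
            )
            if state.iteration > 1 and bool(np.all(ok)):
                break
            state = a1_step(state, ts)
            state.trace = []  # unbounded otherwise; callers wanting a trace drive a1_step
        gaps = state.duality_gaps
        ok = (gaps <= tol) | (
            (tol_rel > 0) & (gaps <= tol_rel * state.lower_bounds)
        )
        state.converged = tuple(bool(b) for b in ok)
    solutions = [
        MinmaxSolution(
            p=state.p[k],
            q=state.q[k],
            value=float(state.upper_bounds[k]),
            lambda_dual=float(state.lower_bounds[k]),
        )
        for k in range(K)
    ]
    return solutions, state
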