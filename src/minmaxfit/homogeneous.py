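"""Minmax-exposure solvers for homogeneous node sets.

The problem: choose attachment probabilities ``p`` on the simplex to minimise
the largest exposure ``p_j * U_j`` to node unfitness ``U_j = 1/phi_j``.  Its
solution is fitness-proportional attachment,

    p_j* = phi_j / sum(phi),    V* = 1 / sum(phi),

and the dual "avoidance" weights coincide with the primal at the optimum
(``q* = p*``, ``V* = lambda*``).  Three routes are provided:

* :func:`closed_form_attachment` / :func:`minmax_value` — the analytic answer;
* :func:`solve_lp_p0` — a generic linear program, used as an independent
  oracle with dual extraction;
* :func:`run_a0` — fictitious play between a scheduler (picks the node with
  the lowest avoidance-weighted unfitness) and a demon (picks the node with
  the highest expected unfitness), averaged with step size ``1/(m+1)``
  (method of successive averages).  The closed form never enters the
  iteration; convergence is judged by the duality gap alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

from ._kernels import _a0_loop
from .errors import SolverError, ValidationError
from .fitness import FitnessVector

SIMPLEX_TOL = 1e-9

#: Default absolute duality-gap tolerance for the iterative solvers.
DEFAULT_TOL = 1e-4
#: Default iteration cap for the iterative solvers.
DEFAULT_MAX_ITER = 10**6


@dataclass(frozen=True)
class SimplexDistribution:
    """A probability vector: non-negative weights summing to one."""

    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=np.float64)
        if w.ndim != 1 or w.size == 0:
            raise ValidationError("weights must be a non-empty 1-D vector")
        if np.any(w < -SIMPLEX_TOL):
            raise ValidationError("weights must be non-negative")
        total = float(w.sum())
        if abs(total - 1.0) > SIMPLEX_TOL * max(1.0, w.size):
            raise ValidationError(f"weights sum to {total!r}, expected 1")
        w = np.maximum(w, 0.0)
        w.setflags(write=False)
        object.__setattr__(self, "weights", w)

    def __len__(self) -> int:
        return self.weights.size

    @classmethod
    def uniform(cls, n: int) -> "SimplexDistribution":
        return cls(np.full(n, 1.0 / n))

    @classmethod
    def point_mass(cls, n: int, index: int) -> "SimplexDistribution":
        w = np.zeros(n)
        w[index] = 1.0
        return cls(w)


@dataclass(frozen=True)
class MinmaxSolution:
    """Primal/dual solution of the minmax-exposure problem.

    ``value`` is the minmax expected unfitness V; ``lambda_dual`` is the
    multiplier on the normalisation constraint, equal to V at the optimum.
    """

    p: SimplexDistribution
    q: SimplexDistribution
    value: float
    lambda_dual: float

    def __post_init__(self) -> None:
        if not (self.value > 0):
            raise ValidationError("minmax value must be positive")


@dataclass
class GameState:
    """Iterate of the scheduler-vs-demon game.

    ``upper_bound = max_j p_j U_j`` and ``lower_bound = min_j q_j U_j``
    bracket the game value; their difference is the duality gap used as the
    stopping criterion.  ``trace`` collects ``(m, upper, lower)`` samples.
    """

    iteration: int
    p: SimplexDistribution
    q: SimplexDistribution
    upper_bound: float
    lower_bound: float
    trace: list = field(default_factory=list)
    converged: bool = False

    @property
    def duality_gap(self) -> float:
        return self.upper_bound - self.lower_bound

    @classmethod
    def initial(cls, n: int) -> "GameState":
        p = SimplexDistribution.uniform(n)
        return cls(iteration=1, p=p, q=p, upper_bound=np.inf, lower_bound=-np.inf)


def closed_form_attachment(fv: FitnessVector) -> SimplexDistribution:
    """Fitness-proportional attachment, ``p_j = phi_j / sum(phi)``."""
    return SimplexDistribution(fv.phi / fv.phi.sum())


def minmax_value(fv: FitnessVector) -> float:
    """Minmax expected network unfitness, ``V = 1 / sum(phi)``."""
    return 1.0 / float(fv.phi.sum())


def step_size(m: int) -> float:
    """MSA step size ``alpha_m = 1/(m+1)``, decreasing with divergent sum."""
    return 1.0 / (m + 1)


def solve_lp_p0(fv: FitnessVector) -> MinmaxSolution:
    """Solve the minmax-exposure linear program with a generic LP routine.

    Variables ``(p_1..p_n, V)``; minimise ``V`` subject to
    ``p_j U_j <= V`` for all j, ``sum p = 1``, ``p >= 0``.  The dual weights
    ``q`` are read off the exposure-constraint multipliers (normalised to sum
    to one, since solver sign/scale conventions vary) and ``lambda`` off the
    normalisation constraint.
    """
    n = len(fv)
    U = fv.unfitness
    c = np.zeros(n + 1)
    c[-1] = 1.0
    A_ub = np.hstack([np.diag(U), -np.ones((n, 1))])
    b_ub = np.zeros(n)
    A_eq = np.ones((1, n + 1))
    A_eq[0, -1] = 0.0
    b_eq = np.array([1.0])
    bounds = [(0.0, None)] * n + [(None, None)]
    res = linprog(
        c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq, bounds=bounds,
        method="highs",
    )
    if not res.success:
        raise SolverError(f"LP failed (status {res.status}): {res.message}")
    p = np.asarray(res.x[:n])
    value = float(res.x[-1])
    # HiGHS reports multipliers of <=-constraints as non-positive
    q_raw = -np.asarray(res.ineqlin.marginals)
    q_sum = q_raw.sum()
    if q_sum <= 0:
        raise SolverError("degenerate dual weights from LP")
    lam = float(res.eqlin.marginals[0])
    return MinmaxSolution(
        p=SimplexDistribution(p / p.sum()),
        q=SimplexDistribution(q_raw / q_sum),
        value=value,
        lambda_dual=lam,
    )


def a0_step(state: GameState, fv: FitnessVector) -> GameState:
    """One fictitious-play round (reference implementation).

    Scheduler moves ``p`` toward the node with the lowest ``q_j U_j``; demon
    then moves ``q`` toward the node with the highest ``p_i U_i`` under the
    *updated* p.  Ties break to the lowest index.
    """
    U = fv.unfitness
    m = state.iteration
    alpha = step_size(m)
    j = int(np.argmin(state.q.weights * U))
    p_new = (1.0 - alpha) * state.p.weights.copy()
    p_new[j] += alpha
    i = int(np.argmax(p_new * U))
    q_new = (1.0 - alpha) * state.q.weights.copy()
    q_new[i] += alpha
    ub = float(np.max(p_new * U))
    lb = float(np.min(q_new * U))
    return GameState(
        iteration=m + 1,
        p=SimplexDistribution(p_new),
        q=SimplexDistribution(q_new),
        upper_bound=ub,
        lower_bound=lb,
        trace=state.trace + [(m + 1, ub, lb)],
        converged=state.converged,
    )


def run_a0(
    fv: FitnessVector,
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float = DEFAULT_TOL,
    tol_rel: float = 0.0,
    trace_every: int = 0,
) -> tuple[MinmaxSolution, GameState]:
    """Iterate the game until the duality gap meets the tolerance.

    Stops when ``gap <= tol`` or, if ``tol_rel > 0``, when
    ``gap <= tol_rel * lower_bound`` (useful when the game value itself is
    tiny).  Non-convergence within ``max_iter`` is flagged on the returned
    state, not raised.  ``trace_every`` samples ``(m, upper, lower)`` bounds
    into the state's trace.
    """
    if max_iter < 1:
        raise ValidationError("max_iter must be >= 1")
    if not (tol > 0):
        raise ValidationError("tol must be > 0")
    U = np.ascontiguousarray(fv.unfitness)
    cp, cq, m, ub, lb, converged, tr_m, tr_ub, tr_lb, n_tr = _a0_loop(
        U, int(max_iter), float(tol), float(tol_rel), int(trace_every)
    )
    p = SimplexDistribution(cp / m)
    q = SimplexDistribution(cq / m)
    state = GameState(
        iteration=int(m),
        p=p,
        q=q,
        upper_bound=float(ub),
        lower_bound=float(lb),
        trace=[
            (int(tr_m[t]), float(tr_ub[t]), float(tr_lb[t])) for t in range(n_tr)
        ],
        converged=bool(converged),
    )
    solution = MinmaxSolution(
        p=p, q=q, value=float(ub), lambda_dual=float(lb)
    )
    return solution, state
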