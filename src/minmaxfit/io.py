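"""Plain-text (TSV) input/output.

Dialects
--------
Homogeneous fitness table::

    node_id<TAB>fitness

Tiered fitness table::

    node_id<TAB>tier<TAB>fitness

Both require the exact header line; numbers are written with 17 significant
digits so write-then-read round trips reproduce values bit-for-bit.  Parse
errors name the offending line number.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .errors import ValidationError
from .fitness import FitnessVector
from .homogeneous import MinmaxSolution, SimplexDistribution
from .tiered import TieredSystem

_FMT = "%.17g"

HOMOGENEOUS_HEADER = ("node_id", "fitness")
TIERED_HEADER = ("node_id", "tier", "fitness")


def _fmt(x: float) -> str:
    return _FMT % x


def read_fitness_tsv(path: str | Path) -> FitnessVector | TieredSystem:
    """Read a fitness table; the header decides the flavour.

    Tiered tables produce a :class:`TieredSystem` with complete adjacency and
    tiers ordered by first appearance in the file.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ValidationError(f"{path}: empty file")
    header = tuple(lines[0].rstrip("\n").split("\t"))
    if header == HOMOGENEOUS_HEADER:
        tiered = False
    elif header == TIERED_HEADER:
        tiered = True
    else:
        raise ValidationError(
            f"{path}: line 1: unrecognised header {header!r}"
        )
    ids: list[str] = []
    tiers: list[str] = []
    values: list[float] = []
    for lineno, raw in enumerate(lines[1:], start=2):
        if not raw.strip():
            continue
        parts = raw.split("\t")
        if len(parts) != len(header):
            raise ValidationError(
                f"{path}: line {lineno}: expected {len(header)} fields, "
                f"got {len(parts)}"
            )
        try:
            value = float(parts[-1])
        except ValueError:
            raise ValidationError(
                f"{path}: line {lineno}: fitness {parts[-1]!r} is not a number"
            ) from None
        if not np.isfinite(value) or value <= 0:
            raise ValidationError(
                f"{path}: line {lineno}: fitness must be strictly positive, "
                f"got {parts[-1]!r}"
            )
        ids.append(parts[0])
        if tiered:
            tiers.append(parts[1])
        values.append(value)
    if not ids:
        raise ValidationError(f"{path}: no data rows")
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        for lineno, i in enumerate(ids, start=2):
            if i in seen:
                raise ValidationError(
                    f"{path}: line {lineno}: duplicate node id {i!r}"
                )
            seen.add(i)
    if not tiered:
        return FitnessVector(tuple(ids), np.asarray(values))
    order: list[str] = []
    for t in tiers:
        if t not in order:
            order.append(t)
    tier_vectors = []
    for t in order:
        sel = [k for k, tt in enumerate(tiers) if tt == t]
        tier_vectors.append(
            FitnessVector(
                tuple(ids[k] for k in sel),
                np.asarray([values[k] for k in sel]),
            )
        )
    return TieredSystem(tuple(tier_vectors), labels=tuple(order))


def write_fitness_tsv(
    obj: FitnessVector | TieredSystem,
    path: str | Path,
    tier_labels: list[str] | None = None,
) -> None:
    """Write a fitness table in the flavour matching ``obj``."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        if isinstance(obj, FitnessVector):
            fh.write("\t".join(HOMOGENEOUS_HEADER) + "\n")
            for nid, phi in zip(obj.node_ids, obj.phi):
                fh.write(f"{nid}\t{_fmt(phi)}\n")
            return
        fh.write("\t".join(TIERED_HEADER) + "\n")
        labels = tier_labels or obj.labels or [
            f"tier{k + 1}" for k in range(obj.n_tiers)
        ]
        for label, fv in zip(labels, obj.tiers):
            for nid, phi in zip(fv.node_ids, fv.phi):
                fh.write(f"{nid}\t{label}\t{_fmt(phi)}\n")


def read_adjacency_tsv(path: str | Path, ts: TieredSystem) -> TieredSystem:
    """Attach sparse adjacency (``tier_index, upstream_node, downstream_node``,
    1-based upstream tier index) to an existing tiered system."""
    path = Path(path)
    blocks = [
        np.zeros((len(ts.tiers[k]), len(ts.tiers[k + 1])), dtype=bool)
        for k in range(ts.n_tiers - 1)
    ]
    index = [
        {nid: i for i, nid in enumerate(fv.node_ids)} for fv in ts.tiers
    ]
    with path.open("r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines or tuple(lines[0].split("\t")) != (
        "tier_index", "upstream_node", "downstream_node",
    ):
        raise ValidationError(f"{path}: line 1: bad adjacency header")
    for lineno, raw in enumerate(lines[1:], start=2):
        if not raw.strip():
            continue
        parts = raw.split("\t")
        if len(parts) != 3:
            raise ValidationError(
                f"{path}: line {lineno}: expected 3 fields, got {len(parts)}"
            )
        try:
            k = int(parts[0]) - 1
        except ValueError:
            raise ValidationError(
                f"{path}: line {lineno}: tier_index must be an integer"
            ) from None
        if not 0 <= k < ts.n_tiers - 1:
            raise ValidationError(
                f"{path}: line {lineno}: tier_index {parts[0]} out of range"
            )
        try:
            u = index[k][parts[1]]
            v = index[k + 1][parts[2]]
        except KeyError as exc:
            raise ValidationError(
                f"{path}: line {lineno}: unknown node id {exc.args[0]!r}"
            ) from None
        blocks[k][u, v] = True
    return TieredSystem(ts.tiers, tuple(blocks), labels=ts.labels)


def write_result_tsv(
    solution: MinmaxSolution,
    fv: FitnessVector,
    path: str | Path,
) -> None:
    """Write ``node_id, p, q, p_closed_form`` for a homogeneous solution."""
    p_closed = fv.phi / fv.phi.sum()
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("node_id\tp\tq\tp_closed_form\n")
        for nid, p, q, pc in zip(
            fv.node_ids, solution.p.weights, solution.q.weights, p_closed
        ):
            fh.write(f"{nid}\t{_fmt(p)}\t{_fmt(q)}\t{_fmt(pc)}\n")


def write_tiered_result_tsv(
    solutions: list[MinmaxSolution] | list[tuple[SimplexDistribution, SimplexDistribution]],
    ts: TieredSystem,
    path: str | Path,
    tier_labels: list[str] | None = None,
) -> None:
    """Write ``node_id, tier, p, q, p_closed_form`` rows for all tiers."""
    labels = tier_labels or ts.labels or [
        f"tier{k + 1}" for k in range(ts.n_tiers)
    ]
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("node_id\ttier\tp\tq\tp_closed_form\n")
        for k, fv in enumerate(ts.tiers):
            sol = solutions[k]
            if isinstance(sol, MinmaxSolution):
                pw, qw = sol.p.weights, sol.q.weights
            else:
                pw, qw = sol[0].weights, sol[1].weights
            pc = fv.phi / fv.phi.sum()
            for nid, p, q, c in zip(fv.node_ids, pw, qw, pc):
                fh.write(f"{nid}\t{labels[k]}\t{_fmt(p)}\t{_fmt(q)}\t{_fmt(c)}\n")


def write_trace_tsv(trace, path: str | Path) -> None:
    """Write a convergence trace as ``iteration, upper_bound, lower_bound``."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("iteration\tupper_bound\tlower_bound\n")
        for m, ub, lb in trace:
            fh.write(f"{m}\t{_fmt(ub)}\t{_fmt(lb)}\n")


def write_edge_list_tsv(net, path: str | Path) -> None:
    """Write grown-network edges as ``u<TAB>v``."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("u\tv\n")
        for u, v in net.edges:
            fh.write(f"{u}\t{v}\n")


def write_node_table_tsv(net, path: str | Path) -> None:
    """Write grown-network nodes as ``node_id, fitness, arrival_order, degree``."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("node_id\tfitness\tarrival_order\tdegree\n")
        for i in range(net.n_nodes):
            fh.write(
                f"{i}\t{_fmt(net.fitness[i])}\t{int(net.arrival_order[i])}"
                f"\t{int(net.degree[i])}\n"
            )
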