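# minmaxfit

Solvers and simulators for a behavioural account of fitness-proportional
attachment in growing networks: if new arrivals choose existing nodes so as
to **minimise their maximum exposure to node unfitness** (the reciprocal of
node fitness), the optimal attachment probabilities are exactly proportional
to fitness,

```
p*_j = phi_j / sum_i phi_i ,      V* = 1 / sum_i phi_i ,
```

where `V*` is the minmax expected unfitness. The package computes this
solution three independent ways and cross-checks them:

- **closed form** — the analytic answer above;
- **linear program** — `min V  s.t.  p_j U_j <= V, sum p = 1, p >= 0`
  solved with `scipy.optimize.linprog` (HiGHS), with dual "avoidance"
  weights `q` extracted from the exposure constraints (at the optimum
  `q* = p*` and `V* = lambda*`);
- **fictitious play** — a two-player zero-sum game between a scheduler
  (picks the node with the lowest avoidance-weighted unfitness) and a demon
  (picks the node with the highest expected unfitness), averaged with
  method-of-successive-averages step sizes `1/(m+1)`; convergence is judged
  by the duality gap `max_j p_j U_j - min_j q_j U_j`.

The same machinery extends to **tiered systems** (supply-chain style:
suppliers → manufacturers → distributors → retailers), where feasible
selections are paths picking one node per tier. The problem decouples into
one minmax program per tier; the iterative algorithm's best-response stage is
a shortest-path computation on the layered DAG (dynamic programming, no path
enumeration), which also supports sparse inter-tier adjacency.

A growth simulator produces networks under three attachment kernels —
`degree` (k_i), `degree_fitness` (k_i·phi_i), and `fitness` (phi_i, the rule
the minmax mechanism justifies) — with log-normal fitness sampling and
degree-distribution diagnostics.

## Layout

| module | contents |
| --- | --- |
| `minmaxfit.fitness` | `FitnessVector`, `LognormalSpec`, sampling, multiplicative attribute composition, unfitness transform |
| `minmaxfit.homogeneous` | closed form, LP oracle, fictitious play (`run_a0`), `SimplexDistribution`, `MinmaxSolution`, `GameState` |
| `minmaxfit.tiered` | `TieredSystem`, per-tier decomposition, per-tier LP, layered shortest path, coupled game (`run_a1`) |
| `minmaxfit.growth` | `GrowthConfig`, `grow_network`, attachment kernels, empirical attachment frequencies, degree distributions |
| `minmaxfit.io` / `minmaxfit.cli` / `minmaxfit.fixtures` | TSV formats, command-line interface, canonical seeded test systems |

The inner game loops are JIT-compiled with numba when available (pure-Python
fallback otherwise); with step size `1/(m+1)` the mixed strategies are
running averages of best-response indicators, so the loops carry integer-ish
count vectors rather than re-normalising on every iteration.

## CLI

```sh
# sample a 12-node log-normal fitness table
minmaxfit sample-fitness --n 12 --mu 0 --sigma 1 --seed 1 --out fitness.tsv

# solve it three ways (result columns: node_id, p, q, p_closed_form)
minmaxfit solve-homogeneous --fitness fitness.tsv --method closed --out closed.tsv
minmaxfit solve-homogeneous --fitness fitness.tsv --method lp     --out lp.tsv
minmaxfit solve-homogeneous --fitness fitness.tsv --method a0 --tol 1e-4 \
    --max-iter 10000000 --out a0.tsv --trace-out trace.tsv

# tiered systems (node_id<TAB>tier<TAB>fitness; optional sparse adjacency)
minmaxfit fixtures --seed 1 --out-dir fx
minmaxfit solve-tiered --fitness fx/tiered100.tsv --method a1 \
    --tol 1e-4 --tol-rel 1e-3 --max-iter 100000000 --out tiered.tsv

# grow a 5000-node network under the fitness kernel
minmaxfit grow --kernel fitness --n 5000 --m 2 --m0 3 --sigma 1 --seed 7 \
    --out-prefix net
```

Exit codes: `0` success, `2` validation error, `3` solver failure,
`4` non-convergence under `--strict`. A JSON config file (`--config`) can
supply any flag; explicit flags win. All numeric output is written with 17
significant digits and every run is bit-reproducible given `--seed`.

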