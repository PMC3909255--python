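# Methods

## Model

A bipartite association network `G = (X, Y, E)` has genes `X` (each typed
`lncRNA` or `coding`), diseases `Y`, and an edge `(x, y)` whenever the gene
is implicated in the disease. Gene and disease ids share one namespace (an
id may not appear on both sides), which protects the one-mode projections
from silent corruption. Edges are simple and undirected; degrees are edge
incidence counts, so the sum of gene degrees, the sum of disease degrees
and the edge count always agree.

### Resource-allocation weighting

The gene projection is weighted by the two-step resource-allocation
process: each gene splits one unit of resource equally over its diseases,
then each disease splits its pool equally over its genes. Merged into one
matrix,

    w_ij = (1 / k(x_j)) · Σ_l a_il a_jl / k(y_l),

the fraction of gene j's resource delivered to gene i. Properties relied
on throughout (and asserted in tests):

* columns of connected genes sum to exactly 1 (resource conservation);
  degree-0 genes get an all-zero row and column rather than an error, so
  gene indexing stays stable across cross-validation folds;
* `w_ij > 0` iff `i = j` (for connected genes) or i and j co-occur in some
  disease;
* the detailed-balance relation `w_ij k(x_j) = w_ji k(x_i)` (the shared
  disease sum is symmetric);
* the diagonal self-return term `w_jj` is kept — the process produces it.
  A `zero_diagonal` flag removes it for sensitivity analysis (note this
  breaks column normalization).

The explicit two-step simulation (`two_step_spread`) is retained as an
independent oracle: `W @ f` must agree with it to 1e-12 for any
non-negative `f`.

`W` is stored dense up to 2,000 genes and as a sparse CSR matrix above;
the contract is identical either way.

### Propagation

For a query disease `d`, `Y_g = 1` iff `(g, d)` is an edge. Scores iterate
`F_t = α W F_{t−1} + (1 − α) Y` from `F_0 = Y`. Since columns of `W` sum
to ≤ 1, the spectral radius of `αW` is below 1 for `α < 1` and the
iteration contracts to `F = (1 − α)(I − αW)^{-1} Y`, which
`propagate_closed_form` computes by a direct solve as the numerical oracle.

Parameters (units: dimensionless):

| parameter | default | meaning |
|---|---|---|
| `alpha` | 0.618 | weight of network information vs. own initial information |
| `tol` | 1e-5 | stopping threshold on the deviation statistic |
| `max_iter` | 1000 | safeguard cap (the iteration provably converges) |
| `deviation` | `mean_square` | statistic compared against `tol` |

`alpha = 0` is admitted as the degenerate limit (`F = Y` after one
iteration). Two stopping statistics are supported. `mean_square` — the
mean of squared per-gene changes — is the default. It controls the *step*
size, not the distance to the fixed point: at stopping, that distance is
of order `sqrt(tol · n) · α/(1−α)` in the worst case. When a guaranteed
error bound is needed (e.g. when validating against the closed form), use
`deviation="max_abs"`, for which the final error is at most
`tol · α/(1−α)` — below `10·tol` for `α ≤ 0.9`. Ranking, which is all that
predictions use, is insensitive to this distinction at the default
tolerance.

A boundedness caveat: although `W` is column-stochastic, its *rows* may sum
to more than 1 (e.g. a gene whose co-associated genes all have degree 1),
so scores can exceed 1 for some 0/1 inputs. Scores are always non-negative,
conserve total mass when all genes are connected, and scale linearly in
`Y`; tests assert exactly these properties.

### Ranking and prediction

Only genes *not* associated with the query disease are ranked, descending
by score, ties broken by ascending gene id. The tie rule is deliberate and
load-bearing: ranks define predictions, and a platform-dependent sort would
make runs irreproducible. Thresholds: top fraction `ceil(f · n)` with a
floor of one candidate (so "top 1%" never selects zero genes from a small
pool), or top-k (`min(k, n)`).

## Evaluation

Leave-one-out cross-validation first removes nodes of degree one (a
held-out edge at such a node would isolate it, and an isolated node can
receive no information). Pruning is a **single pass** on the input degrees
— the literal reading of "remove the degree-one nodes" — with an
`iterative=True` option for fixpoint pruning; the single-pass output can
therefore itself contain degree-one endpoints, and one test pins exactly
this semantics. For every retained edge, the edge is removed, `W` is
rebuilt on the reduced network (so the held-out association cannot leak
through the weights), and the held-out gene's rank among the reduced
network's candidates is recorded.

The rank-threshold ROC sweeps δ = 1..100: TPR(δ) is the fraction of
held-out associations ranked within the top δ, FPR(δ) the fraction of
unassociated pairs ranked within the top δ. Negative-pair ranks are
computed once from the intact (filtered) network; a `per_fold_negatives`
option re-scores them inside every fold at |E|-fold cost with the same
asymptotics. AUC is the trapezoidal area with endpoints (0,0) and (1,1)
appended, because the sweep need not reach FPR = 1. Since δ stops at 100,
the appended segment dominates when the candidate pool is much larger than
100; at the small study scale (≈240 candidates) the sweep covers 40% of
the rank range, which makes the chance level sit slightly above 0.5 for
degree-skewed networks (held-out positives are degree-weighted, and
propagation mildly favors hubs).

## Randomization and robustness

The null model is the bipartite configuration model sampled by double edge
swaps: two edges `(g1,d1), (g2,d2)` are rewired to `(g1,d2), (g2,d1)`
unless that would duplicate an edge or touch a shared endpoint. Default
budget 10 × |E| attempted swaps — a standard mixing heuristic; every node's
degree is preserved exactly and the graph stays simple. Networks with no
legal swap (complete bipartite blocks) return unchanged.

Resampling robustness fixes the top-1% prediction set on the full network,
then repeatedly drops `floor(0.10 · |E|)` uniformly chosen edges and counts
re-predictions (`R`); "re-predicted" means the pair lands in the resample's
own top-1% set, with the threshold recomputed on the reduced candidate
pool. The matched chance count `R_r` runs the identical procedure on
degree-preserving shuffles. The summary z is a two-sample statistic with
sample (n−1) standard deviations; all ensemble z-tests use sample sd.

## Topology

Clustering is the Watts–Strogatz local coefficient; the network value is
the mean over **all** vertices, with degree-<2 vertices contributing 0 (an
`include_low_degree=False` flag averages over degree-≥2 vertices only,
since either convention appears in the literature). Degree-matched null
ensembles for projection statistics use double edge swaps on the
projection itself, which guarantees simple graphs with the same degree
sequence; the degree sequence is re-checked on every draw. The power-law
character of degree distributions is reported descriptively — a least
squares slope of log density vs. log degree on power-of-two bins — with no
maximum-likelihood exponent fitting; module detection is out of scope.

## Synthetic fixtures

The generator emulates the two structural features the method exploits:

* **heavy-tailed degrees** via preferential attachment on a fixed node
  set — attachment weight `(degree + 1)^(degree_exponent − 1)`, default
  exponent 2.0 (linear kernel);
* **disease-class blocks**: diseases are partitioned evenly into
  `n_classes` classes (default 20) and every gene has a home class; each
  disease draw multiplies the attachment weight of home-class diseases by
  `within_class_bias`. The default bias of 100 makes a gene's associations
  strongly class-pure (≈85% in its home class at the default geometry),
  reflecting the observation that most disease genes and lncRNAs act
  within a single phenotype class; it yields a small-fixture
  cross-validation AUC near the value reported for real curated networks.
  Bias 1 is the matched no-signal control and is verified to be
  statistically indistinguishable from degree-preserving shuffles.

A seeding phase gives every disease one association (preferring genes of
the matching home class) so all diseases are scorable. An optional edge
quota (`n_lncrna_edges`) fixes the lncRNA/coding split exactly; the
full-scale preset uses 578 + 980 = 1558. Each fixture also emits hidden
class-consistent pairs absent from the network, used as planted "true"
associations in recovery tests.

What the generator does **not** emulate: real disease/gene identities,
literature ascertainment bias, cross-class comorbidity structure, and
gene–gene interaction data. Passing tests therefore demonstrate that the
pipeline recovers a planted co-association signal at realistic sparsity —
not that any particular real association is correct.

## Problem sizes and determinism

The default test scale is 60 diseases / 250 genes / 500 associations,
chosen so that a full cross-validation (weights rebuilt per fold) runs in
well under a second and ensemble experiments (50 shuffled replicates, 100
resamples) complete in seconds to minutes on one CPU; the full-size preset
(214 / 1096 / 1558) generates in about a second and is used for count and
degree-shape checks. All stochastic steps take explicit integer seeds
(numpy `default_rng`); fixed seeds give identical networks, identical
cross-validation records and byte-identical CLI outputs.

## Known limitations

* Propagation treats the weighted projection as a similarity matrix; where
  genuine gene–gene interaction or similarity data exist they may carry
  more biological meaning than co-association alone.
* The rank-threshold AUC depends on δ_max relative to the candidate pool;
  comparisons are meaningful only at matched geometry.
* Single-pass degree pruning is a convention; fixpoint pruning can remove
  more nodes and is available behind a flag.
* The z-statistics assume approximately normal null ensembles; for highly
  discrete counts (small networks) they are indicative, not exact.
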