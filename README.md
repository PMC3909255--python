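# lncnet

Network-based analysis of lncRNA–disease associations and propagation-based
prediction of disease genes.

Long non-coding RNAs (lncRNAs) are implicated in a broad range of human
diseases, but known lncRNA–disease associations are sparse. `lncnet` is for
computational biologists who want to study such associations as a network
and prioritize new candidate genes for a disease from the network alone: it
models known associations of coding genes and lncRNAs with diseases as a
bipartite graph, analyzes its structure, and scores every gene against
every disease by propagation on a weighted gene projection.

## The method

Let `a_il ∈ {0,1}` be the bipartite adjacency between genes `x_i` and
diseases `y_l`, with gene degrees `k(x_j)` and disease degrees `k(y_l)`.

**Resource-allocation weighting.** Each gene spreads one unit of resource
equally over its diseases, and each disease returns its pooled resource
equally to its genes. The merged two-step process is the weighted gene
projection

```
w_ij = (1 / k(x_j)) · Σ_l  a_il · a_jl / k(y_l)
```

`w_ij` is the fraction of gene *j*'s resource ending on gene *i*; columns
of connected genes sum to exactly 1, so `W` conserves resource.

**Propagation scoring.** For a query disease *d*, the initial information
vector `Y` marks its associated genes (`Y_g = 1`). Scores iterate

```
F_t = α · W · F_{t−1} + (1 − α) · Y,     F_0 = Y
```

with `α = 0.618` by default, stopping when the mean-square change drops to
`1e-5`. The limit is `F = (1 − α)(I − α W)^{-1} Y`, available directly as a
cross-check. Genes not yet associated with *d* are ranked by `F`; the top
1% (or top *k*) are the predicted associations.

**Evaluation and nulls.** Leave-one-out cross-validation hides each
association in turn (weights rebuilt without it) and records the recovery
rank; TPR/FPR at rank thresholds δ = 1..100 give a ROC and AUC.
Degree-preserving double-edge-swap shuffles provide the chance baseline,
resampling (repeatedly dropping 10% of edges) measures prediction
stability, and one-mode projections are compared with degree-matched random
ensembles (clustering, giant components, within-class link enrichment).

Because no curated association table is redistributable, the package ships
a synthetic generator that emulates the data's structure — heavy-tailed
degrees and disease-class blocks — at a small study scale (60 diseases,
250 genes, 500 associations) and at full scale (214 diseases, 295 lncRNAs +
801 coding genes, 1558 associations).

## Worked example

`examples/03_cross_validation.py` (all examples run in seconds):

```
$ python examples/03_cross_validation.py
integrated network: 462 associations retained after degree-1 pruning (121 genes, 60 diseases)
  LOOCV AUC = 0.8048 over 461 folds
  TPR at rank threshold 10: 0.536 (fraction of held-out pairs recovered in the top 10)

degree-preserving shuffle: AUC = 0.5055 (chance level)

lncRNA-only AUC = 0.7063, integrated AUC = 0.8048 (difference +0.0986)
```

Reading the numbers: after removing degree-one nodes (which cannot be
recovered), hiding each of the 462 retained associations and re-scoring
recovers more than half of them within the top 10 of ~240 candidates, for
an AUC of 0.80. The same procedure on a degree-preserving shuffle of the
network collapses to 0.51 — the signal lives in *which* genes and diseases
are connected, not in the degree sequence. Restricting the network to
lncRNA associations only costs about ten AUC points: integrating
coding-gene associations adds paths through which candidate lncRNAs receive
information.

Other examples: `01_network_and_projections.py` (projections, clustering,
giant components, same-class enrichment), `02_predict_candidates.py`
(top-10 candidates for one disease), `04_robustness.py` (resampling
stability of the prediction set).

## Command line

A thin CLI wraps the same entry points:

```
lncnet synth --preset small --seed 0 --out fixture/
lncnet predict --associations fixture/associations.tsv --alpha 0.618 --top-fraction 0.01 --out out/
lncnet loocv --associations fixture/associations.tsv --delta-max 100 --out cv/
lncnet shuffle --associations fixture/associations.tsv --seed 1 --out shuffled.tsv
lncnet robustness --associations fixture/associations.tsv --n-resample 1000 --drop-frac 0.10 --out rob/
lncnet topology --associations fixture/associations.tsv --side disease --n-random 100 --out topo/
lncnet compare --lnc lnc.tsv --integrated all.tsv --out cmp/
```

Outputs are TSV/JSON with a provenance header (version, configuration,
seed); identical configurations give byte-identical files.

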