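"""Leave-one-out cross-validation with a rank-threshold ROC.

Hides each association in turn, rebuilds the weight matrix without it,
re-scores the disease and records the held-out gene's recovery rank.  The
ROC sweeps rank thresholds 1..100; AUC near 1 means held-out associations
are recovered at the top of the candidate list.  A degree-preserving
shuffle of the same network calibrates the chance level, and the
lncRNA-only network shows what integrating coding genes adds.
"""

import lncnet as ln

lnc_only, integrated, _ = ln.make_paired_fixture(ln.GeneratorConfig(seed=0))
cfg = ln.PropagationConfig(alpha=0.618, tol=1e-5)

result = ln.loocv(integrated, cfg)
roc = ln.roc_from_ranks(result, delta_max=100)
print(f"integrated network: {result.n_edges} associations retained after "
      f"degree-1 pruning ({result.n_genes} genes, {result.n_diseases} diseases)")
print(f"  LOOCV AUC = {roc.auc:.4f} over {len(result.folds)} folds")
print(f"  TPR at rank threshold 10: {roc.tpr[9]:.3f} "
      f"(fraction of held-out pairs recovered in the top 10)")

shuffled = ln.degree_preserving_shuffle(integrated, ln.ShuffleConfig(seed=100))
roc_null = ln.roc_from_ranks(ln.loocv(shuffled, cfg), delta_max=100)
print(f"\ndegree-preserving shuffle: AUC = {roc_null.auc:.4f} (chance level)")

report = ln.compare_networks(lnc_only, integrated, cfg)
print(f"\nlncRNA-only AUC = {report.auc_lnc_only:.4f}, "
      f"integrated AUC = {report.auc_integrated:.4f} "
      f"(difference {report.difference:+.4f})")
print("integrating coding-gene associations densifies the class blocks and")
print("improves recovery of held-out lncRNA-disease associations")
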