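"""Stage classification with module-structured Sparse Group Lasso.

Simulates a cohort where one planted miRNA module carries the tumor signal,
fits the SGL classifier using the true modules as groups, and compares its
held-out AUROC against a plain L1-regularized logistic model at the same
penalty strength. Also ranks biomarkers and evaluates precision/recall at k
against a "known marker" list (here: the planted relevant miRNAs).
"""

import mdsn
from mdsn.classifier import GroupStructure

mirna, _, design, truth = mdsn.simulate_cohort(
    n_mirna=200, n_mrna=50, n_modules=4, mirnas_per_module=10,
    targets_per_module=10, subtype_sizes={"alpha": 150, "beta": 150},
    corr_scheme={(m, "alpha"): -0.2 for m in range(4)},
    effect_size=6.0, stage_classes=2, n_relevant_modules=1, seed=3,
)
X, y, _ = mdsn.stage_matrix(mirna, design)
groups = GroupStructure.from_partition(mirna.feature_ids, mdsn.ground_truth_partition(truth))
train, test = mdsn.holdout_split(y, test_fraction=0.8, seed=3)
print(f"{len(train)} training / {len(test)} test samples, {X.shape[1]} miRNAs")

sgl = mdsn.fit_sgl_logistic(
    X[train], y[train], groups, lam=0.05, alpha=0.5, feature_ids=mirna.feature_ids
)
l1 = mdsn.fit_sgl_logistic(
    X[train], y[train], GroupStructure.singletons(X.shape[1]), lam=0.05, alpha=1.0
)
print(f"SGL with modules: macro-AUROC = {mdsn.macro_auroc(sgl, X[test], y[test]):.3f} "
      f"({sgl.n_candidates} candidate miRNAs)")
print(f"pure L1:          macro-AUROC = {mdsn.macro_auroc(l1, X[test], y[test]):.3f} "
      f"({l1.n_candidates} candidate miRNAs)")

known = {m for m, mod in truth.module_of.items() if mod in truth.relevant_modules}
table = mdsn.rank_and_evaluate_biomarkers(sgl, known, k_list=[5, 10, 20])
print("\nprecision/recall of top-|coefficient| candidates vs the relevant module:")
print(table.to_string(index=False))
print("\nhigh precision at small k means the strongest coefficients point at")
print("the miRNAs that actually drive the stage signal.")
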