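# mdsn — miRNA dysregulational synergism networks

`mdsn` identifies groups of microRNAs that lose or change their grip on a
shared set of target mRNAs between sub-populations of a cancer cohort, and
uses those groups to improve stage classification and biomarker ranking from
miRNA expression alone. It is aimed at systems-biology analyses of paired
miRNA/mRNA expression cohorts (e.g. TCGA-style data) where histological or
expression-derived subtypes are available.

## The method

Given sample-matched miRNA expression **x**ᵢ and mRNA expression **y**ⱼ and
two sample groups A and B, a *dysregulation* of the pair (i, j) is a
significant change in their Pearson correlation:

    Dys_ij = r_A(x_i, y_j) − r_B(x_i, y_j)

tested with Fisher's variance-stabilizing transform, z = atanh(r),

    z_AB = (z_A − z_B) / sqrt(1/(n_A−3) + 1/(n_B−3)),   p = 2(1 − Φ(|z_AB|))

at p < 0.001, with the *inverse-correlation prerequisite*: the pair must be
negatively correlated in at least one group, since miRNAs repress their
targets. A slower pooled-permutation test is included as a reference.

Significant pairs from every pairwise-subtype analysis are concatenated into
a binary association matrix **A** (miRNA × (target, analysis)). Two miRNAs
are *synergistic* when they dysregulate overlapping targets; the synergism
network M has edge weights

    s(p, q) = A_p · A_q / (‖A_p‖₂ ‖A_q‖₂)   (cosine similarity, in [0, 1])

optionally raised to a power β (default 1). The network is pruned with the
least stringent hard threshold at which the degree distribution keeps a
scale-free fit R² = corr(log₁₀ k, log₁₀ p(k))² ≥ 0.8, and miRNA modules are
extracted by Louvain modularity clustering. Module agreement across
analyses is measured by normalized mutual information (NMI).

Finally, a one-vs-rest logistic classifier of cancer stage is fitted with
the Sparse Group Lasso penalty over the modules,

    min_W  (1/s) Σᵢ log(1 + exp(−cᵢ·(Wᵀxⁱ))) + λα‖W‖₁ + λ(1−α) Σ_g √|g| ‖W_g‖₂

(FISTA with the exact two-stage proximal operator), so that selecting one
miRNA pulls in the rest of its module. Biomarkers are ranked by absolute
coefficient and scored by precision/recall at k against a known-marker list.

## Worked example

`examples/02_network_and_modules.py` simulates a cohort with 4 planted
modules of 10 miRNAs whose repression of disjoint target sets (r = −0.8)
exists only in subtype alpha, then runs the full chain:

```
association matrix: 40 miRNAs x 100 (target, analysis) columns, 993 dysregulations
hard threshold 0.05: 40 non-isolated miRNAs remain
Louvain found 4 modules, modularity Q = 0.746
agreement with the planted modules: NMI = 1.000 (1.0 = perfect recovery)
```

993 of the 40 × 25 = 1000 planted pairs are detected at p < 0.001, and the
modules are recovered exactly (NMI = 1). `examples/03_stage_classification.py`
shows the classifier half — with one planted tumor-relevant module among 200
miRNAs and 60 training samples:

```
SGL with modules: macro-AUROC = 0.802 (31 candidate miRNAs)
pure L1:          macro-AUROC = 0.783 (26 candidate miRNAs)
 k  precision  recall
 5       0.60     0.3
10       0.70     0.7
20       0.45     0.9
```

The module prior buys ~2 AUROC points over plain L1 at the same λ, and the
top-ranked coefficients concentrate in the truly relevant module.

The other examples cover single-pair dysregulation testing (01) and file
I/O, preprocessing and sample alignment (04).

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the full pipeline from scratch on a seeded synthetic cohort —
dysregulation counts, threshold selection, module recovery NMI and per-stage
AUROC are printed to stderr — and writes the results JSON to `--out`.

## Package layout

| module | contents |
|---|---|
| `mdsn.io` | `ExpressionMatrix`, `GroupDesign`, TSV readers/writers, log2/z preprocessing, sample alignment, JSON config |
| `mdsn.simulate` | synthetic cohorts with planted dysregulation modules and stage labels; ground-truth partitions |
| `mdsn.dysregulation` | Pearson/Fisher machinery, permutation reference, pairwise-subtype analyses, association matrix |
| `mdsn.network` | cosine-similarity network, scale-free fit, hard-threshold selection, pruning, edge-list/GraphML export |
| `mdsn.communities` | weighted modularity, Louvain modules, NMI, consistency matrices |
| `mdsn.classifier` | sparse-group-lasso logistic (FISTA + exact prox), cross-validation, AUROC, biomarker ranking |
| `mdsn.pipeline` | end-to-end orchestration and deterministic output writing |
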