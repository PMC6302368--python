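"""Reading expression tables, preprocessing, and sample alignment.

Writes a small raw-abundance cohort to TSV (the on-disk format: features in
rows, tab-separated, sample IDs in the header), reads it back, log2/z-scores
it, and aligns the miRNA matrix, mRNA matrix and annotations on their shared
samples.
"""

import tempfile
from pathlib import Path

import mdsn

tmp = Path(tempfile.mkdtemp())

mirna_std, mrna_std, design, _ = mdsn.simulate_cohort(
    n_mirna=10, n_mrna=20, n_modules=2, mirnas_per_module=3, targets_per_module=5,
    subtype_sizes={"alpha": 10, "beta": 10}, seed=1,
)
# export on the raw-abundance scale, as real quantifications would arrive
mdsn.write_expression_matrix(mdsn.to_raw_scale(mirna_std), tmp / "mirna.tsv")
mdsn.write_expression_matrix(mdsn.to_raw_scale(mrna_std), tmp / "mrna.tsv")
mdsn.write_group_design(design, tmp / "samples.tsv")

mirna = mdsn.read_expression_matrix(tmp / "mirna.tsv")
print(f"read {mirna.n_features} miRNAs x {mirna.n_samples} samples "
      f"(raw abundance, min = {mirna.values.min():.2f})")

mirna = mdsn.preprocess_expression(mirna, pseudocount=1.0)
print(f"after log2(x + 1) and per-feature z-scoring: "
      f"row means ~ {abs(mirna.values.mean(axis=1)).max():.1e}, "
      f"row sds ~ {mirna.values.std(axis=1).max():.6f}")

mrna = mdsn.preprocess_expression(mdsn.read_expression_matrix(tmp / "mrna.tsv"))
annot = mdsn.read_group_design(tmp / "samples.tsv")
mirna, mrna, annot = mdsn.align_samples(mirna, mrna, annot)
print(f"aligned on {len(annot.sample_ids)} shared samples; "
      f"subtype groups: { {k: len(v) for k, v in annot.subtype_groups().items()} }")
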