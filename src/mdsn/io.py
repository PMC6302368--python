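"""Expression-matrix and sample-annotation containers, readers and preprocessing.

Expression tables are tab-separated with a header row of sample IDs and a
leading feature-identifier column (the layout TCGA-style matrices are usually
shipped in). Annotation tables carry one row per sample with columns
``sample_id``, ``subtype`` and ``stage``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import (
    AlignmentError,
    AlreadyProcessedError,
    DomainError,
    IdentifierCollisionError,
    LabelError,
    ParseError,
)

DEFAULT_LABEL_ORDER = ("normal", "I", "II", "III", "IV")

#: Default configuration for the whole pipeline. ``p_threshold`` and the
#: inverse-correlation prerequisite follow the published analysis; the
#: similarity power beta=1 and the R^2 > 0.8 scale-free criterion follow
#: WGCNA practice.
DEFAULT_CONFIG = {
    "p_threshold": 0.001,
    "require_negative": True,
    "beta": 1.0,
    "r2_min": 0.8,
    "threshold_grid": [round(0.05 * i, 2) for i in range(1, 20)],
    "sgl_lambda": 1.0,
    "sgl_alpha": 0.5,
    "seed": 0,
    "label_order": list(DEFAULT_LABEL_ORDER),
}


@dataclass
class ExpressionMatrix:
    """Feature x sample real-valued expression with identifiers.

    ``processed`` tracks whether values are raw non-negative abundances
    (False) or log2 + per-feature z-scored (True). ``constant_features``
    marks zero-variance rows that were set to all-zero during preprocessing
    and must be excluded from correlation testing.
    """

    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    processed: bool = False
    constant_features: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        for name, ids in (("feature", self.feature_ids), ("sample", self.sample_ids)):
            if len(set(ids)) != len(ids):
                dupes = sorted({i for i in ids if ids.count(i) > 1})
                raise IdentifierCollisionError(f"duplicate {name} identifiers: {dupes}")

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.sample_ids)

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return replace(self, sample_ids=list(sample_ids), values=self.values[:, idx])


@dataclass
class GroupDesign:
    """Sample-to-subtype and sample-to-stage assignments.

    Samples may lack a subtype label ("not otherwise specified"); they stay
    available for stage classification but are excluded from subtype
    dysregulation analyses.
    """

    sample_ids: list[str]
    subtype_of: dict[str, str] = field(default_factory=dict)
    stage_of: dict[str, str] = field(default_factory=dict)
    label_order: tuple[str, ...] = DEFAULT_LABEL_ORDER

    def __post_init__(self):
        known = set(self.sample_ids)
        stray = set(self.subtype_of) - known
        if stray:
            raise ValueError(f"subtype labels for unknown samples: {sorted(stray)}")
        bad = {v for v in self.stage_of.values() if v not in self.label_order}
        if bad:
            raise LabelError(
                f"stage labels {sorted(bad)} not in label order {list(self.label_order)}"
            )

    def subtype_groups(self) -> dict[str, list[str]]:
        """Map subtype label -> sample IDs carrying it (insertion order kept)."""
        groups: dict[str, list[str]] = {}
        for s in self.sample_ids:
            label = self.subtype_of.get(s)
            if label is not None:
                groups.setdefault(label, []).append(s)
        return groups

    def subset(self, sample_ids: list[str]) -> "GroupDesign":
        keep = set(sample_ids)
        return GroupDesign(
            sample_ids=list(sample_ids),
            subtype_of={s: v for s, v in self.subtype_of.items() if s in keep},
            stage_of={s: v for s, v in self.stage_of.items() if s in keep},
            label_order=self.label_order,
        )


def read_expression_matrix(path, orientation: str = "features_in_rows") -> ExpressionMatrix:
    """Read a TSV expression table into features x samples orientation.

    ``orientation`` is ``"features_in_rows"`` (default) or
    ``"samples_in_rows"``; in the latter case the table is transposed so the
    returned matrix is always features x samples.
    """
    if orientation not in ("features_in_rows", "samples_in_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if orientation == "samples_in_rows":
        df = df.T
    if df.index.has_duplicates:
        dupes = sorted(df.index[df.index.duplicated()].unique())
        raise IdentifierCollisionError(f"duplicate feature identifiers in {path}: {dupes}")
    if df.columns.has_duplicates:
        dupes = sorted(df.columns[df.columns.duplicated()].unique())
        raise IdentifierCollisionError(f"duplicate sample identifiers in {path}: {dupes}")
    try:
        values = df.to_numpy(dtype=float)
    except ValueError:
        for i, row in enumerate(df.itertuples(index=True)):
            for j, cell in enumerate(row[1:]):
                try:
                    float(cell)
                except (TypeError, ValueError):
                    raise ParseError(
                        f"non-numeric cell {cell!r} at feature {row[0]!r}, "
                        f"sample {df.columns[j]!r} in {path}"
                    ) from None
        raise  # pragma: no cover - unreachable, loop above locates the cell
    if not np.isfinite(values).all():
        i, j = np.argwhere(~np.isfinite(values))[0]
        raise ParseError(
            f"non-finite value at feature {df.index[i]!r}, sample {df.columns[j]!r} in {path}"
        )
    return ExpressionMatrix(list(df.index), list(df.columns), values)


def write_expression_matrix(m: ExpressionMatrix, path, float_format: str = "%.10g") -> None:
    m.to_frame().to_csv(path, sep="\t", float_format=float_format)


def preprocess_expression(m: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """log2(value + pseudocount), then per-feature standardization to mean 0, sd 1.

    The sd denominator is n (population convention); Pearson correlation is
    invariant to the choice. Zero-variance rows are set to 0 and flagged in
    ``constant_features`` so downstream correlation testing can skip them.
    """
    if m.processed:
        raise AlreadyProcessedError("matrix is already log-transformed and standardized")
    if pseudocount < 0:
        raise DomainError(f"pseudocount must be >= 0, got {pseudocount}")
    if (m.values < 0).any():
        i, j = np.argwhere(m.values < 0)[0]
        raise DomainError(
            f"negative expression value at feature {m.feature_ids[i]!r}, "
            f"sample {m.sample_ids[j]!r}; preprocessing expects raw abundances"
        )
    logged = np.log2(m.values + pseudocount)
    mu = logged.mean(axis=1, keepdims=True)
    sd = logged.std(axis=1, keepdims=True)  # population sd (ddof=0)
    constant = sd[:, 0] == 0.0
    sd[constant] = 1.0
    z = (logged - mu) / sd
    z[constant] = 0.0
    return ExpressionMatrix(
        list(m.feature_ids), list(m.sample_ids), z, processed=True, constant_features=constant
    )


def read_group_design(path, label_order=DEFAULT_LABEL_ORDER) -> GroupDesign:
    """Read the sample annotation TSV (columns sample_id, subtype, stage)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"sample_id", "subtype", "stage"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"annotation table {path} missing columns {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        dupes = sorted(df.loc[df["sample_id"].duplicated(), "sample_id"].unique())
        raise IdentifierCollisionError(f"duplicate sample identifiers in {path}: {dupes}")
    sample_ids = list(df["sample_id"])
    subtype_of = {s: v for s, v in zip(sample_ids, df["subtype"]) if v != ""}
    stage_of = {s: v for s, v in zip(sample_ids, df["stage"]) if v != ""}
    return GroupDesign(sample_ids, subtype_of, stage_of, tuple(label_order))


def write_group_design(design: GroupDesign, path) -> None:
    pd.DataFrame(
        {
            "sample_id": design.sample_ids,
            "subtype": [design.subtype_of.get(s, "") for s in design.sample_ids],
            "stage": [design.stage_of.get(s, "") for s in design.sample_ids],
        }
    ).to_csv(path, sep="\t", index=False)


def align_samples(
    mirna: ExpressionMatrix, mrna: ExpressionMatrix, design: GroupDesign
) -> tuple[ExpressionMatrix, ExpressionMatrix, GroupDesign]:
    """Restrict all three objects to the shared sample IDs, in a common order.

    Column order follows the miRNA matrix; the correlation machinery needs
    sample-matched columns in both matrices.
    """
    shared = set(mirna.sample_ids) & set(mrna.sample_ids) & set(design.sample_ids)
    if not shared:
        raise AlignmentError("no sample IDs shared between miRNA, mRNA and annotations")
    order = [s for s in mirna.sample_ids if s in shared]
    return mirna.subset_samples(order), mrna.subset_samples(order), design.subset(order)


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Merge a JSON config file and overrides onto the defaults."""
    cfg = {k: (list(v) if isinstance(v, list) else v) for k, v in DEFAULT_CONFIG.items()}
    if path is not None:
        with open(path) as fh:
            user = json.load(fh)
        unknown = set(user) - set(cfg)
        if unknown:
            raise ParseError(f"unknown config keys: {sorted(unknown)}")
        cfg.update(user)
    if overrides:
        cfg.update(overrides)
    return cfg
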