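"""Differential miRNA-target correlation (dysregulation) testing.

A miRNA-target pair is *dysregulated* between sample groups A and B when its
Pearson correlation differs significantly between the groups. Significance
uses Fisher's z-transformation:

    z = atanh(r),   z_AB = (z_A - z_B) / sqrt(1/(n_A-3) + 1/(n_B-3))

with a two-tailed normal p-value. A slower permutation test (re-splitting the
pooled samples and recomputing |r_A - r_B|) is provided as the exact
reference the z-approximation is checked against.

Because miRNAs repress their targets, a pair only counts as a candidate
dysregulation when it is negatively correlated in at least one of the two
groups (the inverse-correlation prerequisite). Significant, eligible pairs
across all pairwise subtype analyses are assembled into the binary
association matrix A whose rows are the miRNA "dysregulated target" profiles
used to build the synergism network.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats

from .errors import ConstantVectorError, GroupSizeError
from .io import ExpressionMatrix, GroupDesign

logger = logging.getLogger(__name__)

#: |r| is clipped here before atanh to keep perfect correlations finite.
_R_CLIP = 1.0 - 1e-15


def pearson_correlation(x, y) -> float:
    """Sample Pearson correlation of two equal-length vectors.

    Raises ConstantVectorError for zero-variance input; callers treat such
    pairs as untestable and skip them.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if x.size < 2:
        raise ValueError("correlation needs at least 2 observations")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt(xc @ xc)
    sy = np.sqrt(yc @ yc)
    if sx == 0.0 or sy == 0.0:
        raise ConstantVectorError("correlation undefined for a constant vector")
    return float(np.clip((xc @ yc) / (sx * sy), -1.0, 1.0))


def fisher_z(r: float) -> float:
    """Fisher's variance-stabilizing transform z = 0.5*ln((1+r)/(1-r)) = atanh(r).

    |r| is clipped just below 1 so degenerate perfect correlations stay finite.
    """
    r = np.clip(r, -_R_CLIP, _R_CLIP)
    return float(np.arctanh(r))


def correlation_difference_test(x_a, y_a, x_b, y_b) -> tuple[float, float]:
    """z-statistic and two-tailed p for a change in correlation between groups.

    Returns (z_AB, p) where p = 2*(1 - Phi(|z_AB|)). Both groups need at
    least 4 samples for the 1/(n-3) variance terms.
    """
    n_a, n_b = len(x_a), len(x_b)
    if n_a < 4 or n_b < 4:
        raise GroupSizeError(f"group sizes ({n_a}, {n_b}) must both be >= 4")
    r_a = pearson_correlation(x_a, y_a)
    r_b = pearson_correlation(x_b, y_b)
    return _fisher_z_test(r_a, r_b, n_a, n_b)


def _fisher_z_test(r_a: float, r_b: float, n_a: int, n_b: int) -> tuple[float, float]:
    se = np.sqrt(1.0 / (n_a - 3) + 1.0 / (n_b - 3))
    z_ab = (fisher_z(r_a) - fisher_z(r_b)) / se
    p = float(2.0 * stats.norm.sf(abs(z_ab)))
    return float(z_ab), p


def permutation_difference_test(x_a, y_a, x_b, y_b, n_perm: int = 10_000, seed: int = 0) -> float:
    """Permutation reference for the correlation-difference test.

    Pools the (x, y) sample pairs of both groups, re-splits them into groups
    of the original sizes n_perm times, and recomputes |Dys| = |r_A - r_B|
    for each split. Uses the add-one estimator
    p = (1 + #{|Dys_perm| >= |Dys_obs|}) / (1 + n_perm) so p is never 0.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    x_a = np.asarray(x_a, float)
    y_a = np.asarray(y_a, float)
    x_b = np.asarray(x_b, float)
    y_b = np.asarray(y_b, float)
    n_a = x_a.size
    obs = abs(pearson_correlation(x_a, y_a) - pearson_correlation(x_b, y_b))

    x = np.concatenate([x_a, x_b])
    y = np.concatenate([y_a, y_b])
    rng = np.random.default_rng(seed)
    # n_perm independent permutations of the pooled sample indices, as rows
    perms = np.argsort(rng.random((n_perm, x.size)), axis=1)
    xp, yp = x[perms], y[perms]
    r_a = _rowwise_corr(xp[:, :n_a], yp[:, :n_a])
    r_b = _rowwise_corr(xp[:, n_a:], yp[:, n_a:])
    dys = np.abs(r_a - r_b)
    return float((1 + int((dys >= obs - 1e-12).sum())) / (1 + n_perm))


def _rowwise_corr(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson correlation of corresponding rows of two 2-D arrays."""
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    num = (xc * yc).sum(axis=1)
    den = np.sqrt((xc**2).sum(axis=1) * (yc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = num / den
    return np.clip(np.nan_to_num(r), -1.0, 1.0)


@dataclass
class AssociationMatrix:
    """Binary miRNA x (target, analysis) dysregulation indicator matrix.

    ``columns`` lists (mrna_id, analysis_id) pairs; blocks from independent
    pairwise-subtype analyses are concatenated in lexicographic analysis
    order. ``A[i, j] == 1`` iff the pair passed ``p < p_threshold`` and, when
    the prerequisite is enabled, was negatively correlated in at least one
    group of that analysis.
    """

    mirna_ids: list[str]
    columns: list[tuple[str, str]]
    A: np.ndarray
    p_threshold: float
    analysis_ids: list[str]
    counts_by_analysis: dict[str, int]
    n_skipped_constant: int = 0

    def __post_init__(self):
        self.A = np.asarray(self.A)
        if self.A.shape != (len(self.mirna_ids), len(self.columns)):
            raise ValueError("A shape does not match mirna_ids x columns")
        if not np.isin(self.A, (0, 1)).all():
            raise ValueError("A must be binary")

    @property
    def total_dysregulations(self) -> int:
        return int(self.A.sum())


def _group_standardized(values: np.ndarray, cols: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rows standardized within the sample subset; flags zero-variance rows."""
    sub = values[:, cols]
    sub = sub - sub.mean(axis=1, keepdims=True)
    norm = np.sqrt((sub**2).sum(axis=1))
    constant = norm == 0.0
    norm[constant] = 1.0
    return sub / norm[:, None], constant


def analysis_id_for(subtype_a: str, subtype_b: str) -> str:
    """Canonical analysis name: unordered pair, lexicographically sorted."""
    a, b = sorted((subtype_a, subtype_b))
    return f"{a}_vs_{b}"


def dysregulation_analysis(
    mirna: ExpressionMatrix,
    mrna: ExpressionMatrix,
    cols_a: np.ndarray,
    cols_b: np.ndarray,
) -> dict[str, np.ndarray]:
    """Test all miRNA x mRNA pairs for correlation change between two groups.

    Returns dense matrices ``r_a``, ``r_b``, ``z``, ``p`` (miRNA x mRNA) and
    ``testable`` marking pairs where neither vector was constant in either
    group. Vectorized: within-group correlation matrices are products of
    group-standardized expression rows.
    """
    n_a, n_b = len(cols_a), len(cols_b)
    if n_a < 4 or n_b < 4:
        raise GroupSizeError(f"group sizes ({n_a}, {n_b}) must both be >= 4")
    xa, xa_const = _group_standardized(mirna.values, cols_a)
    ya, ya_const = _group_standardized(mrna.values, cols_a)
    xb, xb_const = _group_standardized(mirna.values, cols_b)
    yb, yb_const = _group_standardized(mrna.values, cols_b)
    r_a = np.clip(xa @ ya.T, -1.0, 1.0)
    r_b = np.clip(xb @ yb.T, -1.0, 1.0)
    se = np.sqrt(1.0 / (n_a - 3) + 1.0 / (n_b - 3))
    z = (np.arctanh(np.clip(r_a, -_R_CLIP, _R_CLIP)) - np.arctanh(np.clip(r_b, -_R_CLIP, _R_CLIP))) / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    testable = ~(
        (xa_const | xb_const)[:, None] | (ya_const | yb_const)[None, :]
    )
    return {"r_a": r_a, "r_b": r_b, "z": z, "p": p, "testable": testable}


def run_pairwise_analyses(
    mirna: ExpressionMatrix,
    mrna: ExpressionMatrix,
    design: GroupDesign,
    subtypes: list[str] | None = None,
    p_threshold: float = 0.001,
    require_negative: bool = True,
) -> AssociationMatrix:
    """Dysregulation analysis for every unordered pair of subtypes.

    For each of the C(k, 2) subtype pairs, every miRNA x mRNA combination is
    tested (no target-prediction pre-filter); a pair enters the association
    matrix when p < p_threshold and, if ``require_negative``, r_A < 0 or
    r_B < 0. Subtypes with fewer than 4 samples are skipped with a warning.
    """
    groups = design.subtype_groups()
    if subtypes is None:
        subtypes = sorted(groups)
    usable = []
    for s in subtypes:
        n = len(groups.get(s, ()))
        if n < 4:
            logger.warning("subtype %r has %d samples (< 4); excluded from analysis", s, n)
        else:
            usable.append(s)
    if len(usable) < 2:
        raise GroupSizeError("need at least two subtypes with >= 4 samples")

    col_index = {s: i for i, s in enumerate(mirna.sample_ids)}
    if mirna.sample_ids != mrna.sample_ids:
        raise ValueError("matrices are not sample-aligned; call align_samples first")

    analyses = sorted(analysis_id_for(a, b) for a, b in combinations(usable, 2))
    by_id = {analysis_id_for(a, b): (a, b) for a, b in combinations(usable, 2)}

    blocks, columns, counts = [], [], {}
    n_skipped = 0
    for aid in analyses:
        a, b = sorted(by_id[aid])
        cols_a = np.array([col_index[s] for s in groups[a]])
        cols_b = np.array([col_index[s] for s in groups[b]])
        res = dysregulation_analysis(mirna, mrna, cols_a, cols_b)
        hit = (res["p"] < p_threshold) & res["testable"]
        if require_negative:
            hit &= (res["r_a"] < 0) | (res["r_b"] < 0)
        n_skipped += int((~res["testable"]).sum())
        blocks.append(hit.astype(np.uint8))
        columns.extend((g, aid) for g in mrna.feature_ids)
        counts[aid] = int(hit.sum())
        logger.info("analysis %s: %d dysregulations", aid, counts[aid])
    A = np.concatenate(blocks, axis=1)
    logger.info("total dysregulations across %d analyses: %d", len(analyses), int(A.sum()))
    return AssociationMatrix(
        mirna_ids=list(mirna.feature_ids),
        columns=columns,
        A=A,
        p_threshold=p_threshold,
        analysis_ids=analyses,
        counts_by_analysis=counts,
        n_skipped_constant=n_skipped,
    )
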