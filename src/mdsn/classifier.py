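"""Sparse Group Lasso logistic classification of cancer stage over miRNA modules.

One-vs-rest binary logistic models with the composite penalty

    lambda * alpha * ||w||_1  +  lambda * (1 - alpha) * sum_g sqrt(|g|) * ||w_g||_2

where the groups g are the extracted miRNA modules (features outside every
module become singleton groups). The loss is the mean logistic loss with
labels in {-1, +1}; the intercept is unpenalized. Optimization is FISTA with
backtracking line search and adaptive restart; the proximal operator of the
penalty is exact: coordinate soft-threshold at step*lambda*alpha followed by
group-wise block soft-threshold at step*lambda*(1-alpha)*sqrt(|g|).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .communities import ModulePartition
from .errors import DegenerateLabelError, StratificationError

logger = logging.getLogger(__name__)


@dataclass
class GroupStructure:
    """Disjoint feature-index groups covering all features, weighted by sqrt(|g|)."""

    groups: list[np.ndarray]
    n_features: int
    weights: np.ndarray = field(init=False)

    def __post_init__(self):
        self.groups = [np.asarray(g, dtype=int) for g in self.groups]
        seen: set[int] = set()
        for g in self.groups:
            if len(g) == 0:
                raise ValueError("empty group")
            gset = set(g.tolist())
            if seen & gset:
                raise ValueError(f"overlapping groups at features {sorted(seen & gset)[:5]}")
            seen |= gset
        uncovered = sorted(set(range(self.n_features)) - seen)
        if max(seen, default=-1) >= self.n_features:
            raise ValueError("group index out of range")
        # singleton groups for features no module claimed
        self.groups = self.groups + [np.array([j]) for j in uncovered]
        self.weights = np.sqrt(np.array([len(g) for g in self.groups], dtype=float))

    @classmethod
    def from_partition(cls, feature_ids: list[str], partition: ModulePartition) -> "GroupStructure":
        """Groups from a miRNA module assignment; unassigned features -> singletons."""
        by_module: dict[int, list[int]] = {}
        index = {f: i for i, f in enumerate(feature_ids)}
        for node, m in partition.assignment.items():
            if node in index:
                by_module.setdefault(m, []).append(index[node])
        groups = [np.array(sorted(v)) for _, v in sorted(by_module.items())]
        return cls(groups=groups, n_features=len(feature_ids))

    @classmethod
    def singletons(cls, n_features: int) -> "GroupStructure":
        return cls(groups=[], n_features=n_features)


def group_lasso_penalty(w: np.ndarray, groups: GroupStructure) -> float:
    """GL(w) = sum_g sqrt(|g|) * ||w_g||_2."""
    return float(sum(wt * np.linalg.norm(w[g]) for g, wt in zip(groups.groups, groups.weights)))


def sgl_penalty(w: np.ndarray, lam: float, alpha: float, groups: GroupStructure) -> float:
    return lam * alpha * float(np.abs(w).sum()) + lam * (1 - alpha) * group_lasso_penalty(w, groups)


def _logistic_loss(margins: np.ndarray) -> float:
    # mean log(1 + exp(-m)), stable for large |m|
    return float(np.logaddexp(0.0, -margins).mean())


def sgl_objective(
    w: np.ndarray,
    intercept: float,
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    alpha: float,
    groups: GroupStructure,
) -> float:
    """Mean logistic loss + sparse-group penalty; intercept unpenalized."""
    X = np.asarray(X, float)
    w = np.asarray(w, float)
    y = np.asarray(y, float)
    if X.shape[1] != w.size or X.shape[0] != y.size:
        raise ValueError(
            f"shape mismatch: X {X.shape}, w {w.shape}, y {y.shape}"
        )
    if not np.isin(y, (-1.0, 1.0)).all():
        raise ValueError("labels must be in {-1, +1}")
    margins = y * (X @ w + intercept)
    return _logistic_loss(margins) + sgl_penalty(w, lam, alpha, groups)


def sgl_prox(v: np.ndarray, step: float, lam: float, alpha: float, groups: GroupStructure) -> np.ndarray:
    """Exact prox of the sparse-group-lasso penalty at step size ``step``.

    argmin_w 0.5*||w - v||^2 + step*[lam*alpha*||w||_1
                                     + lam*(1-alpha)*sum_g sqrt(|g|)*||w_g||_2]

    computed as soft-thresholding at step*lam*alpha followed by per-group
    block soft-thresholding at step*lam*(1-alpha)*sqrt(|g|) — the known
    closed form for this composite penalty.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    v = np.asarray(v, float)
    w = np.sign(v) * np.maximum(np.abs(v) - step * lam * alpha, 0.0)
    out = w.copy()
    for g, wt in zip(groups.groups, groups.weights):
        norm = np.linalg.norm(w[g])
        thr = step * lam * (1 - alpha) * wt
        if norm <= thr:
            out[g] = 0.0
        elif thr > 0:
            out[g] = w[g] * (1.0 - thr / norm)
    return out


def _loss_and_grad(w, intercept, X, y):
    margins = y * (X @ w + intercept)
    loss = _logistic_loss(margins)
    # d/dm log(1+e^-m) = -sigmoid(-m)
    s = -1.0 / (1.0 + np.exp(margins)) * y / y.size
    return loss, X.T @ s, float(s.sum())


def fit_sgl_binary(
    X: np.ndarray,
    y: np.ndarray,
    groups: GroupStructure,
    lam: float,
    alpha: float,
    max_iter: int = 10_000,
    tol: float = 1e-6,
    fit_intercept: bool = True,
):
    """FISTA with backtracking and adaptive restart for one +-1 logistic problem.

    Returns (w, intercept, history) where history is the recorded objective
    per iteration (non-increasing thanks to the restart scheme).
    """
    n, d = X.shape
    w = np.zeros(d)
    b = 0.0
    zw, zb = w.copy(), b  # extrapolation point
    t = 1.0
    step = 1.0
    obj = sgl_objective(w, b, X, y, lam, alpha, groups)
    history = [obj]
    for it in range(max_iter):
        loss_z, grad_w, grad_b = _loss_and_grad(zw, zb, X, y)
        # backtracking on the smooth part
        while True:
            w_new = sgl_prox(zw - step * grad_w, step, lam, alpha, groups)
            b_new = zb - step * grad_b if fit_intercept else 0.0
            dw, db = w_new - zw, b_new - zb
            loss_new = _logistic_loss(y * (X @ w_new + b_new))
            quad = loss_z + grad_w @ dw + grad_b * db + (dw @ dw + db * db) / (2 * step)
            if loss_new <= quad + 1e-12:
                break
            step *= 0.5
            if step < 1e-12:
                break
        obj_new = loss_new + sgl_penalty(w_new, lam, alpha, groups)
        if obj_new > obj:  # adaptive restart: fall back to plain prox step
            zw, zb, t = w.copy(), b, 1.0
            loss_z, grad_w, grad_b = _loss_and_grad(zw, zb, X, y)
            w_new = sgl_prox(zw - step * grad_w, step, lam, alpha, groups)
            b_new = zb - step * grad_b if fit_intercept else 0.0
            obj_new = sgl_objective(w_new, b_new, X, y, lam, alpha, groups)
            if obj_new > obj:  # no descent possible at this step size
                history.append(obj)
                break
        t_new = (1 + np.sqrt(1 + 4 * t * t)) / 2
        zw = w_new + ((t - 1) / t_new) * (w_new - w)
        zb = b_new + ((t - 1) / t_new) * (b_new - b)
        w, b, t = w_new, b_new, t_new
        history.append(obj_new)
        if obj - obj_new < tol * max(1.0, abs(obj)):
            obj = obj_new
            break
        obj = obj_new
        step *= 1.1  # gentle step growth; backtracking re-shrinks if needed
    else:
        warnings.warn(
            f"SGL solver hit max_iter={max_iter} (last change "
            f"{history[-2] - history[-1]:.2e}); returning current iterate",
            RuntimeWarning,
        )
    return w, b, np.array(history)


@dataclass
class SGLModel:
    """One-vs-rest sparse-group-lasso logistic model over miRNA features."""

    W: np.ndarray  # (k classes, d features)
    intercepts: np.ndarray
    lam: float
    alpha: float
    groups: GroupStructure
    class_labels: list[str]
    feature_ids: list[str]
    histories: list[np.ndarray] = field(default_factory=list)

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, float) @ self.W.T + self.intercepts

    def predict(self, X: np.ndarray) -> list[str]:
        scores = self.decision_function(X)
        return [self.class_labels[i] for i in scores.argmax(axis=1)]

    @property
    def n_candidates(self) -> int:
        return int((np.abs(self.W).max(axis=0) > 0).sum())

    def to_json(self, path=None) -> str:
        payload = {
            "class_labels": self.class_labels,
            "lambda": self.lam,
            "alpha": self.alpha,
            "feature_ids": self.feature_ids,
            "groups": [g.tolist() for g in self.groups.groups],
            "intercepts": [round(float(v), 12) for v in self.intercepts],
            "coefficients": {
                label: {
                    self.feature_ids[j]: round(float(self.W[c, j]), 12)
                    for j in np.flatnonzero(self.W[c])
                }
                for c, label in enumerate(self.class_labels)
            },
        }
        text = json.dumps(payload, indent=1, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def fit_sgl_logistic(
    X: np.ndarray,
    labels,
    groups: GroupStructure,
    lam: float = 1.0,
    alpha: float = 0.5,
    max_iter: int = 10_000,
    tol: float = 1e-6,
    feature_ids: list[str] | None = None,
    class_order: list[str] | None = None,
) -> SGLModel:
    """One-vs-rest SGL logistic fit; one +-1 binary problem per class label."""
    X = np.asarray(X, float)
    labels = np.asarray([str(l) for l in labels])
    present = sorted(set(labels))
    if class_order is not None:
        present = [c for c in class_order if c in present]
    if len(present) < 2:
        raise DegenerateLabelError(f"need >= 2 classes, got {present}")
    if feature_ids is None:
        feature_ids = [f"f{j}" for j in range(X.shape[1])]
    W = np.zeros((len(present), X.shape[1]))
    intercepts = np.zeros(len(present))
    histories = []
    for c, label in enumerate(present):
        y = np.where(labels == label, 1.0, -1.0)
        w, b, hist = fit_sgl_binary(X, y, groups, lam, alpha, max_iter, tol)
        W[c], intercepts[c] = w, b
        histories.append(hist)
    return SGLModel(W, intercepts, lam, alpha, groups, present, list(feature_ids), histories)


def roc_auc_per_class(model: SGLModel, X_test: np.ndarray, labels_test) -> dict[str, float]:
    """One-vs-rest AUROC per class from the class decision values.

    Classes absent from the test set (or with no negatives) map to NaN.
    """
    labels_test = np.asarray([str(l) for l in labels_test])
    scores = model.decision_function(X_test)
    out = {}
    for c, label in enumerate(model.class_labels):
        pos = labels_test == label
        if pos.all() or not pos.any():
            out[label] = float("nan")
            continue
        out[label] = float(roc_auc_score(pos.astype(int), scores[:, c]))
    return out


def macro_auroc(model: SGLModel, X_test, labels_test) -> float:
    per_class = roc_auc_per_class(model, X_test, labels_test)
    vals = [v for v in per_class.values() if not np.isnan(v)]
    return float(np.mean(vals)) if vals else float("nan")


def cross_validate(
    X: np.ndarray,
    labels,
    groups: GroupStructure,
    lambda_grid,
    alpha_grid,
    n_folds: int = 5,
    seed: int = 0,
    max_iter: int = 2_000,
    tol: float = 1e-6,
):
    """Grid search maximizing mean one-vs-rest macro-AUROC over stratified folds.

    Returns (best_lambda, best_alpha, table) where ``table`` has one row per
    (lambda, alpha, fold). Deterministic given ``seed``.
    """
    labels = np.asarray([str(l) for l in labels])
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    counts = pd.Series(labels).value_counts()
    if (counts < n_folds).any():
        raise StratificationError(
            f"classes {list(counts[counts < n_folds].index)} have fewer samples than folds"
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    rows = []
    for lam in lambda_grid:
        for alpha in alpha_grid:
            for fold, (tr, te) in enumerate(skf.split(X, labels)):
                if len(set(labels[te])) < 2 or len(set(labels[tr])) < 2:
                    raise StratificationError(f"fold {fold} is missing a class")
                model = fit_sgl_logistic(
                    X[tr], labels[tr], groups, lam, alpha, max_iter=max_iter, tol=tol
                )
                rows.append(
                    {
                        "lambda": lam,
                        "alpha": alpha,
                        "fold": fold,
                        "macro_auroc": macro_auroc(model, X[te], labels[te]),
                    }
                )
    table = pd.DataFrame(rows)
    means = table.groupby(["lambda", "alpha"])["macro_auroc"].mean()
    best_lam, best_alpha = means.idxmax()
    return float(best_lam), float(best_alpha), table


def rank_and_evaluate_biomarkers(
    model: SGLModel, known_set: set, k_list=(10, 25, 50, 100)
) -> pd.DataFrame:
    """Precision/recall of top-|coefficient| candidate features against a known set.

    Candidates are the features with any nonzero coefficient; the ranking
    score is the maximum |coefficient| across classes (for a binary
    tumor-vs-normal model both classes carry mirrored weights, so this
    equals the single binary profile). For each k: precision =
    |top-k ∩ known| / k, recall = |top-k ∩ known| / |known|.
    """
    if not known_set:
        raise ValueError("known_set must be non-empty")
    score = np.abs(model.W).max(axis=0)
    candidates = np.flatnonzero(score > 0)
    # stable ranking: descending score, feature ID as tie-break
    order = sorted(candidates, key=lambda j: (-score[j], model.feature_ids[j]))
    ranked = [model.feature_ids[j] for j in order]
    rows = []
    for k in k_list:
        kk = int(k)
        if kk > len(ranked):
            logger.warning("k=%d exceeds %d candidates; truncated", kk, len(ranked))
            kk = len(ranked)
        top = set(ranked[:kk])
        hits = len(top & set(known_set))
        rows.append(
            {
                "k": kk,
                "precision": hits / kk if kk else float("nan"),
                "recall": hits / len(known_set),
            }
        )
    return pd.DataFrame(rows)


def write_biomarkers(model: SGLModel, known_set: set, path) -> None:
    """Ranked-biomarker TSV: rank, feature_id, coefficient, known_flag."""
    score = np.abs(model.W).max(axis=0)
    candidates = np.flatnonzero(score > 0)
    order = sorted(candidates, key=lambda j: (-score[j], model.feature_ids[j]))
    pd.DataFrame(
        {
            "rank": np.arange(1, len(order) + 1),
            "feature_id": [model.feature_ids[j] for j in order],
            "coefficient": [score[j] for j in order],
            "known_flag": [int(model.feature_ids[j] in known_set) for j in order],
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.10g")
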