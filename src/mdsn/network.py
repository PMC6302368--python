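"""MiRNA-miRNA dysregulational synergism network (MDSN) construction.

Two miRNAs are functionally synergistic when they dysregulate overlapping
target sets; the edge weight is the cosine similarity of their binary
association-matrix rows, optionally raised to a power beta (WGCNA-style,
beta = 1 by default). The dense network is pruned with a hard threshold
chosen as the least stringent grid value at which the degree distribution
still looks scale-free, quantified by the squared log-log correlation

    R^2 = corr(log10(k), log10(p(k)))^2

over a histogram of node degrees (or, in ``mode="score"``, of the surviving
similarity scores).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .dysregulation import AssociationMatrix
from .errors import DegenerateNetworkError, FitUndefinedError, ThresholdSelectionError

logger = logging.getLogger(__name__)


def cosine_similarity(a, b) -> float:
    """Cosine similarity of two vectors; 0 by convention when either norm is 0."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("vectors must have equal length")
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        return 0.0
    return float(a @ b / (na * nb))


@dataclass
class SimilarityNetwork:
    """Weighted miRNA-miRNA graph with threshold state and fit diagnostics."""

    node_ids: list[str]
    M: np.ndarray
    beta: float = 1.0
    threshold: float | None = None
    r2_by_threshold: dict[float, float] = field(default_factory=dict)
    n_nonisolated: int | None = None
    dropped_nodes: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.M = np.asarray(self.M, dtype=float)
        n = len(self.node_ids)
        if self.M.shape != (n, n):
            raise ValueError("M must be square over node_ids")
        if not np.allclose(self.M, self.M.T):
            raise ValueError("M must be symmetric")
        if (np.diag(self.M) != 0).any():
            raise ValueError("M must have zero diagonal")
        if self.M.size and (self.M.min() < -1e-12 or self.M.max() > 1 + 1e-12):
            raise ValueError("edge weights must lie in [0, 1]")

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    def degrees(self, threshold: float = 0.0) -> np.ndarray:
        """Unweighted node degrees counting edges with weight >= threshold."""
        adj = (self.M >= max(threshold, np.finfo(float).tiny)) & (self.M > 0)
        return adj.sum(axis=1)

    def edge_weights(self, threshold: float = 0.0) -> np.ndarray:
        """Upper-triangle edge weights surviving the threshold."""
        iu = np.triu_indices(self.n_nodes, k=1)
        w = self.M[iu]
        return w[(w > 0) & (w >= threshold)]

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.node_ids)
        iu, ju = np.triu_indices(self.n_nodes, k=1)
        mask = self.M[iu, ju] > 0
        g.add_weighted_edges_from(
            (self.node_ids[i], self.node_ids[j], float(self.M[i, j]))
            for i, j in zip(iu[mask], ju[mask])
        )
        return g


def build_similarity_network(A: AssociationMatrix, beta: float = 1.0) -> SimilarityNetwork:
    """Cosine-similarity network over miRNAs with at least one dysregulation.

    M_pq = s(p, q)^beta for p != q; miRNAs whose association row is all zero
    never dysregulated anything and are excluded from the node set.
    """
    if beta <= 0:
        raise ValueError("beta must be positive")
    mat = A.A.astype(float)
    nonzero = mat.sum(axis=1) > 0
    if int(nonzero.sum()) < 2:
        raise DegenerateNetworkError(
            f"only {int(nonzero.sum())} miRNA(s) with any dysregulated target"
        )
    node_ids = [m for m, keep in zip(A.mirna_ids, nonzero) if keep]
    dropped = [m for m, keep in zip(A.mirna_ids, nonzero) if not keep]
    rows = mat[nonzero]
    rows = rows / np.linalg.norm(rows, axis=1, keepdims=True)
    M = np.clip(rows @ rows.T, 0.0, 1.0) ** beta
    np.fill_diagonal(M, 0.0)
    M = (M + M.T) / 2.0  # exact symmetry against float noise
    logger.info(
        "similarity network: %d nodes, %d pair scores (%d all-zero miRNAs dropped)",
        len(node_ids), len(node_ids) * (len(node_ids) - 1) // 2, len(dropped),
    )
    return SimilarityNetwork(node_ids=node_ids, M=M, beta=beta, dropped_nodes=dropped)


def _log_binned_fit(values: np.ndarray, n_bins: int) -> float:
    """Squared Pearson correlation of log10(bin center) vs log10(frequency).

    Equal-width bins in log10 space, empty bins dropped, centers at the
    arithmetic midpoint of the log-space bin edges.
    """
    values = np.asarray(values, dtype=float)
    values = values[values > 0]
    if values.size == 0:
        raise FitUndefinedError("no positive values to bin")
    logv = np.log10(values)
    lo, hi = logv.min(), logv.max()
    if hi - lo <= 0:
        raise FitUndefinedError("all values identical; single bin")
    edges = np.linspace(lo, hi, n_bins + 1)
    counts, _ = np.histogram(logv, bins=edges)
    centers = (edges[:-1] + edges[1:]) / 2.0
    keep = counts > 0
    if int(keep.sum()) < 3:
        raise FitUndefinedError(f"only {int(keep.sum())} non-empty bins (< 3)")
    freq = counts[keep] / counts.sum()
    r = np.corrcoef(centers[keep], np.log10(freq))[0, 1]
    return float(r**2)


def scale_free_fit(
    network: SimilarityNetwork, threshold: float = 0.0, n_bins: int = 10, mode: str = "degree"
) -> float:
    """Power-law fit score of the thresholded network, in [0, 1].

    ``mode="degree"`` bins the unweighted node degrees (degree-0 nodes are
    excluded: log10 undefined); ``mode="score"`` bins the surviving
    similarity scores. Raises FitUndefinedError when fewer than 3 histogram
    bins are occupied — callers treat that threshold as unusable.
    """
    if n_bins < 3:
        raise ValueError("n_bins must be >= 3")
    if mode == "degree":
        values = network.degrees(threshold)
    elif mode == "score":
        values = network.edge_weights(threshold)
    else:
        raise ValueError(f"unknown fit mode {mode!r}")
    if values.size == 0 or not (values > 0).any():
        raise FitUndefinedError("thresholded network is empty")
    # squared correlation exactly as defined: a positive log-log slope also
    # scores high; downstream diagnostics (threshold_curve) expose the raw
    # histogram so such fits can be inspected
    return _log_binned_fit(values, n_bins)


def fit_from_degree_sequence(degrees, n_bins: int = 10) -> float:
    """Scale-free fit score of a raw degree sequence (diagnostic helper)."""
    return _log_binned_fit(np.asarray(degrees, dtype=float), n_bins)


def threshold_curve(
    network: SimilarityNetwork, grid, n_bins: int = 10
) -> pd.DataFrame:
    """Fit scores and network sizes along the threshold grid (diagnostic table)."""
    rows = []
    for t in grid:
        row = {"threshold": float(t)}
        for mode in ("degree", "score"):
            try:
                row[f"r2_{mode}"] = scale_free_fit(network, t, n_bins, mode)
            except FitUndefinedError:
                row[f"r2_{mode}"] = np.nan
        deg = network.degrees(t)
        row["n_edges"] = int(deg.sum() // 2)
        row["n_nonisolated"] = int((deg > 0).sum())
        rows.append(row)
    return pd.DataFrame(rows)


def select_threshold(
    network: SimilarityNetwork,
    grid=None,
    r2_min: float = 0.8,
    n_bins: int = 10,
    mode: str = "degree",
) -> float:
    """Least stringent (smallest) grid threshold with fit score >= r2_min.

    Records the full threshold -> score curve on the network. Thresholds
    where the fit is undefined are skipped. Raises ThresholdSelectionError,
    reporting the best achieved score, when no grid value qualifies.
    """
    if grid is None:
        grid = [round(0.05 * i, 2) for i in range(1, 20)]
    grid = sorted(float(t) for t in grid)
    if not 0 < r2_min < 1:
        raise ValueError("r2_min must be in (0, 1)")
    best_t, best_score = None, -np.inf
    chosen = None
    for t in grid:
        try:
            score = scale_free_fit(network, t, n_bins, mode)
        except FitUndefinedError:
            network.r2_by_threshold[t] = float("nan")
            continue
        network.r2_by_threshold[t] = score
        if score > best_score:
            best_t, best_score = t, score
        if chosen is None and score >= r2_min:
            chosen = t
    if chosen is None:
        raise ThresholdSelectionError(
            f"no grid threshold reaches R^2 >= {r2_min}; "
            f"best was {best_score:.4f} at {best_t}",
            best_threshold=best_t,
            best_score=None if best_score == -np.inf else best_score,
        )
    logger.info("selected hard threshold %.3f (R^2 = %.4f)", chosen, network.r2_by_threshold[chosen])
    return chosen


def prune(network: SimilarityNetwork, threshold: float) -> SimilarityNetwork:
    """Drop edges below the hard threshold and remove isolated nodes."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must lie in [0, 1], got {threshold}")
    M = network.M.copy()
    M[M < threshold] = 0.0
    keep = (M > 0).any(axis=1)
    dropped = [n for n, k in zip(network.node_ids, keep) if not k]
    M = M[np.ix_(keep, keep)]
    node_ids = [n for n, k in zip(network.node_ids, keep) if k]
    return SimilarityNetwork(
        node_ids=node_ids,
        M=M,
        beta=network.beta,
        threshold=threshold,
        r2_by_threshold=dict(network.r2_by_threshold),
        n_nonisolated=len(node_ids),
        dropped_nodes=list(network.dropped_nodes) + dropped,
    )


def write_edge_list(network: SimilarityNetwork, path) -> None:
    """Weighted edge list TSV: node_a, node_b, weight (upper triangle)."""
    iu, ju = np.triu_indices(network.n_nodes, k=1)
    mask = network.M[iu, ju] > 0
    pd.DataFrame(
        {
            "node_a": [network.node_ids[i] for i in iu[mask]],
            "node_b": [network.node_ids[j] for j in ju[mask]],
            "weight": network.M[iu[mask], ju[mask]],
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_graphml(network: SimilarityNetwork, path) -> None:
    nx.write_graphml(network.to_networkx(), path)
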