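"""MiRNA module extraction by Louvain modularity clustering, plus NMI comparison.

Modules are communities of the pruned synergism network under the weighted
modularity objective

    Q = (1/2m) * sum_pq [ M_pq - k_p k_q / 2m ] * delta(c_p, c_q)

with k the weighted degree and m the total edge weight. The Louvain
hierarchy is recorded and the level with the highest modularity is returned.
Agreement between module assignments from independent analyses is measured
with normalized mutual information (arithmetic-mean normalization) on the
shared node set.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from networkx.algorithms.community import louvain_partitions
from sklearn.metrics import normalized_mutual_info_score

from .errors import ComparisonError, CoverageError
from .network import SimilarityNetwork


@dataclass
class ModulePartition:
    """Node -> module assignment with its modularity and the Louvain hierarchy."""

    assignment: dict[str, int]
    modularity: float = float("nan")
    levels: list[dict[str, int]] = field(default_factory=list)
    seed: int | None = None

    @property
    def n_modules(self) -> int:
        return len(set(self.assignment.values()))

    def members(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for node, c in self.assignment.items():
            out.setdefault(c, []).append(node)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"mirna_id": list(self.assignment), "module_index": list(self.assignment.values())}
        )


def _as_graph(graph) -> nx.Graph:
    if isinstance(graph, SimilarityNetwork):
        return graph.to_networkx()
    return graph


def modularity(graph, assignment: dict[str, int]) -> float:
    """Weighted modularity of a partition (independent of networkx's own).

    Q = (1/2m) sum over same-community pairs of [w_pq - k_p k_q / 2m],
    computed community-by-community as sum_c (w_in_c/m_tot - (k_c/2m)^2)
    where w_in_c counts each internal undirected edge once.
    """
    g = _as_graph(graph)
    missing = set(g.nodes) - set(assignment)
    if missing:
        raise CoverageError(f"partition missing {len(missing)} node(s), e.g. {sorted(missing)[:3]}")
    two_m = sum(d for _, d in g.degree(weight="weight"))
    if two_m == 0:
        return 0.0
    q = 0.0
    communities: dict[int, set] = {}
    for node, c in assignment.items():
        if node in g:
            communities.setdefault(c, set()).add(node)
    for members in communities.values():
        w_in = sum(d.get("weight", 1.0) for u, v, d in g.edges(members, data=True) if v in members and u in members)
        k_c = sum(d for _, d in g.degree(members, weight="weight"))
        q += 2.0 * w_in / two_m - (k_c / two_m) ** 2
    return float(q)


def louvain(graph, seed: int = 0, resolution: float = 1.0, restarts: int = 5) -> ModulePartition:
    """Two-phase greedy modularity optimization (Louvain) on a weighted graph.

    The greedy node-move phase depends on the node visit order, so the
    optimizer is run ``restarts`` times with visit orders derived
    deterministically from ``seed`` and the hierarchy level with the highest
    modularity across all runs is returned (coarser levels can beat the final
    one when the last aggregation pass over-merges). The recorded ``levels``
    are those of the winning run.
    """
    g = _as_graph(graph)
    if g.number_of_nodes() == 0:
        return ModulePartition(assignment={}, modularity=float("nan"), levels=[], seed=seed)
    if g.number_of_edges() == 0:
        assignment = {n: i for i, n in enumerate(g.nodes)}
        return ModulePartition(assignment, 0.0, [assignment], seed=seed)
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    best_levels, best_scores, best_idx = None, None, None
    for k in range(restarts):
        run_seed = (seed + 0x9E3779B1 * k) % (2**31)  # distinct, reproducible
        levels = []
        for communities in louvain_partitions(
            g, weight="weight", resolution=resolution, seed=run_seed
        ):
            level = {}
            for idx, members in enumerate(communities):
                for node in members:
                    level[node] = idx
            levels.append(level)
        scores = [modularity(g, level) for level in levels]
        i = int(np.argmax(scores))
        if best_scores is None or scores[i] > best_scores[best_idx] + 1e-15:
            best_levels, best_scores, best_idx = levels, scores, i
    return ModulePartition(
        assignment=best_levels[best_idx],
        modularity=best_scores[best_idx],
        levels=best_levels,
        seed=seed,
    )


def nmi(p1: ModulePartition, p2: ModulePartition) -> float:
    """Normalized mutual information between two module assignments.

    Computed on the intersection of the node sets with arithmetic-mean
    entropy normalization; label-permutation invariant, in [0, 1].
    """
    shared = sorted(set(p1.assignment) & set(p2.assignment))
    if not shared:
        raise ComparisonError("partitions share no nodes")
    l1 = [p1.assignment[n] for n in shared]
    l2 = [p2.assignment[n] for n in shared]
    return float(normalized_mutual_info_score(l1, l2, average_method="arithmetic"))


def module_consistency_matrix(partitions: dict[str, ModulePartition]) -> pd.DataFrame:
    """Pairwise NMI between module assignments from different analyses.

    Symmetric with unit diagonal; entries for partition pairs with no shared
    nodes are NaN (flagged missing).
    """
    if len(partitions) < 2:
        raise ValueError("need at least two partitions to compare")
    labels = list(partitions)
    mat = np.eye(len(labels))
    for (i, a), (j, b) in itertools.combinations(enumerate(labels), 2):
        try:
            v = nmi(partitions[a], partitions[b])
        except ComparisonError:
            v = np.nan
        mat[i, j] = mat[j, i] = v
    return pd.DataFrame(mat, index=labels, columns=labels)


def write_modules(partition: ModulePartition, path) -> None:
    """Module TSV: (mirna_id, module_index), sorted by module then ID."""
    df = partition.to_frame().sort_values(["module_index", "mirna_id"])
    df.to_csv(path, sep="\t", index=False)
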