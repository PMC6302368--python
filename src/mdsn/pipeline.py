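"""End-to-end orchestration: dysregulation -> MDSN -> modules -> SGL staging.

``run_pipeline`` wires the stages together with the default configuration
(p < 0.001, inverse-correlation prerequisite, beta = 1, R^2 > 0.8 hard
threshold, Louvain modules, SGL with the modules as groups) and returns all
intermediate objects. ``PipelineResult.write`` emits the deterministic text
outputs (module TSV, model JSON, evaluation tables).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .classifier import (
    GroupStructure,
    SGLModel,
    fit_sgl_logistic,
    roc_auc_per_class,
)
from .communities import ModulePartition, louvain, write_modules
from .dysregulation import AssociationMatrix, run_pairwise_analyses
from .errors import ThresholdSelectionError
from .io import DEFAULT_CONFIG, ExpressionMatrix, GroupDesign, align_samples
from .network import (
    SimilarityNetwork,
    build_similarity_network,
    prune,
    select_threshold,
    threshold_curve,
    write_edge_list,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    association: AssociationMatrix
    network: SimilarityNetwork
    threshold: float | None
    partition: ModulePartition
    model: SGLModel | None
    auroc_by_stage: dict[str, float] | None
    curve: pd.DataFrame

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_modules(self.partition, out / "modules.tsv")
        write_edge_list(self.network, out / "mdsn_edges.tsv")
        self.curve.to_csv(out / "threshold_curve.tsv", sep="\t", index=False, float_format="%.10g")
        if self.model is not None:
            self.model.to_json(out / "model.json")
        if self.auroc_by_stage is not None:
            pd.DataFrame(
                sorted(self.auroc_by_stage.items()), columns=["stage", "auroc"]
            ).to_csv(out / "auroc_by_stage.tsv", sep="\t", index=False, float_format="%.10g")


def stage_matrix(mirna: ExpressionMatrix, design: GroupDesign):
    """Samples x features matrix and stage labels for the classifier."""
    keep = [s for s in mirna.sample_ids if s in design.stage_of]
    idx = [mirna.sample_ids.index(s) for s in keep]
    X = mirna.values[:, idx].T
    y = np.array([design.stage_of[s] for s in keep])
    return X, y, keep


def holdout_split(labels, test_fraction: float = 0.2, seed: int = 0):
    """Stratified train/test index split, deterministic given the seed."""
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    train, test = [], []
    for label in sorted(set(labels)):
        idx = np.flatnonzero(labels == label)
        idx = idx[rng.permutation(idx.size)]
        n_test = max(1, int(round(test_fraction * idx.size)))
        test.extend(idx[:n_test])
        train.extend(idx[n_test:])
    return np.sort(np.array(train)), np.sort(np.array(test))


def run_pipeline(
    mirna: ExpressionMatrix,
    mrna: ExpressionMatrix,
    design: GroupDesign,
    subtypes: list[str] | None = None,
    config: dict | None = None,
    classify: bool = True,
    test_fraction: float = 0.2,
) -> PipelineResult:
    """Full MDSN pipeline on preprocessed, sample-matched expression data.

    When no grid threshold satisfies the scale-free criterion (common on
    small synthetic cohorts whose planted cliques have near-uniform degrees,
    making the log-log fit undefined), the network is left unpruned with a
    warning rather than aborting; ``select_threshold`` itself still raises.
    """
    cfg = dict(DEFAULT_CONFIG)
    if config:
        cfg.update(config)
    mirna, mrna, design = align_samples(mirna, mrna, design)
    assoc = run_pairwise_analyses(
        mirna,
        mrna,
        design,
        subtypes=subtypes,
        p_threshold=cfg["p_threshold"],
        require_negative=cfg["require_negative"],
    )
    net = build_similarity_network(assoc, beta=cfg["beta"])
    curve = threshold_curve(net, cfg["threshold_grid"])
    try:
        thr = select_threshold(net, cfg["threshold_grid"], r2_min=cfg["r2_min"])
    except ThresholdSelectionError as err:
        logger.warning("threshold selection failed (%s); keeping network unpruned", err)
        thr = None
    pruned = prune(net, thr) if thr is not None else prune(net, 0.0)
    partition = louvain(pruned, seed=cfg["seed"])
    model = None
    aurocs = None
    if classify and design.stage_of:
        X, y, _ = stage_matrix(mirna, design)
        groups = GroupStructure.from_partition(mirna.feature_ids, partition)
        tr, te = holdout_split(y, test_fraction, seed=cfg["seed"])
        model = fit_sgl_logistic(
            X[tr],
            y[tr],
            groups,
            lam=cfg["sgl_lambda"],
            alpha=cfg["sgl_alpha"],
            feature_ids=mirna.feature_ids,
            class_order=cfg["label_order"],
        )
        aurocs = roc_auc_per_class(model, X[te], y[te])
    return PipelineResult(
        association=assoc,
        network=pruned,
        threshold=thr,
        partition=partition,
        model=model,
        auroc_by_stage=aurocs,
        curve=curve,
    )
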