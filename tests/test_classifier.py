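import numpy as np
import pytest
from scipy import optimize

import mdsn
from mdsn.classifier import GroupStructure, fit_sgl_binary, group_lasso_penalty
from mdsn.errors import DegenerateLabelError, StratificationError


def groups_of(sizes):
    idx, out = 0, []
    for s in sizes:
        out.append(np.arange(idx, idx + s))
        idx += s
    return GroupStructure(groups=out, n_features=idx)


def logistic_instance(n=50, d=10, seed=0, informative=3):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, d))
    # modest signal keeps the instance non-separable (finite logistic MLE)
    w_true = np.zeros(d)
    w_true[:informative] = rng.normal(0, 0.8, informative)
    margins = X @ w_true + rng.logistic(size=n)
    y = np.where(margins > 0, 1.0, -1.0)
    return X, y


class TestGroupStructure:
    def test_weights_and_singleton_fill(self):
        gs = groups_of([4, 2])
        np.testing.assert_allclose(gs.weights, [2.0, np.sqrt(2)])
        gs2 = GroupStructure(groups=[np.array([0, 1])], n_features=4)
        assert len(gs2.groups) == 3  # features 2, 3 become singletons
        covered = np.sort(np.concatenate(gs2.groups))
        np.testing.assert_array_equal(covered, np.arange(4))

    def test_overlap_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            GroupStructure(groups=[np.array([0, 1]), np.array([1, 2])], n_features=3)

    def test_from_partition(self):
        part = mdsn.ModulePartition({"m0": 0, "m2": 0, "m3": 1})
        gs = GroupStructure.from_partition(["m0", "m1", "m2", "m3"], part)
        blocks = {tuple(g.tolist()) for g in gs.groups}
        assert blocks == {(0, 2), (3,), (1,)}


class TestObjective:
    def test_loss_at_origin_is_log2(self):
        X, y = logistic_instance()
        gs = groups_of([5, 5])
        obj = mdsn.sgl_objective(np.zeros(10), 0.0, X, y, lam=3.0, alpha=0.4, groups=gs)
        assert obj == pytest.approx(np.log(2), abs=1e-12)

    def test_group_penalty_sqrt_size(self):
        w = np.full(4, 0.5)  # ||w||_2 = 1
        gs = groups_of([4])
        assert group_lasso_penalty(w, gs) == pytest.approx(2.0)  # sqrt(4) * 1

    def test_alpha_one_is_plain_lasso(self):
        X, y = logistic_instance(seed=2)
        gs = groups_of([3, 7])
        w = np.linspace(-1, 1, 10)
        obj = mdsn.sgl_objective(w, 0.1, X, y, lam=0.7, alpha=1.0, groups=gs)
        margins = y * (X @ w + 0.1)
        expected = np.logaddexp(0, -margins).mean() + 0.7 * np.abs(w).sum()
        assert obj == pytest.approx(expected, abs=1e-12)


class TestProx:
    def prox_objective(self, w, v, step, lam, alpha, gs):
        from mdsn.classifier import sgl_penalty

        return 0.5 * np.sum((w - v) ** 2) + step * sgl_penalty(w, lam, alpha, gs)

    def test_lambda_zero_identity(self):
        v = np.array([3.0, -1.0, 0.5])
        gs = groups_of([3])
        np.testing.assert_array_equal(mdsn.sgl_prox(v, 1.0, 0.0, 0.5, gs), v)

    def test_block_kill(self):
        gs = groups_of([2])
        v = np.array([0.3, -0.4])  # ||v|| = 0.5 <= step*lam*sqrt(2)
        out = mdsn.sgl_prox(v, 1.0, 1.0, 0.0, gs)
        np.testing.assert_array_equal(out, np.zeros(2))

    def test_two_stage_hand_value(self):
        # v = [3, -1], lam = 1, alpha = 0.5, step = 1, one group of 2:
        # soft-threshold at 0.5 -> [2.5, -0.5]; block shrink by
        # (1 - 0.5*sqrt(2)/||[2.5,-0.5]||)
        gs = groups_of([2])
        v = np.array([3.0, -1.0])
        inner = np.array([2.5, -0.5])
        shrink = 1 - 0.5 * np.sqrt(2) / np.linalg.norm(inner)
        np.testing.assert_allclose(
            mdsn.sgl_prox(v, 1.0, 1.0, 0.5, gs), inner * shrink, atol=1e-12
        )

    def test_matches_numerical_minimizer(self):
        rng = np.random.default_rng(0)
        for trial in range(20):
            sizes = rng.integers(1, 4, size=rng.integers(1, 4))
            gs = groups_of(sizes.tolist())
            d = int(sizes.sum())
            v = rng.normal(0, 2, d)
            step = float(rng.uniform(0.1, 2))
            lam = float(rng.uniform(0, 1.5))
            alpha = float(rng.uniform(0, 1))
            ours = mdsn.sgl_prox(v, step, lam, alpha, gs)
            res = optimize.minimize(
                self.prox_objective, x0=v, args=(v, step, lam, alpha, gs),
                method="Powell", options={"xtol": 1e-12, "ftol": 1e-14, "maxiter": 10000},
            )
            f_ours = self.prox_objective(ours, v, step, lam, alpha, gs)
            assert f_ours <= res.fun + 1e-9
            # strong convexity (modulus 1): ||w - w*|| <= sqrt(2 * suboptimality)
            assert np.linalg.norm(ours - res.x) <= np.sqrt(2 * max(res.fun - f_ours, 0)) + 1e-6


class TestFit:
    def test_unpenalized_matches_reference(self):
        from sklearn.linear_model import LogisticRegression

        X, y = logistic_instance(n=50, d=10, seed=0)
        gs = groups_of([5, 5])
        w, b, hist = fit_sgl_binary(X, y, gs, lam=0.0, alpha=0.5, tol=1e-14, max_iter=50_000)
        ref = LogisticRegression(C=np.inf, tol=1e-12, max_iter=10_000).fit(X, (y > 0))
        ours = X @ w + b
        theirs = X @ ref.coef_[0] + ref.intercept_[0]
        np.testing.assert_allclose(ours, theirs, atol=1e-4)

    def test_objective_non_increasing(self):
        X, y = logistic_instance(n=80, d=12, seed=4)
        gs = groups_of([4, 4, 4])
        _, _, hist = fit_sgl_binary(X, y, gs, lam=0.05, alpha=0.5)
        assert (np.diff(hist) <= 1e-12).all()

    def test_complete_shrinkage_at_large_lambda(self):
        X, y = logistic_instance(seed=5)
        gs = groups_of([5, 5])
        model = mdsn.fit_sgl_logistic(X, np.where(y > 0, "tumor", "normal"), gs, lam=1e3, alpha=0.5)
        np.testing.assert_array_equal(model.W, np.zeros_like(model.W))

    def test_group_level_sparsity_at_alpha_zero(self):
        X, y = logistic_instance(n=60, d=12, seed=6)
        gs = groups_of([3, 3, 3, 3])
        w, _, _ = fit_sgl_binary(X, y, gs, lam=0.08, alpha=0.0)
        for g in gs.groups:
            block = w[g]
            assert (block == 0).all() or (np.abs(block) > 1e-12).all()

    def test_group_recovery(self):
        """Signal aligned with one group: nonzero weight mass concentrates there."""
        rng = np.random.default_rng(8)
        n, d = 120, 30
        X = rng.standard_normal((n, d))
        w_true = np.zeros(d)
        w_true[:5] = 1.5  # first group carries all signal
        y = np.where(X @ w_true + rng.logistic(size=n) > 0, 1.0, -1.0)
        gs = groups_of([5] * 6)
        w, _, _ = fit_sgl_binary(X, y, gs, lam=0.08, alpha=0.1)
        assert np.abs(w).sum() > 0
        mass_in = np.abs(w[:5]).sum() / np.abs(w).sum()
        assert mass_in >= 0.8

    def test_single_class_rejected(self):
        X, _ = logistic_instance()
        with pytest.raises(DegenerateLabelError):
            mdsn.fit_sgl_logistic(X, ["I"] * 50, groups_of([10]), lam=0.1)


class TestEvaluation:
    def _model(self, W, labels=("neg", "pos"), feature_ids=None):
        d = W.shape[1]
        return mdsn.SGLModel(
            W=W, intercepts=np.zeros(W.shape[0]), lam=0.1, alpha=0.5,
            groups=GroupStructure.singletons(d), class_labels=list(labels),
            feature_ids=feature_ids or [f"m{i}" for i in range(d)],
        )

    def test_auroc_worked_example(self):
        # scores [.9,.8,.7,.4,.3,.1] with positives at ranks 1, 2, 4 -> 8/9
        scores = np.array([0.9, 0.8, 0.7, 0.4, 0.3, 0.1])
        labels = ["pos", "pos", "neg", "pos", "neg", "neg"]
        model = self._model(np.vstack([-scores, scores]))
        X = np.eye(6)
        aucs = mdsn.roc_auc_per_class(model, X, labels)
        assert aucs["pos"] == pytest.approx(8 / 9)
        # flipping both the labels and the scores preserves the AUC
        assert aucs["neg"] == pytest.approx(8 / 9)

    def test_constant_scores_tie_convention(self):
        model = self._model(np.zeros((2, 4)))
        aucs = mdsn.roc_auc_per_class(model, np.eye(4), ["pos", "neg", "pos", "neg"])
        assert aucs["pos"] == pytest.approx(0.5)

    def test_missing_class_flagged(self):
        model = self._model(np.ones((2, 3)))
        aucs = mdsn.roc_auc_per_class(model, np.eye(3), ["pos", "pos", "pos"])
        assert np.isnan(aucs["neg"]) and np.isnan(aucs["pos"])

    def test_biomarker_table(self):
        # 10 candidates with hand-set coefficients; 4 known among the top 5
        coef = np.array([1.0, 0.9, 0.8, 0.7, 0.6, 0.5, 0.4, 0.3, 0.2, 0.1])
        model = self._model(np.vstack([coef, -coef]))
        known = {"m0", "m1", "m3", "m4", "m7", "m8", "m9", "mX"}  # |known| = 8
        table = mdsn.rank_and_evaluate_biomarkers(model, known, k_list=[5])
        row = table.iloc[0]
        assert (row["k"], row["precision"], row["recall"]) == (5, 0.8, 0.5)

    def test_saturation_and_disjoint(self):
        coef = np.array([0.5, 0.0, 0.3])
        model = self._model(np.vstack([coef, -coef]))
        all_known = {"m0", "m2"}
        t = mdsn.rank_and_evaluate_biomarkers(model, all_known, k_list=[1, 2])
        assert (t["precision"] == 1.0).all()
        t2 = mdsn.rank_and_evaluate_biomarkers(model, {"zzz"}, k_list=[2])
        assert t2.iloc[0]["precision"] == 0.0 and t2.iloc[0]["recall"] == 0.0

    def test_k_truncated_to_candidates(self):
        coef = np.array([0.5, 0.0, 0.3])
        model = self._model(np.vstack([coef, -coef]))
        t = mdsn.rank_and_evaluate_biomarkers(model, {"m0"}, k_list=[10])
        assert t.iloc[0]["k"] == 2


class TestCrossValidate:
    def _data(self, seed=0):
        rng = np.random.default_rng(seed)
        n, d = 80, 10
        X = rng.standard_normal((n, d))
        y = np.where(X[:, 0] + 0.5 * rng.logistic(size=n) > 0, "tumor", "normal")
        return X, y

    def test_singleton_grid(self):
        X, y = self._data()
        gs = groups_of([5, 5])
        lam, alpha, table = mdsn.cross_validate(X, y, gs, [0.02], [0.5], n_folds=3, seed=1)
        assert (lam, alpha) == (0.02, 0.5)
        assert len(table) == 3

    def test_deterministic(self):
        X, y = self._data(seed=3)
        gs = groups_of([10])
        out1 = mdsn.cross_validate(X, y, gs, [0.02, 0.1], [0.5], n_folds=3, seed=7)
        out2 = mdsn.cross_validate(X, y, gs, [0.02, 0.1], [0.5], n_folds=3, seed=7)
        assert out1[0] == out2[0] and out1[1] == out2[1]
        assert out1[2].equals(out2[2])

    def test_shuffled_labels_near_half(self):
        rng = np.random.default_rng(11)
        X, y = self._data(seed=4)
        y = rng.permutation(y)
        gs = groups_of([10])
        _, _, table = mdsn.cross_validate(X, y, gs, [0.02], [0.5], n_folds=4, seed=2)
        assert abs(table["macro_auroc"].mean() - 0.5) < 0.15

    def test_too_few_per_class(self):
        X, y = self._data()
        y = np.array(["rare"] * 2 + list(y[2:]))
        with pytest.raises(StratificationError):
            mdsn.cross_validate(X, y, groups_of([10]), [0.1], [0.5], n_folds=5, seed=0)
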