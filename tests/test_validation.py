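import warnings

import numpy as np
import pytest

from conftest import make_glm_records
from kelpscape import validation
from kelpscape.errors import UndefinedAUCError


def brute_force_auc(scores, labels):
    """All-pairs concordance oracle: ties count one half."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    pos = scores[labels]
    neg = scores[~labels]
    total = 0.0
    for sp in pos:
        for sn in neg:
            total += 1.0 if sp > sn else (0.5 if sp == sn else 0.0)
    return total / (len(pos) * len(neg))


class TestAUC:
    def test_perfect_separation(self):
        assert validation.auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_all_ties_is_half(self):
        assert validation.auc([0.5] * 6, [0, 1, 0, 1, 0, 1]) == 0.5

    def test_hand_counted_example(self):
        # 4 presence/absence pairs, 3 concordant
        assert validation.auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == 0.75

    def test_matches_pair_counting_on_random_instances(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            n = int(rng.integers(4, 51))
            scores = np.round(rng.random(n), 2)  # induce ties
            labels = rng.random(n) < 0.5
            if labels.all() or not labels.any():
                labels[0] = ~labels[0]
            assert validation.auc(scores, labels) == pytest.approx(
                brute_force_auc(scores, labels), abs=1e-12
            )

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(12)
        scores = rng.random(200)
        labels = rng.random(200) < 0.3
        assert validation.auc(scores, labels) == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12
        )

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(13)
        scores = rng.random(100)
        labels = rng.random(100) < 0.4
        base = validation.auc(scores, labels)
        assert validation.auc(np.exp(5 * scores), labels) == pytest.approx(base, abs=1e-12)
        assert validation.auc(np.log(scores + 1e-9), labels) == pytest.approx(base, abs=1e-12)

    def test_single_class_undefined(self):
        with pytest.raises(UndefinedAUCError):
            validation.auc([0.1, 0.9], [1, 1])


class TestLOOCV:
    def test_intercept_only_matches_closed_form(self):
        df = make_glm_records(7, n=50)
        res = validation.loocv(df, covariates=())
        K, M = df["k"].sum(), df["m"].sum()
        closed = [(K - df["k"][i]) / (M - df["m"][i]) for i in res.heldout["index"]]
        np.testing.assert_allclose(res.heldout["p_hat"], closed, atol=1e-9)

    def test_capped_subset_is_reproducible(self):
        df = make_glm_records(8, n=120)
        a = validation.loocv(df, max_n=30, seed=5)
        b = validation.loocv(df, max_n=30, seed=5)
        assert list(a.heldout["index"]) == list(b.heldout["index"])
        np.testing.assert_array_equal(a.heldout["p_hat"], b.heldout["p_hat"])

    def test_loocv_error_exceeds_resubstitution(self):
        wins = 0
        for s in range(10):
            df = make_glm_records(100 + s, n=120)
            loo = validation.loocv(df)
            resub = validation.resubstitution_error(df)
            wins += loo.rmse >= resub
        assert wins >= 9


class TestKFold:
    def test_fold_sizes_balanced(self):
        df = make_glm_records(20, n=500)
        res = validation.kfold_cv(df, k=10, seed=3)
        sizes = res.heldout.groupby("fold").size()
        assert sizes.between(49, 51).all()
        assert len(res.fold_auc) == 10
        # folds partition the data
        assert sorted(res.heldout["index"]) == list(range(500))

    def test_same_seed_identical_folds(self):
        df = make_glm_records(21, n=300)
        a = validation.kfold_cv(df, k=10, seed=9)
        b = validation.kfold_cv(df, k=10, seed=9)
        assert a.fold_auc == b.fold_auc

    def test_kfold_close_to_loocv(self):
        df = make_glm_records(55, n=500)
        loo = validation.loocv(df, seed=1)
        kf = validation.kfold_cv(df, k=10, seed=1)
        assert abs(loo.mean_auc - kf.mean_auc) < 0.05


class TestLearningCurve:
    @pytest.fixture(scope="class")
    def curve(self):
        df = make_glm_records(30, n=600)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return validation.learning_curve(
                df, n_grid=range(20, 301, 70), repeats=3, seed=2, full_cap=300
            )

    def test_error_decreases_from_small_to_large_n(self, curve):
        me = curve.mean_error()
        assert me.iloc[0] > me.iloc[-1]

    def test_largest_n_close_to_full_error(self, curve):
        me = curve.mean_error()
        assert me.iloc[-1] - curve.full_error <= 2 * curve.eps

    def test_table_shape_and_flags(self, curve):
        assert set(curve.table.columns) >= {"n_train", "repeat", "error", "converged"}
        assert len(curve.table) == 5 * 3
        assert curve.table["converged"].all()

    def test_oversized_grid_rejected(self):
        df = make_glm_records(31, n=50)
        with pytest.raises(ValueError):
            validation.learning_curve(df, n_grid=[100], seed=1)


class TestOracleScorer:
    def test_true_probabilities_score_near_optimal(self):
        # scoring by the generative p is at least as good as the fitted model
        from scipy.special import expit

        beta = (-1.0, 0.004, -0.003, -0.15, 0.8)
        df = make_glm_records(42, n=500, beta=beta)
        eta = (
            beta[0]
            + beta[1] * df["y"]
            + beta[2] * df["x"]
            + beta[3] * df["depth_m"]
            + beta[4] * df["reef"]
        )
        labels = validation.presence_labels(df)
        auc_true = validation.auc(expit(eta), labels)
        from kelpscape import sdm

        model = sdm.fit_binomial_glm(df)
        p_fit, _ = sdm.predict_records(model, df)
        auc_fit = validation.auc(p_fit, labels)
        assert auc_true >= auc_fit - 0.02
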