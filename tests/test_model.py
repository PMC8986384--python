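"""ROC/AUC, stratified splitting, AdaBoost boosting arithmetic, operating
metrics and the calibration curve."""

import math

import numpy as np
import pandas as pd
import pytest

from habitatkit import (
    BoostedModel,
    DecisionStump,
    calibration_curve,
    evaluate,
    fit_adaboost_gp,
    mann_whitney_auc,
    operating_metrics,
    roc_auc,
    split_cohort,
)
from oracles import brute_auc

HALF_LN_3 = 0.5 * math.log(3.0)
HALF_LN_5 = 0.5 * math.log(5.0)


class TestAuc:
    def test_trivial_cases(self):
        assert mann_whitney_auc([1, 2, 3, 4], [0, 0, 1, 1]) == 1.0
        assert mann_whitney_auc([1, 2, 3, 4], [1, 1, 0, 0]) == 0.0
        assert mann_whitney_auc([1, 2, 3, 4], [0, 1, 0, 1]) == 0.75
        assert mann_whitney_auc([2, 2, 2, 2], [0, 1, 0, 1]) == 0.5

    @pytest.mark.parametrize("seed", range(10))
    def test_equals_pair_enumeration_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 61))
        scores = rng.integers(0, 8, size=n).astype(float)  # heavy ties
        labels = rng.integers(0, 2, size=n)
        if labels.sum() in (0, n):
            labels[0], labels[1] = 0, 1
        assert mann_whitney_auc(scores, labels) == pytest.approx(
            brute_auc(scores, labels), abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=40)
        labels = rng.integers(0, 2, size=40)
        labels[:2] = [0, 1]
        ref = mann_whitney_auc(scores, labels)
        assert mann_whitney_auc(np.exp(scores), labels) == pytest.approx(ref)
        assert mann_whitney_auc(3 * scores - 7, labels) == pytest.approx(ref)

    def test_roc_auc_orientation_and_ci(self):
        rng = np.random.default_rng(4)
        scores = np.concatenate([rng.normal(0, 1, 40), rng.normal(-1.5, 1, 40)])
        labels = np.array([1] * 40 + [0] * 40)
        res = roc_auc(-scores, labels, n_boot=500, seed=0)  # inverted marker
        assert res.flipped and res.auc > 0.5
        assert 0.0 <= res.ci_low <= res.auc <= res.ci_high <= 1.0
        assert res.n_pos == 40 and res.n_neg == 40
        unflipped = roc_auc(scores, labels, n_boot=10, seed=0)
        assert unflipped.auc == pytest.approx(res.auc)
        assert not unflipped.flipped

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            mann_whitney_auc([1.0, 2.0], [1, 1])


class TestSplitCohort:
    def _table(self, n=125, n_pos=69):
        rng = np.random.default_rng(0)
        return pd.DataFrame({
            "inertia": rng.normal(size=n),
            "label": [1] * n_pos + [0] * (n - n_pos),
        })

    def test_mirrors_100_25_design(self):
        train, test = split_cohort(self._table(), ratio=0.8, seed=0)
        assert len(train) == 100 and len(test) == 25
        for part in (train, test):
            assert set(part["label"].unique()) == {0, 1}

    def test_deterministic_per_seed(self):
        t1, _ = split_cohort(self._table(), seed=5)
        t2, _ = split_cohort(self._table(), seed=5)
        pd.testing.assert_frame_equal(t1, t2)

    def test_single_class_rejected(self):
        df = self._table()
        df["label"] = 1
        with pytest.raises(ValueError):
            split_cohort(df)


class TestAdaBoost:
    def test_stump_trace_matches_manual_oracle(self):
        """Hand-traced boosting on x = 0..7, y = 1 1 1 0 0 0 1 1.

        Round 1 picks the x <= 2.5 stump (eps 1/4), round 2 the always-positive
        stump (eps 1/4), round 3 the x > 5.5 stump (eps 1/6); the weight
        vectors after each update were computed by hand with the
        w <- w * exp(-alpha y h) / Z rule.
        """
        X = np.arange(8, dtype=float).reshape(-1, 1)
        y = np.array([1, 1, 1, 0, 0, 0, 1, 1])
        model = fit_adaboost_gp(X, y, n_rounds=3, seed=0, weak_learner="stump")
        eps = [r.error for r in model.rounds]
        alphas = [r.alpha for r in model.rounds]
        assert eps == pytest.approx([0.25, 0.25, 1 / 6], abs=1e-12)
        assert alphas == pytest.approx([HALF_LN_3, HALF_LN_3, HALF_LN_5], abs=1e-12)
        w1 = [1 / 12] * 6 + [1 / 4] * 2
        w2 = [1 / 18] * 3 + [1 / 6] * 5
        w3 = [1 / 6] * 3 + [1 / 10] * 5
        assert model.weight_history[1] == pytest.approx(w1, abs=1e-12)
        assert model.weight_history[2] == pytest.approx(w2, abs=1e-12)
        assert model.weight_history[3] == pytest.approx(w3, abs=1e-12)
        # the three rounds jointly classify the training set perfectly
        assert np.array_equal(model.predict(X), y)

    def test_ensemble_weighted_error_non_increasing_with_stumps(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(60, 2))
        y = ((X[:, 0] + 0.5 * X[:, 1] + rng.normal(0, 0.4, 60)) > 0).astype(int)
        model = fit_adaboost_gp(X, y, n_rounds=8, seed=0, weak_learner="stump")
        F = np.zeros(len(y))
        errs = []
        for r in model.rounds:
            F += r.alpha * (r.learner.predict(model._standardize(X)) * 2 - 1)
            errs.append(np.mean((F > 0).astype(int) != y))
        assert errs[-1] <= errs[0]
        assert all(r.error < 0.5 for r in model.rounds)

    def test_separable_data_fits_perfectly_within_five_rounds(self):
        rng = np.random.default_rng(2)
        X = np.vstack([rng.normal(-3, 0.3, (20, 2)), rng.normal(3, 0.3, (20, 2))])
        y = np.array([0] * 20 + [1] * 20)
        model = fit_adaboost_gp(X, y, n_rounds=5, seed=0)
        assert np.mean(model.predict(X) == y) == 1.0

    def test_shuffled_labels_give_chance_heldout_auc(self):
        """Null experiment: with labels shuffled, held-out AUC sits at 1/2."""
        aucs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(80, 2))
            y = rng.permutation([0, 1] * 40)
            model = fit_adaboost_gp(X[:60], y[:60], n_rounds=3, seed=seed)
            probs = model.predict_proba(X[60:])
            if len(np.unique(y[60:])) == 2:
                aucs.append(mann_whitney_auc(probs, y[60:]))
        assert abs(np.mean(aucs) - 0.5) <= 0.1

    def test_too_few_samples_or_one_class_raise(self):
        X = np.zeros((5, 2))
        with pytest.raises(ValueError):
            fit_adaboost_gp(X, np.array([0, 1, 0, 1, 0]))
        X = np.zeros((12, 2))
        with pytest.raises(ValueError):
            fit_adaboost_gp(X, np.ones(12, dtype=int))

    def test_json_round_trip_preserves_predictions(self, tmp_path):
        rng = np.random.default_rng(5)
        X = np.vstack([rng.normal(-1, 1, (15, 2)), rng.normal(1, 1, (15, 2))])
        y = np.array([0] * 15 + [1] * 15)
        for weak in ("stump", "gp"):
            model = fit_adaboost_gp(X, y, n_rounds=3, seed=0, weak_learner=weak)
            path = tmp_path / f"model_{weak}.json"
            model.to_json(path)
            loaded = BoostedModel.from_json(path)
            assert np.allclose(loaded.predict_proba(X), model.predict_proba(X),
                               atol=1e-9)


class TestEvaluate:
    def _fitted(self):
        rng = np.random.default_rng(6)
        X = np.vstack([rng.normal(-2, 1, (30, 2)), rng.normal(2, 1, (30, 2))])
        y = np.array([0] * 30 + [1] * 30)
        return fit_adaboost_gp(X, y, n_rounds=3, seed=0), X, y

    def test_training_accuracy_of_separable_model(self):
        model, X, y = self._fitted()
        _, metrics, _ = evaluate(model, X, y, n_boot=50)
        assert metrics.accuracy == 1.0

    def test_metrics_match_confusion_matrix_oracle(self):
        rng = np.random.default_rng(7)
        probs = rng.random(50)
        labels = rng.integers(0, 2, size=50)
        m = operating_metrics(probs, labels, 0.4)
        pred = (probs >= 0.4).astype(int)
        tp = np.sum((pred == 1) & (labels == 1))
        fn = np.sum((pred == 0) & (labels == 1))
        tn = np.sum((pred == 0) & (labels == 0))
        fp = np.sum((pred == 1) & (labels == 0))
        assert m.sensitivity == pytest.approx(tp / (tp + fn))
        assert m.specificity == pytest.approx(tn / (tn + fp))
        assert m.accuracy == pytest.approx((tp + tn) / 50)

    def test_extreme_threshold(self):
        model, X, y = self._fitted()
        _, metrics, _ = evaluate(model, X, y, threshold=0.0, n_boot=10)
        assert metrics.sensitivity == 1.0
        assert metrics.specificity == 0.0

    def test_single_class_raises(self):
        model, X, y = self._fitted()
        with pytest.raises(ValueError):
            evaluate(model, X, np.ones_like(y))


class TestCalibrationCurve:
    def test_hand_binned_ten_points(self):
        probs = np.array([0.05, 0.15, 0.15, 0.35, 0.55, 0.55, 0.75, 0.95,
                          0.95, 0.95])
        labels = np.array([0, 0, 1, 0, 1, 0, 1, 1, 1, 0])
        pred, obs, counts = calibration_curve(probs, labels, n_bins=5)
        assert counts.tolist() == [3, 1, 2, 1, 3]
        assert pred == pytest.approx([0.35 / 3, 0.35, 0.55, 0.75, 2.85 / 3])
        assert obs == pytest.approx([1 / 3, 0.0, 0.5, 1.0, 2 / 3])

    def test_all_ones_single_point(self):
        pred, obs, counts = calibration_curve(np.ones(5), np.ones(5, dtype=int))
        assert pred.tolist() == [1.0] and obs.tolist() == [1.0]
        assert counts.tolist() == [5]

    def test_well_calibrated_probabilities_track_diagonal(self):
        rng = np.random.default_rng(8)
        probs = rng.random(5000)
        labels = (rng.random(5000) < probs).astype(int)
        pred, obs, counts = calibration_curve(probs, labels, n_bins=10)
        assert np.all(np.abs(pred - obs) < 0.08)

    def test_matches_sklearn_reference(self):
        from sklearn.calibration import calibration_curve as sk_curve

        rng = np.random.default_rng(9)
        probs = rng.random(200)
        labels = rng.integers(0, 2, size=200)
        pred, obs, _ = calibration_curve(probs, labels, n_bins=10)
        sk_obs, sk_pred = sk_curve(labels, probs, n_bins=10, strategy="uniform")
        assert pred == pytest.approx(sk_pred)
        assert obs == pytest.approx(sk_obs)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            calibration_curve(np.array([0.5, 1.2]), np.array([0, 1]))
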