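"""Feature assembly, SMOTE balancing, network training and calibration."""

import numpy as np
import pytest

from genescout.errors import StageError
from genescout.filter_model import (
    FilterModel,
    assemble_features,
    calibrate_threshold,
    smote_balance,
    train_filter,
)
from genescout.regions import NNConfig


class TestAssembleFeatures:
    def test_pass_through_fixed_order(self):
        vec = assemble_features(92.5, 0.8, 75.0, 90.0, 95.0, 0.85)
        assert vec.tolist() == [92.5, 0.8, 75.0, 90.0, 95.0, 0.85]

    def test_perfect_candidate(self):
        assert assemble_features(100, 1.0, 100, 100, 100, 1.0).tolist() == [
            100, 1.0, 100, 100, 100, 1.0
        ]

    def test_missing_hint_support_names_stage(self):
        with pytest.raises(StageError, match="prediction stage"):
            assemble_features(92.5, 0.8, None, 90.0, 95.0, 0.85)

    def test_out_of_range_rejected(self):
        with pytest.raises(StageError):
            assemble_features(150.0, 0.8, 50.0, 90.0, 95.0, 0.85)


def _clustered(n_pos, n_neg, seed=0):
    rng = np.random.default_rng(seed)
    pos = np.array([100, 1.0, 100, 100, 100, 1.0]) - rng.random((n_pos, 6)) * 5
    neg = np.array([20, 0.1, 0, 20, 25, 0.1]) + rng.random((n_neg, 6)) * 5
    X = np.vstack([pos, neg])
    y = np.array([1] * n_pos + [0] * n_neg)
    return X, y


class TestSmoteBalance:
    def test_exact_one_to_one_ratio(self):
        X, y = _clustered(10, 40)
        Xb, yb = smote_balance(X, y, seed=1)
        assert (yb == 1).sum() == (yb == 0).sum() == 40

    def test_balanced_input_unchanged(self):
        X, y = _clustered(25, 25)
        Xb, yb = smote_balance(X, y, seed=1)
        np.testing.assert_array_equal(Xb, X)

    def test_singleton_minority_duplicates_with_warning(self):
        X, y = _clustered(1, 40)
        with pytest.warns(UserWarning, match="duplicat"):
            Xb, yb = smote_balance(X, y, seed=1)
        assert (yb == 1).sum() == 40
        np.testing.assert_array_equal(Xb[yb == 1], np.repeat(X[:1], 40, axis=0))

    def test_majority_unchanged_and_synthetic_in_minority_hull(self):
        X, y = _clustered(10, 40, seed=3)
        Xb, yb = smote_balance(X, y, seed=3)
        np.testing.assert_array_equal(Xb[:50], X)
        synth = Xb[50:]
        lo, hi = X[y == 1].min(axis=0), X[y == 1].max(axis=0)
        assert np.all(synth >= lo - 1e-9) and np.all(synth <= hi + 1e-9)

    def test_deterministic_given_seed(self):
        X, y = _clustered(7, 31)
        a = smote_balance(X, y, seed=9)
        b = smote_balance(X, y, seed=9)
        np.testing.assert_array_equal(a[0], b[0])

    @pytest.mark.parametrize("ratio", [(3, 50), (20, 21), (2, 100)])
    def test_ratio_property(self, ratio):
        X, y = _clustered(*ratio)
        _, yb = smote_balance(X, y, seed=2)
        assert (yb == 1).sum() == (yb == 0).sum()

    def test_single_class_rejected(self):
        X, _ = _clustered(5, 5)
        with pytest.raises(StageError):
            smote_balance(X, np.ones(10, dtype=int), seed=0)


class TestTrainFilter:
    def test_zero_weight_model_outputs_half(self):
        model = FilterModel.zeros()
        probs = model.predict_proba(np.array([[50, 0.5, 50, 50, 50, 0.5]]))
        assert probs[0] == 0.5

    def test_separable_set_learns(self):
        X, y = _clustered(60, 60, seed=1)
        model = train_filter(X, y, NNConfig(seed=1))
        acc = ((model.predict_proba(X) >= 0.5).astype(int) == y).mean()
        assert acc >= 0.9

    def test_length_mismatch_rejected(self):
        X, y = _clustered(5, 5)
        with pytest.raises(StageError):
            train_filter(X, y[:9], NNConfig(seed=0))

    def test_reproducible_given_seed(self):
        X, y = _clustered(20, 20)
        cfg = NNConfig(seed=4, epochs=50, min_steps=0)
        a, b = train_filter(X, y, cfg), train_filter(X, y, cfg)
        for wa, wb in zip(a.weights, b.weights):
            np.testing.assert_array_equal(wa, wb)

    def test_loss_decreases_on_average(self):
        X, y = _clustered(40, 40, seed=2)
        model = train_filter(X, y, NNConfig(seed=2))
        curve = model.metadata["loss_curve"]
        assert np.mean(curve[-10:]) <= np.mean(curve[:10])


class TestPredictProba:
    def test_in_open_unit_interval(self):
        X, y = _clustered(10, 10)
        model = train_filter(X, y, NNConfig(seed=0, epochs=20, min_steps=0))
        probs = model.predict_proba(X)
        assert np.all(probs > 0) and np.all(probs < 1)

    def test_nan_vector_rejected(self):
        model = FilterModel.zeros()
        with pytest.raises(StageError):
            model.predict_proba(np.array([[np.nan, 0, 0, 0, 0, 0]]))

    def test_trained_positive_scores_above_half(self):
        X, y = _clustered(60, 60, seed=1)
        model = train_filter(X, y, NNConfig(seed=1))
        assert model.predict_proba(X[:1])[0] > 0.5


class TestCalibrateThreshold:
    def _fixed_model(self, prob_map):
        """A stub model whose predict_proba maps rows to fixed values."""
        model = FilterModel.zeros()
        values = np.array(prob_map)
        model.predict_proba = lambda X: values  # type: ignore[assignment]
        return model

    def test_all_positives_needed(self):
        model = self._fixed_model([0.9, 0.8, 0.2, 0.1])
        y = np.array([1, 1, 1, 0])
        assert calibrate_threshold(model, np.zeros((4, 6)), y, 0.95) == pytest.approx(0.2)

    def test_drops_weak_negative(self):
        model = self._fixed_model([0.9, 0.8, 0.5])
        y = np.array([1, 1, 0])
        assert calibrate_threshold(model, np.zeros((3, 6)), y, 0.95) == pytest.approx(0.8)

    def test_single_positive(self):
        model = self._fixed_model([0.3])
        y = np.array([1])
        assert calibrate_threshold(model, np.zeros((1, 6)), y, 0.95) == pytest.approx(0.3)

    def test_no_positives_rejected(self):
        model = self._fixed_model([0.3])
        with pytest.raises(StageError):
            calibrate_threshold(model, np.zeros((1, 6)), np.array([0]), 0.95)

    def test_sensitivity_floor_and_next_candidate_fails(self):
        rng = np.random.default_rng(8)
        probs = rng.random(200)
        y = (rng.random(200) < 0.4).astype(int)
        if y.sum() == 0:
            y[0] = 1
        model = self._fixed_model(probs)
        t = calibrate_threshold(model, np.zeros((200, 6)), y, 0.9)
        pos = probs[y == 1]
        assert (pos >= t).mean() >= 0.9
        larger = sorted(p for p in np.unique(probs) if p > t)
        if larger:
            assert (pos >= larger[0]).mean() < 0.9


class TestSerialization:
    def test_round_trip_bit_identical(self, tmp_path):
        X, y = _clustered(15, 15)
        model = train_filter(X, y, NNConfig(seed=3, epochs=30, min_steps=0))
        calibrate_threshold(model, X, y, 0.95)
        path = tmp_path / "model.json"
        model.save(path)
        again = FilterModel.load(path)
        np.testing.assert_array_equal(model.predict_proba(X), again.predict_proba(X))
        assert again.calibrated_threshold == model.calibrated_threshold

    def test_bad_format_rejected(self):
        with pytest.raises(StageError):
            FilterModel.from_dict({"format": "something-else"})
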