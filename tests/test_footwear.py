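"""Footwear recognition: polynomial features, training, grouped CV."""

import numpy as np
import pytest

import gaitid
from gaitid import (
    footwear_dataset,
    grouped_cv,
    lr_poly_features,
    predict_footwear,
    train_footwear,
)
from gaitid.footwear import FEATURE_BLOCKS, load_classifier, save_classifier
from gaitid.phases import phase_window
from tests.conftest import make_stride


def _stride_with_lr(curve_fn, n=120, bw=600.0):
    """Stride whose fx_L loading-response equals ``curve_fn(t01) * bw``."""
    forces = np.ones((n, 6)) * 0.1 * bw
    w = phase_window(n, "LR")
    t = np.linspace(0, 1, len(w))
    forces[w.start_index : w.end_index, 0] = curve_fn(t) * bw
    return make_stride(forces, body_weight_n=bw)


class TestLrPolyFeatures:
    def test_quintic_interpolated_exactly(self):
        feats = lr_poly_features(_stride_with_lr(lambda t: t**5))
        np.testing.assert_allclose(feats[:6], [1, 0, 0, 0, 0, 0], atol=1e-8)

    def test_constant_series(self):
        feats = lr_poly_features(_stride_with_lr(lambda t: np.full_like(t, 0.5)))
        np.testing.assert_allclose(feats[:6], [0, 0, 0, 0, 0, 0.5], atol=1e-7)

    def test_matches_normal_equations_oracle(self, rng):
        stride = _stride_with_lr(lambda t: 0.3 * t + rng.normal(0, 0.05, t.size))
        w = phase_window(stride.n_samples, "LR")
        t = np.linspace(0, 1, len(w))
        V = np.vander(t, 6)  # descending degree, as the features are ordered
        f = stride.column("L", "fx")[w.start_index : w.end_index] / stride.body_weight_n
        expected = np.linalg.solve(V.T @ V, V.T @ f)
        np.testing.assert_allclose(lr_poly_features(stride)[:6], expected, atol=1e-7)

    def test_weight_invariance(self, subject):
        """Scaling body weight and forces together leaves features unchanged."""
        stride = gaitid.synth_grf_stride(subject, "sport", 55)
        scaled = make_stride(
            stride.forces * 2.0,
            subject_id=stride.subject_id,
            body_weight_n=stride.body_weight_n * 2.0,
        )
        np.testing.assert_allclose(
            lr_poly_features(stride), lr_poly_features(scaled), rtol=1e-9
        )

    def test_feature_block_layout(self):
        assert FEATURE_BLOCKS == (("fx", "L"), ("fx", "R"), ("fy", "L"), ("fy", "R"))

    def test_short_lr_window_rejected(self):
        with pytest.raises(ValueError, match="LR window"):
            lr_poly_features(make_stride(np.ones((20, 6))))


def _two_blob_data(rng, n=40):
    X = np.vstack([rng.normal(0, 0.3, (n, 24)), rng.normal(5, 0.3, (n, 24))])
    y = np.r_[np.zeros(n, int), np.ones(n, int)]
    return X, y


class TestTrainPredict:
    def test_separable_blobs_fit_perfectly(self, rng):
        X, y = _two_blob_data(rng)
        clf = train_footwear(X, y, seed=1)
        assert (predict_footwear(clf, X) == y).all()

    def test_row_order_invariance(self, rng):
        X, y = _two_blob_data(rng)
        perm = rng.permutation(len(y))
        a = train_footwear(X, y, seed=1)
        b = train_footwear(X[perm], y[perm], seed=1)
        probe = rng.normal(2.5, 1.0, (20, 24))
        np.testing.assert_array_equal(predict_footwear(a, probe), predict_footwear(b, probe))

    def test_seeded_determinism(self, rng):
        X, y = _two_blob_data(rng)
        probe = rng.normal(2.5, 1.0, (50, 24))
        a = train_footwear(X, y, seed=7)
        b = train_footwear(X, y, seed=7)
        np.testing.assert_array_equal(predict_footwear(a, probe), predict_footwear(b, probe))

    def test_single_class_rejected(self, rng):
        X = rng.normal(size=(10, 24))
        with pytest.raises(ValueError, match="both"):
            train_footwear(X, np.zeros(10, int))

    def test_serialization_roundtrip(self, rng, tmp_path):
        X, y = _two_blob_data(rng)
        clf = train_footwear(X, y, seed=1)
        save_classifier(clf, tmp_path / "clf.joblib")
        loaded = load_classifier(tmp_path / "clf.joblib")
        probe = rng.normal(2.5, 1.0, (20, 24))
        np.testing.assert_array_equal(predict_footwear(clf, probe), predict_footwear(loaded, probe))


@pytest.fixture(scope="module")
def synthetic_benchmark():
    """Strides of both footwear types for 48 subjects, split by subject.

    The cohort is sized so the classifier is not data-starved, mirroring a
    footwear model trained on a full enrollment corpus."""
    pop = gaitid.sample_population(gaitid.PopulationConfig(n_subjects=48, seed=19))
    rng = np.random.default_rng(19)
    strides = [
        gaitid.synth_grf_stride(subject, fw, int(rng.integers(2**31)), 240.0)
        for subject in pop
        for fw in ("sport", "heels")
        for _ in range(6)
    ]
    return footwear_dataset(strides)


class TestOnSyntheticGait:
    def test_heldout_accuracy_above_90(self, synthetic_benchmark):
        """Subject-disjoint accuracy beats 90% on the default generator."""
        X, y, groups = synthetic_benchmark
        train_mask = np.isin(groups, np.unique(groups)[:36])
        clf = train_footwear(X[train_mask], y[train_mask], seed=3)
        pred = predict_footwear(clf, X[~train_mask])
        acc = np.mean(pred == y[~train_mask])
        assert acc > 0.9
        # both class-conditional accuracies clear the bar as well
        heels = y[~train_mask] == 1
        assert np.mean(pred[heels] == 1) > 0.85
        assert np.mean(pred[~heels] == 0) > 0.85

    def test_grouped_cv_no_subject_leakage_and_beats_chance(self, synthetic_benchmark):
        X, y, groups = synthetic_benchmark
        result = grouped_cv(X, y, groups, n_folds=8, seed=5)
        assert result["ccr_mean"] > 60.0  # well above the 50% no-information rate
        assert len(result["folds"]) == 8

    def test_grouped_cv_metrics_formulas(self):
        """Degenerate predictors produce the textbook sensitivity/specificity."""
        rng = np.random.default_rng(0)
        # blob data so separable that CV is perfect
        X, y = _two_blob_data(rng, n=60)
        # every subject contributes rows of both classes
        groups = np.r_[np.repeat(np.arange(12), 5), np.repeat(np.arange(12), 5)]
        result = grouped_cv(X, y, groups, n_folds=6, seed=1)
        assert result["ccr_mean"] == pytest.approx(100.0)
        assert result["sensitivity_mean"] == pytest.approx(100.0)
        assert result["specificity_mean"] == pytest.approx(100.0)

    def test_grouped_cv_needs_enough_subjects(self, synthetic_benchmark):
        X, y, groups = synthetic_benchmark
        with pytest.raises(ValueError, match="distinct subjects"):
            grouped_cv(X, y, groups, n_folds=100)
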