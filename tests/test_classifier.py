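import numpy as np
import pytest

from depthfall.classifier import (
    ADL_FRAME,
    FALL_FRAME,
    SVMFrameClassifier,
    TrainedModel,
    TrainingSet,
    balance_classes,
    build_training_set,
    loao_folds,
    majority_vote,
    train,
)
from depthfall.config import ActionCode
from depthfall.io import DepthFrame
from depthfall.simulate import iter_sequences


def _delta_rows(bin_index, n, rng=None, spread=0):
    """Unit-sum histogram rows concentrated around one bin."""
    rows = np.zeros((n, 256))
    rng = rng or np.random.default_rng(0)
    for r in rows:
        b = bin_index + (int(rng.integers(-spread, spread + 1)) if spread
                         else 0)
        r[b] = 1.0
    return rows


def _toy_training_set(n_fall=40, n_adl=40):
    rng = np.random.default_rng(1)
    X = np.vstack([_delta_rows(230, n_fall, rng, spread=3),
                   _delta_rows(90, n_adl, rng, spread=3)])
    y = np.array([FALL_FRAME] * n_fall + [ADL_FRAME] * n_adl)
    subjects = np.array(["ES01"] * (n_fall // 2) + ["ES02"] * (n_fall // 2)
                        + ["ES01"] * (n_adl // 2) + ["ES02"] * (n_adl // 2))
    areas = np.full(n_fall + n_adl, 1500)
    return TrainingSet(X=X, y=y, subjects=subjects, areas=areas)


class TestTrain:
    def test_separable_toy_problem(self):
        ts = _toy_training_set()
        model = train(ts.X, ts.y, seed=0)
        assert (model.predict(ts.X) == ts.y).all()
        assert model.classes == (ADL_FRAME, FALL_FRAME)
        assert model.feature_dim == 256

    def test_deterministic_given_seed(self):
        ts = _toy_training_set()
        a = train(ts.X, ts.y, seed=5)
        b = train(ts.X, ts.y, seed=5)
        np.testing.assert_array_equal(
            a.pipeline.named_steps["svm"].coef_,
            b.pipeline.named_steps["svm"].coef_)
        assert a.training_digest == b.training_digest

    def test_single_class_rejected(self):
        X = _delta_rows(100, 10)
        with pytest.raises(ValueError, match="two classes"):
            train(X, [FALL_FRAME] * 10)

    def test_nonpositive_regularization_rejected(self):
        ts = _toy_training_set()
        with pytest.raises(ValueError):
            train(ts.X, ts.y, regularization=0.0)

    def test_feature_dim_checked_at_predict(self):
        ts = _toy_training_set()
        model = train(ts.X, ts.y)
        with pytest.raises(ValueError, match="features"):
            model.predict(np.zeros((1, 100)))


class TestSerialization:
    def test_round_trip_identical_predictions(self, tmp_path):
        ts = _toy_training_set()
        model = train(ts.X, ts.y, seed=2)
        path = model.save(tmp_path / "model.joblib")
        loaded = TrainedModel.load(path)
        np.testing.assert_array_equal(loaded.predict(ts.X),
                                      model.predict(ts.X))
        assert loaded.kind == model.kind
        assert loaded.classes == model.classes
        assert loaded.training_digest == model.training_digest

    def test_foreign_archive_rejected(self, tmp_path):
        import joblib
        path = tmp_path / "other.joblib"
        joblib.dump({"something": "else"}, path)
        with pytest.raises(ValueError, match="not a"):
            TrainedModel.load(path)


class TestMajorityVote:
    def test_strict_majority(self):
        assert majority_vote([FALL_FRAME] * 46 + [ADL_FRAME] * 44) \
            == FALL_FRAME
        assert majority_vote([FALL_FRAME] * 45 + [ADL_FRAME] * 45) \
            == ADL_FRAME
        assert majority_vote([ADL_FRAME]) == ADL_FRAME

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            majority_vote([])


class TestBalancing:
    def _skewed(self, n_fall=300, n_adl=60):
        return _toy_training_set(n_fall=n_fall, n_adl=n_adl)

    def _ratio(self, ts):
        _, counts = np.unique(ts.y, return_counts=True)
        return counts.min() / counts.max()

    def test_subsample_balances_without_new_rows(self, params):
        ts = self._skewed()
        out = balance_classes(ts, "subsample", params, seed=3)
        assert self._ratio(out) >= 0.9
        assert len(out.y) < len(ts.y)
        # every kept row exists in the original matrix
        original = {row.tobytes() for row in ts.X}
        assert all(row.tobytes() in original for row in out.X)

    def test_rotation_augmentation_replicates_minority(self, params):
        ts = self._skewed()
        out = balance_classes(ts, "augment_rotation", params, seed=3)
        assert self._ratio(out) >= 0.9
        minority = {row.tobytes() for row in ts.X[ts.y == ADL_FRAME]}
        new_rows = out.X[len(ts.y):]
        assert all(row.tobytes() in minority for row in new_rows)

    def test_noise_augmentation_unit_sum_and_novel(self, params):
        ts = self._skewed()
        out = balance_classes(ts, "augment_noise", params, seed=3)
        assert self._ratio(out) >= 0.9
        new_rows = out.X[len(ts.y):]
        np.testing.assert_allclose(new_rows.sum(axis=1), 1.0, atol=1e-9)
        assert (out.y[len(ts.y):] == ADL_FRAME).all()

    def test_noise_augmentation_deterministic(self, params):
        ts = self._skewed()
        a = balance_classes(ts, "augment_noise", params, seed=9)
        b = balance_classes(ts, "augment_noise", params, seed=9)
        np.testing.assert_array_equal(a.X, b.X)

    def test_already_balanced_untouched(self, params):
        ts = _toy_training_set(40, 40)
        out = balance_classes(ts, "subsample", params)
        assert out is ts

    def test_single_class_rejected(self, params):
        ts = _toy_training_set(40, 40)
        ts = TrainingSet(X=ts.X[:40], y=ts.y[:40], subjects=ts.subjects[:40],
                         areas=ts.areas[:40])
        with pytest.raises(ValueError):
            balance_classes(ts, "subsample", params)

    def test_unknown_strategy_rejected(self, params):
        with pytest.raises(ValueError, match="strategy"):
            balance_classes(self._skewed(), "smote", params)


class TestLoaoFolds:
    def test_folds_partition_subjects(self):
        folds = loao_folds(["ES01", "ES02", "ES03", "ES02"])
        assert len(folds) == 3
        for train_ids, test_id in folds:
            assert test_id not in train_ids
            assert len(train_ids) == 2

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError):
            loao_folds(["ES01"])


class TestSVMFrameClassifier:
    def _window(self, depth_mm, n=5):
        frames = []
        for _ in range(n):
            grid = np.full((8, 8), depth_mm, dtype=np.uint16)
            frames.append((DepthFrame(grid=grid), np.ones((8, 8), bool)))
        return frames

    def test_window_decision(self, params):
        ts = _toy_training_set()
        model = train(ts.X, ts.y, seed=0)
        clf = SVMFrameClassifier(model, params)
        # bin 230 ~ depth 2700 mm (near floor), bin 90 ~ 1060 mm (standing)
        assert clf(self._window(2700)) == FALL_FRAME
        assert clf(self._window(1060)) == ADL_FRAME

    def test_empty_window_is_adl(self, params):
        ts = _toy_training_set()
        clf = SVMFrameClassifier(train(ts.X, ts.y), params)
        assert clf([]) == ADL_FRAME


class TestBuildTrainingSet:
    CODES = [ActionCode("APBE", "ST"), ActionCode("FBELFR", "ST")]

    def test_frame_labels_inherit_sequence_truth(self, params, subject,
                                                 quiet_scene):
        ts = build_training_set(
            iter_sequences([subject], self.CODES, quiet_scene, params,
                           master_seed=5),
            params, kind="binary")
        assert ts.X.shape[1] == 256
        np.testing.assert_allclose(ts.X.sum(axis=1), 1.0, atol=1e-9)
        assert set(ts.y) == {ADL_FRAME, FALL_FRAME}
        assert set(ts.subjects) == {subject.subject_id}
        # each sequence contributes at most sit_time x fps frames
        window = int(round(params.sit_time_s * params.fps))
        assert len(ts.y) <= 2 * window
        assert ts.skipped == []
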