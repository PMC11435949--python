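import numpy as np
import pytest
from sklearn.base import clone

import sleepradar as sr
from sleepradar.train import images_to_arrays, partition_images, report_from_predictions

from conftest import make_image


class TestSubjectSplit:
    def test_sizes(self):
        subjects = [f"S{i:02d}" for i in range(16)]
        spec = sr.subject_split(subjects, 8, 2, 6, seed=0)
        assert (len(spec.train_subjects), len(spec.val_subjects),
                len(spec.test_subjects)) == (8, 2, 6)

    def test_deterministic(self):
        subjects = [f"S{i}" for i in range(9)]
        assert sr.subject_split(subjects, 6, 1, 2, 3) == sr.subject_split(subjects, 6, 1, 2, 3)

    def test_partition_covers_all_subjects_disjointly(self):
        subjects = [f"S{i}" for i in range(9)]
        spec = sr.subject_split(subjects, 6, 1, 2, seed=1)
        groups = [set(spec.train_subjects), set(spec.val_subjects), set(spec.test_subjects)]
        assert set().union(*groups) == set(subjects)
        assert sum(len(g) for g in groups) == 9

    def test_count_mismatch_rejected(self):
        with pytest.raises(ValueError):
            sr.subject_split(["a", "b", "c"], 2, 2, 2)

    def test_images_of_one_subject_land_in_one_split(self):
        rng = np.random.default_rng(0)
        images = [make_image(rng.random((4, 5)), np.eye(3)[i % 3], f"S{i % 5}")
                  for i in range(30)]
        spec = sr.subject_split([f"S{i}" for i in range(5)], 3, 1, 1, seed=2)
        parts = partition_images(images, spec)
        seen = {}
        for split_name, imgs in parts.items():
            for img in imgs:
                assert seen.setdefault(img.subject_id, split_name) == split_name
        assert sum(len(v) for v in parts.values()) == 30


class TestEvalReport:
    def test_perfect_predictions(self):
        y = np.array([0, 1, 2, 0, 1, 2])
        report = report_from_predictions(y, y)
        assert report.accuracy == 1.0
        assert report.macro_precision == report.macro_recall == report.macro_f1 == 1.0
        assert np.trace(report.confusion) == 6

    def test_binary_style_counts(self):
        """TP=8, FP=2, FN=2 for class 0 gives precision = recall = F1 = 0.8."""
        y_true = np.array([0] * 10 + [1] * 18)
        y_pred = np.array([0] * 8 + [1] * 2 + [0] * 2 + [1] * 16)
        report = report_from_predictions(y_true, y_pred, n_classes=2)
        assert report.precision[0] == pytest.approx(0.8)
        assert report.recall[0] == pytest.approx(0.8)
        assert report.f1[0] == pytest.approx(0.8)

    def test_diagonal_confusion_has_unit_macro_f1(self):
        y = np.repeat([0, 1, 2], 5)
        report = report_from_predictions(y, y)
        assert np.array_equal(report.confusion, np.diag([5, 5, 5]))
        assert report.macro_f1 == 1.0

    def test_accuracy_equals_trace_over_total(self):
        rng = np.random.default_rng(1)
        y_true = rng.integers(0, 3, 200)
        y_pred = rng.integers(0, 3, 200)
        report = report_from_predictions(y_true, y_pred)
        manual = np.mean(y_true == y_pred)
        assert report.accuracy == pytest.approx(manual)
        assert 0.0 <= report.macro_f1 <= 1.0

    def test_formulas_match_hand_arithmetic(self):
        """One-vs-rest precision/recall/F1 recomputed from the confusion
        matrix by the printed binary formulas."""
        rng = np.random.default_rng(2)
        y_true = rng.integers(0, 3, 90)
        y_pred = rng.integers(0, 3, 90)
        report = report_from_predictions(y_true, y_pred)
        c = report.confusion
        for k in range(3):
            tp = c[k, k]
            fp = c[:, k].sum() - tp
            fn = c[k, :].sum() - tp
            prec = tp / (tp + fp) if tp + fp else 0.0
            rec = tp / (tp + fn) if tp + fn else 0.0
            f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
            assert report.precision[k] == pytest.approx(prec)
            assert report.recall[k] == pytest.approx(rec)
            assert report.f1[k] == pytest.approx(f1)

    def test_absent_class_flagged_with_zero_metrics(self):
        y_true = np.array([0, 0, 1, 1])
        y_pred = np.array([0, 0, 1, 1])
        report = report_from_predictions(y_true, y_pred)
        assert report.absent_classes == (2,)
        assert report.recall[2] == 0.0


def _tiny_images(n=12, shape=(40, 60), seed=0):
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        cls = i % 3
        values = rng.random(shape) * 0.1
        values[5 + 8 * cls : 13 + 8 * cls] += 1.0  # class-coded stripe
        out.append(make_image(values, np.eye(3)[cls], f"S{i % 4}"))
    return out


class TestTraining:
    @pytest.fixture(scope="class")
    def fitted(self):
        images = _tiny_images(24)
        config = sr.TrainConfig(epochs=21, batch_size=8, seed=0)
        clf = sr.train(images, images[:6], config,
                       stage_channels=(8, 8), tcn_channels=(16, 16),
                       tcn_dilations=(1, 2), embedding_dim=64)
        return clf, images

    def test_lr_schedule_decays_tenfold_every_ten_epochs(self, fitted):
        clf, _ = fitted
        lr = clf.history_["lr"]
        assert lr[0] == pytest.approx(0.005)
        assert lr[10] == pytest.approx(0.0005)
        assert lr[20] == pytest.approx(0.00005)

    def test_history_covers_every_epoch(self, fitted):
        clf, _ = fitted
        assert len(clf.history_) == 21
        assert "val_accuracy" in clf.history_

    def test_loss_decreases_on_separable_data(self, fitted):
        clf, _ = fitted
        losses = clf.history_["train_loss"].to_numpy()
        assert losses[-1] < losses[0]

    def test_evaluate_on_training_data(self, fitted):
        clf, images = fitted
        report = sr.evaluate(clf, images)
        assert report.n_samples == 24
        assert report.confusion.sum() == 24

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            sr.train([], None, sr.TrainConfig(epochs=1))

    def test_soft_label_targets_accepted(self):
        images = _tiny_images(6)
        X, y, _ = images_to_arrays(images)
        soft = 0.9 * y + 0.1 / 3
        clf = sr.ResTCNClassifier(variant="tcn_only", epochs=1, tcn_channels=(8,),
                                  tcn_dilations=(1,), random_state=0)
        clf.fit(X, soft)
        assert clf.predict(X).shape == (6,)


class TestSklearnCompat:
    def test_clone_and_params_roundtrip(self):
        clf = sr.ResTCNClassifier(epochs=3, dropout=0.25)
        other = clone(clf)
        assert other.get_params() == clf.get_params()
        other.set_params(epochs=7)
        assert other.epochs == 7 and clf.epochs == 3

    def test_fitted_attributes(self):
        images = _tiny_images(6)
        X, y, _ = images_to_arrays(images)
        clf = sr.ResTCNClassifier(variant="tcn_only", epochs=1, tcn_channels=(8,),
                                  tcn_dilations=(1,), random_state=0)
        clf.fit(X, y.argmax(1))
        assert hasattr(clf, "net_") and hasattr(clf, "classes_")
        assert clf.classes_.tolist() == [0, 1, 2]
        proba = clf.predict_proba(X)
        assert np.allclose(proba.sum(axis=1), 1.0, atol=1e-6)
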