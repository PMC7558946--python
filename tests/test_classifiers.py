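"""Classifiers: NTC optimality, strictness rule, PLS-DA, SVM, CNN."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tabletscan import classifiers as clf
from tabletscan import features as feat
from tabletscan import segmentation as seg
from tabletscan import synthetic as syn
from tabletscan.pipeline import assign_true_classes, stratified_split

from _oracles import ntc_min_errors_exhaustive


def _random_instance(rng, n):
    """Overlapping 4-class intensity values."""
    y = rng.integers(1, 5, n)
    centers = {1: 40.0, 2: 30.0, 3: 20.0, 4: 10.0}
    s = np.array([rng.normal(centers[k], 6.0) for k in y])
    return s, y


class TestFitNtc:
    def test_separable_thresholds_at_gap_midpoints(self):
        values = [(100, 1), (90, 1), (70, 2), (60, 2), (40, 3), (30, 3),
                  (10, 4), (5, 4)]
        model = clf.fit_ntc(values)
        assert model.train_errors == 0
        assert model.thresholds == (80.0, 50.0, 20.0)

    def test_two_class_midpoint(self):
        """Single-boundary sub-problem: classes {10, 9} and {8, 7} split at
        8.5 with no training error."""
        values = [(10, 1), (9, 1), (8, 2), (7, 2), (3, 3), (1, 4)]
        model = clf.fit_ntc(values)
        assert model.train_errors == 0
        assert model.thresholds[0] == 8.5

    def test_missing_class_named(self):
        with pytest.raises(ValueError, match="class 3"):
            clf.fit_ntc([(9, 1), (8, 2), (7, 4)])

    def test_deterministic(self, rng):
        s, y = _random_instance(rng, 40)
        y[:4] = [1, 2, 3, 4]
        m1 = clf.fit_ntc(list(zip(s, y)))
        m2 = clf.fit_ntc(list(zip(s, y)))
        assert m1.thresholds == m2.thresholds

    def test_training_error_matches_exhaustive_oracle(self, rng):
        """Exact minimization: the DP fit achieves the same training error
        as a brute-force scan over every threshold triple."""
        for trial in range(40):
            n = int(rng.integers(8, 50))
            s, y = _random_instance(rng, n)
            while len(set(y)) < 4:
                y = rng.integers(1, 5, n)
            model = clf.fit_ntc(list(zip(s, y)))
            want = ntc_min_errors_exhaustive(s, y)
            got = int((clf.predict_ntc(model, s) != y).sum())
            assert got == model.train_errors == want


class TestPredictNtc:
    def test_boundary_goes_to_lower_intensity_class(self):
        m = clf.ThresholdModel("B", (30.0, 20.0, 10.0))
        assert clf.predict_ntc(m, 30.0) == 2
        assert clf.predict_ntc(m, 20.0) == 3
        assert clf.predict_ntc(m, 10.0) == 4

    def test_extremes(self):
        m = clf.ThresholdModel("B", (30.0, 20.0, 10.0))
        assert clf.predict_ntc(m, 1e9) == 1
        assert clf.predict_ntc(m, -5.0) == 4

    @given(st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=20))
    def test_monotone_in_intensity(self, values):
        m = clf.ThresholdModel("B", (300.0, 200.0, 100.0))
        s = np.sort(np.asarray(values))
        pred = clf.predict_ntc(m, s)
        assert (np.diff(pred) <= 0).all()

    def test_strictly_ordered_thresholds_required(self):
        with pytest.raises(ValueError):
            clf.ThresholdModel("B", (10.0, 10.0, 5.0))


class TestPredictStrict:
    def test_clear_winner(self):
        assert clf.predict_strict(np.array([0.9, 0.1, 0.0, 0.0])) == 1

    def test_ambiguous_rejected(self):
        assert clf.predict_strict(np.array([0.6, 0.6, 0.1, 0.1])) == 0

    def test_all_below_cut_rejected(self):
        assert clf.predict_strict(np.array([0.4, 0.3, 0.2, 0.1])) == 0

    def test_argmax_variant(self):
        s = np.array([[0.6, 0.6, 0.1, 0.1], [0.4, 0.3, 0.2, 0.1]])
        out = clf.predict_strict(s, rule="argmax_above_cut")
        assert out.tolist() == [1, 0]


class TestPlsda:
    def test_separable_two_class_zero_cv_error_at_one_component(self, rng):
        X = np.vstack([rng.normal(0, 0.5, (20, 4)), rng.normal(8, 0.5, (20, 4))])
        y = np.repeat([1, 2], 20)
        model = clf.fit_plsda(X, y, n_components_grid=[1], cv_folds=5)
        assert model.cv_misclassifications[1] == 0
        assert (model.predict(X) == y).all()

    def test_permuted_labels_near_chance(self, rng):
        X = np.vstack([rng.normal(k * 8, 0.5, (20, 4)) for k in range(4)])
        y_perm = rng.permutation(np.repeat([1, 2, 3, 4], 20))
        model = clf.fit_plsda(X, y_perm, cv_folds=5)
        acc = (model.predict(X) == y_perm).mean()
        assert acc <= 0.5

    def test_scores_sum_to_one(self, rng):
        """One-hot PLS2 score vectors sum to exactly 1: centered indicator
        columns sum to zero, so the fitted responses keep the simplex sum."""
        X = np.vstack([rng.normal(k * 5, 1.0, (10, 6)) for k in range(4)])
        y = np.repeat([1, 2, 3, 4], 10)
        model = clf.fit_plsda(X, y, n_components_grid=[3], cv_folds=5)
        sums = model.predict_scores(X).sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-10)

    def test_degenerate_rejected(self):
        X = np.ones((12, 5))
        y = np.tile([1, 2, 3, 4], 3)
        with pytest.raises(ValueError, match="degenerate"):
            clf.fit_plsda(X, y, cv_folds=4)

    def test_venetian_blinds_assignment(self):
        folds = clf.venetian_blinds_folds(7, 3)
        assert folds.tolist() == [0, 1, 2, 0, 1, 2, 0]
        with pytest.raises(ValueError):
            clf.venetian_blinds_folds(3, 5)


class TestSvm:
    def test_separable_training_accuracy(self, rng):
        X = np.vstack([rng.normal(50, 2, (15, 6)), rng.normal(150, 2, (15, 6))])
        y = np.repeat([1, 2], 15)
        model = clf.fit_svm(X, y)
        assert (model.predict(X) == y).all()

    def test_blue_subset_uses_one_third_of_columns(self, rng):
        X = rng.normal(100, 10, (24, 12))
        y = np.tile([1, 2, 3, 4], 6)
        model = clf.fit_svm(X, y, channel_subset="B")
        assert model.columns.size == 4
        assert model.columns.tolist() == [8, 9, 10, 11]

    def test_misaligned_rejected(self, rng):
        with pytest.raises(ValueError):
            clf.fit_svm(rng.normal(0, 1, (10, 3)), np.ones(9))


class TestCnn:
    def _zero_noise_images(self, n_per_class=20, size=8):
        base = {1: (242, 240, 235), 2: (241, 231, 178),
                3: (237, 211, 128), 4: (223, 178, 86)}
        imgs, y = [], []
        for k in (1, 2, 3, 4):
            for _ in range(n_per_class):
                a = np.zeros((size, size, 3), np.uint8)
                a[...] = base[k]
                imgs.append(a)
                y.append(k)
        return imgs, np.array(y)

    def test_iteration_budget_arithmetic(self):
        assert clf.iteration_cap(128, 11) == 1408
        assert clf.iterations_per_epoch(1488, 136) == 11

    def test_zero_noise_training_accuracy_reaches_100(self):
        imgs, y = self._zero_noise_images()
        spec = clf.CnnSpec(epochs=5, batch_size=16, n_conv_blocks=2,
                           channels_per_block=(8, 16), train_per_class=None,
                           seed=0)
        model = clf.fit_cnn(imgs, y, spec)
        assert (model.predict(imgs) == y).all()
        assert model.log[-1]["iterations"] == clf.iteration_cap(
            5, clf.iterations_per_epoch(len(imgs), 16))

    def test_deterministic_given_seed(self):
        imgs, y = self._zero_noise_images(n_per_class=8)
        spec = clf.CnnSpec(epochs=2, batch_size=8, n_conv_blocks=2,
                           channels_per_block=(4, 8), train_per_class=None,
                           seed=42)
        m1 = clf.fit_cnn(imgs, y, spec)
        m2 = clf.fit_cnn(imgs, y, spec)
        assert m1.log == m2.log
        assert np.array_equal(m1.net.dense.W, m2.net.dense.W)

    def test_single_class_rejected(self):
        imgs, _ = self._zero_noise_images(n_per_class=4)
        with pytest.raises(ValueError, match="2 classes"):
            clf.fit_cnn(imgs[:16], np.ones(16, dtype=int),
                        clf.CnnSpec(train_per_class=None))

    def test_unequal_sizes_rejected(self):
        a = np.zeros((8, 8, 3), np.uint8)
        b = np.zeros((6, 8, 3), np.uint8)
        with pytest.raises(ValueError, match="canonical"):
            clf.fit_cnn([a, b], np.array([1, 2]), clf.CnnSpec(train_per_class=None))

    def test_quota_enforced(self):
        imgs, y = self._zero_noise_images(n_per_class=4)
        with pytest.raises(ValueError, match="train_per_class"):
            clf.fit_cnn(imgs, y, clf.CnnSpec(train_per_class=10))

    def test_filter_sizes_fixed(self):
        with pytest.raises(ValueError):
            clf.CnnSpec(conv_filter=5)
        with pytest.raises(ValueError):
            clf.CnnSpec(pool_filter=3)


class TestOverlapDegradation:
    def test_accuracy_decreases_as_gaps_shrink(self):
        """Shrinking the class blue-mean gap relative to the spread drives
        held-out NTC accuracy down monotonically (seeded sweep)."""
        accs = []
        for gap in (60.0, 24.0, 6.0):
            classes = syn.overlap_classes(gap, sd=10.0, n_per_class=25)
            spec = syn.SheetSpec(width_px=1024, height_px=768, seed=77)
            sheet, truth = syn.generate_sheet(spec, classes)
            _, crops, _ = seg.segment_sheet(sheet,
                                            min_area=seg.default_min_area(14.7))
            crops = [c for c in assign_true_classes(crops, truth)
                     if c.class_true is not None]
            tab = feat.build_features(crops, factor=4)
            y = tab.y.astype(int)
            tr, te = stratified_split(y, 0.5, seed=5)
            model = clf.fit_ntc(list(zip(tab.s("B")[tr], y[tr])))
            accs.append((clf.predict_ntc(model, tab.s("B")[te]) == y[te]).mean())
        assert accs[0] > accs[1] > accs[2]
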