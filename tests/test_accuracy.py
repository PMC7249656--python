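import numpy as np
import pandas as pd
import pytest
import shapely

from treatscan.accuracy import (ContingencyTable2x2, accuracy_report,
                                binarize_votes, contingency, roc_auc,
                                sample_validation)
from treatscan.classify import VoteRaster
from treatscan.raster_core import PolygonSet
from conftest import make_raster


def votes_from(band2):
    band2 = np.asarray(band2, dtype=float)
    raster = make_raster(np.stack([1.0 - band2, band2]),
                         names=["non_treatment", "treatment"])
    return VoteRaster(raster)


def mann_whitney_auc(scores, labels):
    """Pair-counting U-statistic oracle, ties counted one half."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestBinarizeVotes:
    def test_threshold_zero_all_positive(self):
        out = binarize_votes(votes_from(np.full((4, 4), 0.3)), 0.0)
        np.testing.assert_array_equal(out.values[0], 1.0)

    def test_exactly_at_threshold_is_zero(self):
        out = binarize_votes(votes_from(np.full((2, 2), 0.25)), 0.25)
        np.testing.assert_array_equal(out.values[0], 0.0)

    def test_monotone_in_threshold(self, rng):
        v = votes_from(rng.random((20, 20)))
        n25 = binarize_votes(v, 0.25).values[0].sum()
        n75 = binarize_votes(v, 0.75).values[0].sum()
        assert n25 >= n75

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            binarize_votes(votes_from(np.zeros((2, 2))), 1.5)


class TestSampleValidation:
    def _setup(self):
        mask = make_raster(np.ones((40, 40)), cell_size=10.0, origin=(0, 400),
                           names=["mask"])
        truth = PolygonSet([shapely.box(0, 200, 200, 400)])  # top-left quarter
        return truth, mask

    def test_size_and_balance(self):
        truth, mask = self._setup()
        s = sample_validation(truth, mask, n_per_class=100, seed=0)
        assert len(s) == 200
        assert (s["label"] == 1).sum() == 100

    def test_label1_inside_oracle(self):
        truth, mask = self._setup()
        s = sample_validation(truth, mask, n_per_class=100, seed=1)
        union = shapely.union_all(truth.geometries)
        for _, row in s.iterrows():
            inside = union.covers(shapely.Point(row["x"], row["y"]))
            assert inside == (row["label"] == 1)

    def test_seed_reproducible(self):
        truth, mask = self._setup()
        a = sample_validation(truth, mask, n_per_class=50, seed=5)
        b = sample_validation(truth, mask, n_per_class=50, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_insufficient_cells(self):
        truth, mask = self._setup()
        with pytest.raises(ValueError, match="need"):
            sample_validation(truth, mask, n_per_class=10_000, seed=0)


class TestContingency:
    def test_perfect_match_no_off_diagonal(self):
        band = np.zeros((10, 10))
        band[:5] = 1.0
        modeled = binarize_votes(votes_from(band), 0.5)
        xs = np.repeat(np.arange(10) * 10 + 5.0, 10)
        ys = np.tile(900 + np.arange(10) * 10 + 5.0, 10)
        rows = ((1000 - ys) // 10).astype(int)
        labels = (rows < 5).astype(int)
        t = contingency(modeled, pd.DataFrame({"x": xs, "y": ys, "label": labels}))
        assert t.b == 0 and t.c == 0
        assert t.a == 50 and t.d == 50

    def test_all_zero_model(self):
        modeled = binarize_votes(votes_from(np.zeros((5, 5))), 0.5)
        s = pd.DataFrame({"x": [5.0, 15.0], "y": [955.0, 965.0], "label": [1, 0]})
        t = contingency(modeled, s)
        assert t.a == 0 and t.b == 0 and t.c == 1 and t.d == 1

    def test_counts_match_brute_force_loop(self, rng):
        band = rng.random((20, 20))
        modeled = binarize_votes(votes_from(band), 0.5)
        xs = rng.uniform(0, 200, 1000)
        ys = rng.uniform(800, 1000, 1000)
        labels = rng.integers(0, 2, 1000)
        s = pd.DataFrame({"x": xs, "y": ys, "label": labels})
        t = contingency(modeled, s)
        counts = {"a": 0, "b": 0, "c": 0, "d": 0}
        for x, y, lab in zip(xs, ys, labels):
            row = int((1000 - y) // 10)
            col = int(x // 10)
            mod = band[row, col] > 0.5
            key = ("a" if lab else "b") if mod else ("c" if lab else "d")
            counts[key] += 1
        assert (t.a, t.b, t.c, t.d) == tuple(counts.values())


class TestAccuracyReport:
    def test_validation_table_statistics_period1(self):
        """Error-matrix statistics on a published 1000-point validation
        table (threshold 0.25)."""
        r = accuracy_report(ContingencyTable2x2(450, 24, 50, 476))
        assert r.overall == pytest.approx(0.926, abs=5e-4)
        assert r.chi_square == pytest.approx(727.87, abs=5e-3)
        assert r.user_acc_1 == pytest.approx(94.9, abs=0.05)
        assert r.user_acc_0 == pytest.approx(90.5, abs=0.05)
        assert r.producer_acc_1 == pytest.approx(90.0, abs=0.05)
        assert r.producer_acc_0 == pytest.approx(95.2, abs=0.05)

    def test_validation_table_statistics_period2(self):
        r = accuracy_report(ContingencyTable2x2(350, 14, 150, 486))
        assert r.chi_square == pytest.approx(487.66, abs=5e-3)
        assert r.overall == pytest.approx(0.836, abs=5e-4)

    def test_perfect_classification(self):
        r = accuracy_report(ContingencyTable2x2(30, 0, 0, 70))
        assert r.overall == 1.0
        assert r.user_acc_1 == 100.0 and r.user_acc_0 == 100.0

    def test_zero_marginal_chi_square_undefined(self):
        r = accuracy_report(ContingencyTable2x2(0, 0, 30, 70))
        assert r.chi_square is None and r.p_value is None

    def test_ste_is_binomial(self):
        r = accuracy_report(ContingencyTable2x2(450, 24, 50, 476))
        assert r.ste == pytest.approx(np.sqrt(0.926 * 0.074 / 1000), rel=1e-6)


class TestROC:
    def test_perfect_separation(self):
        scores = np.r_[np.full(10, 0.9), np.full(10, 0.1)]
        labels = np.r_[np.ones(10, int), np.zeros(10, int)]
        assert roc_auc(scores, labels).auc == pytest.approx(1.0)

    def test_all_ties_half(self):
        scores = np.full(20, 0.5)
        labels = np.r_[np.ones(10, int), np.zeros(10, int)]
        assert roc_auc(scores, labels).auc == pytest.approx(0.5)

    def test_mann_whitney_oracle(self, rng):
        scores = np.round(rng.random(200), 2)  # rounding forces ties
        labels = rng.integers(0, 2, 200)
        curve = roc_auc(scores, labels)
        assert curve.auc == pytest.approx(mann_whitney_auc(scores, labels),
                                          abs=1e-12)

    def test_curve_endpoints_and_monotone(self, rng):
        scores = rng.random(100)
        labels = rng.integers(0, 2, 100)
        c = roc_auc(scores, labels)
        assert c.tpr[0] == 0.0 and c.fpr[0] == 0.0
        assert c.tpr[-1] == 1.0 and c.fpr[-1] == 1.0
        assert (np.diff(c.tpr) >= 0).all() and (np.diff(c.fpr) >= 0).all()

    def test_negation_symmetry(self, rng):
        scores = rng.random(100)
        labels = rng.integers(0, 2, 100)
        auc = roc_auc(scores, labels).auc
        neg = roc_auc(-scores, labels).auc
        assert auc == pytest.approx(1.0 - neg, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_auc(np.array([0.1, 0.9]), np.array([1, 1]))


class TestThresholdMonotonicityProperty:
    def test_producer_accuracies_move_oppositely(self, rng):
        """Raising the binarization threshold cannot improve detection of
        true positives nor hurt detection of true negatives."""
        band = rng.random((30, 30))
        v = votes_from(band)
        xs = rng.uniform(0, 300, 400)
        ys = rng.uniform(700, 1000, 400)
        labels = rng.integers(0, 2, 400)
        s = pd.DataFrame({"x": xs, "y": ys, "label": labels})
        pa1, pa0 = [], []
        for thr in (0.25, 0.5, 0.75):
            r = accuracy_report(contingency(binarize_votes(v, thr), s))
            pa1.append(r.producer_acc_1)
            pa0.append(r.producer_acc_0)
        assert pa1[0] >= pa1[1] >= pa1[2]
        assert pa0[0] <= pa0[1] <= pa0[2]
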