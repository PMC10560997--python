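"""Evaluation metrics against hand-derived values and brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from uqgan import (MetricReport, assd, auroc, cce_loss, confusion_scores,
                   expected_calibration_error, negative_log_likelihood,
                   one_hot, paired_t_test, segmentation_report)
from uqgan.metrics import _boundary_points


def brute_force_assd(a, b):
    """All-pairs nearest-boundary-distance oracle."""
    ap = _boundary_points(a).astype(float)
    bp = _boundary_points(b).astype(float)
    d_ab = [min(np.hypot(*(q - p)) for q in bp) for p in ap]
    d_ba = [min(np.hypot(*(q - p)) for q in ap) for p in bp]
    return (np.mean(d_ab) + np.mean(d_ba)) / 2


class TestConfusionScores:
    def test_identity_masks(self):
        m = np.array([[0, 1], [1, 0]])
        assert confusion_scores(m, m, 1) == (1.0, 1.0, 1.0)

    def test_hand_counts(self):
        """TP=3, FP=1, FN=1 -> precision = recall = F1 = 0.75."""
        true = np.array([[1, 1, 1, 1], [0, 0, 0, 0]])
        pred = np.array([[1, 1, 1, 0], [1, 0, 0, 0]])
        assert confusion_scores(pred, true, 1) == (0.75, 0.75, 0.75)

    def test_no_predicted_positives(self):
        true = np.array([[1, 0], [0, 0]])
        pred = np.zeros_like(true)
        p, r, f = confusion_scores(pred, true, 1)
        assert (p, r, f) == (0.0, 0.0, 0.0)

    def test_absent_class_is_undefined(self):
        m = np.zeros((3, 3), dtype=int)
        assert all(np.isnan(v) for v in confusion_scores(m, m, 2))


class TestAssd:
    def test_identical_masks(self):
        m = np.zeros((8, 8), dtype=bool)
        m[2:5, 2:5] = True
        assert assd(m, m) == 0.0

    def test_two_pixels_three_apart(self):
        a = np.zeros((5, 8), dtype=bool)
        b = np.zeros((5, 8), dtype=bool)
        a[2, 1] = True
        b[2, 4] = True
        assert assd(a, b) == 3.0

    def test_matches_brute_force_on_random_masks(self, rng):
        for _ in range(5):
            a = rng.random((32, 32)) > 0.6
            b = rng.random((32, 32)) > 0.6
            assert assd(a, b) == pytest.approx(brute_force_assd(a, b),
                                               abs=1e-9)

    def test_symmetry(self, rng):
        a = rng.random((16, 16)) > 0.5
        b = rng.random((16, 16)) > 0.5
        assert assd(a, b) == assd(b, a)

    def test_empty_mask_sentinel(self):
        a = np.zeros((4, 4), dtype=bool)
        b = np.ones((4, 4), dtype=bool)
        assert assd(a, b) == np.inf

    def test_spacing_scales_distances(self):
        a = np.zeros((5, 8), dtype=bool)
        b = np.zeros((5, 8), dtype=bool)
        a[2, 1] = True
        b[2, 4] = True
        assert assd(a, b, spacing=(1.0, 2.0)) == 6.0


class TestEce:
    def test_perfectly_confident_and_correct(self):
        assert expected_calibration_error(np.ones(10), np.ones(10)) == 0.0

    def test_single_bin_hand_value(self):
        """10 predictions at 0.8, 6 correct: ECE = |0.8 - 0.6| = 0.2."""
        conf = np.full(10, 0.8)
        corr = np.array([1] * 6 + [0] * 4)
        assert expected_calibration_error(conf, corr) == pytest.approx(0.2)

    def test_matches_binning_oracle(self, rng):
        conf = rng.random(500)
        corr = (rng.random(500) < conf).astype(float)
        n_bins = 10
        ece = 0.0
        edges = np.linspace(0, 1, n_bins + 1)
        for b in range(n_bins):
            lo, hi = edges[b], edges[b + 1]
            sel = (conf > lo) & (conf <= hi) if b else (conf <= hi)
            if sel.sum():
                ece += sel.mean() * abs(corr[sel].mean() - conf[sel].mean())
        assert expected_calibration_error(conf, corr) \
            == pytest.approx(ece, abs=1e-12)

    def test_calibrated_by_construction(self):
        """Per-bin accuracy equals per-bin confidence -> ECE = 0."""
        conf = np.repeat([0.25, 0.75], 8)
        corr = np.array([1, 1, 0, 0, 0, 0, 0, 0] + [1, 1, 1, 1, 1, 1, 0, 0])
        assert expected_calibration_error(conf, corr) == pytest.approx(0.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            expected_calibration_error([], [])


class TestNll:
    def test_certain_correct_is_zero(self):
        p = one_hot(np.zeros((3, 3), dtype=int), 2)
        assert negative_log_likelihood(p, np.zeros((3, 3), dtype=int)) == 0.0

    def test_half_confidence_is_ln2(self):
        p = np.full((2, 4, 4), 0.5)
        assert negative_log_likelihood(p, np.zeros((4, 4), dtype=int)) \
            == pytest.approx(np.log(2), abs=1e-12)

    def test_equals_cce_loss(self, rng):
        raw = rng.random((3, 6, 6)) + 1e-3
        p = raw / raw.sum(axis=0, keepdims=True)
        y = rng.integers(0, 3, size=(6, 6))
        assert negative_log_likelihood(p, y) \
            == pytest.approx(cce_loss(p, one_hot(y, 3)), abs=1e-12)


class TestAuroc:
    def test_perfect_separation(self):
        assert auroc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_all_ties_is_half(self):
        assert auroc([0.5] * 6, [0, 0, 0, 1, 1, 1]) == 0.5

    def test_pair_counting_worked_example(self):
        assert auroc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == 0.75

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            auroc([0.1, 0.2], [1, 1])

    def test_agrees_with_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score
        scores = rng.normal(size=200)
        scores[::4] = scores[1::4]  # inject ties
        labels = rng.integers(0, 2, size=200)
        if labels.sum() in (0, 200):
            labels[0] = 1 - labels[0]
        assert auroc(scores, labels) \
            == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    @given(st.floats(0.1, 5.0), st.floats(-3.0, 3.0))
    @settings(deadline=None, max_examples=25)
    def test_invariant_under_monotone_transforms(self, scale, shift):
        rng = np.random.default_rng(99)
        s = rng.normal(size=50)
        y = rng.integers(0, 2, size=50)
        y[0], y[1] = 0, 1
        base = auroc(s, y)
        assert auroc(scale * s + shift, y) == pytest.approx(base, abs=1e-12)
        assert auroc(np.exp(s), y) == pytest.approx(base, abs=1e-12)


class TestPairedTTest:
    def test_identical_sequences_degenerate(self):
        t, p = paired_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and np.isnan(p)

    def test_closed_form_differences(self):
        """Differences (1,2,3): t = 2 / (1/sqrt(3)) = 2*sqrt(3)."""
        t, _ = paired_t_test([2.0, 4.0, 6.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(2 * np.sqrt(3), abs=1e-9)

    def test_matches_brute_force_definition(self, rng):
        a = rng.normal(size=12)
        b = rng.normal(size=12)
        d = a - b
        t_manual = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        t, p = paired_t_test(a, b)
        assert t == pytest.approx(t_manual, abs=1e-10)
        assert 0 <= p <= 1


class TestReports:
    def test_metric_report_range_validation(self):
        with pytest.raises(ValueError, match="f1"):
            MetricReport(f1=1.2)

    def test_segmentation_report_perfect_prediction(self, rng):
        masks = [(rng.random((16, 16)) > 0.6).astype(int) + 0 for _ in range(3)]
        rep = segmentation_report(masks, masks, 2)
        assert rep.f1 == 1.0 and rep.precision == 1.0 and rep.recall == 1.0
        assert rep.assd == 0.0

    def test_segmentation_report_flags_missing_class(self, rng):
        true = [np.zeros((8, 8), dtype=int)]
        true[0][2, 2] = 1
        pred = [np.zeros((8, 8), dtype=int)]
        rep = segmentation_report(pred, true, 3)
        assert any("class 2" in f for f in rep.flags)
        assert any("no predicted positives" in f for f in rep.flags)
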