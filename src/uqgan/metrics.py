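"""Segmentation, calibration and OOD evaluation metrics.

Pixel-level precision/recall/F1, average symmetric surface distance (ASSD,
boundary pixels under 4-connectivity), expected calibration error (ECE,
equal-width bins), negative log-likelihood, Mann–Whitney AUROC (ties count
1/2), and the paired two-sided t-test used to compare models fold-by-fold.

Multi-class segmentation reports are macro-averages over foreground classes;
degenerate cases (empty masks, absent classes, zero denominators) are
flagged rather than silently zeroed where the value is genuinely undefined.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
from scipy import stats
from scipy.spatial import cKDTree

__all__ = [
    "MetricReport",
    "confusion_scores",
    "assd",
    "expected_calibration_error",
    "negative_log_likelihood",
    "auroc",
    "paired_t_test",
    "segmentation_report",
]


@dataclass
class MetricReport:
    """One evaluation's metric values plus the settings that produced them."""

    assd: float = float("nan")
    f1: float = float("nan")
    precision: float = float("nan")
    recall: float = float("nan")
    ece: float = float("nan")
    nll: float = float("nan")
    auroc: float = float("nan")
    settings: dict = field(default_factory=dict)
    flags: list = field(default_factory=list)

    def __post_init__(self):
        for name in ("f1", "precision", "recall", "ece", "auroc"):
            v = getattr(self, name)
            if np.isfinite(v) and not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if np.isfinite(self.nll) and self.nll < 0:
            raise ValueError("nll must be >= 0")

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("assd", "f1", "precision", "recall", "ece", "nll", "auroc")} | \
            {"settings": self.settings, "flags": list(self.flags)}


def confusion_scores(pred_mask: np.ndarray, true_mask: np.ndarray,
                     positive_class: int) -> tuple[float, float, float]:
    """Pixel-level (precision, recall, F1) for one class.

    Zero denominators yield 0 for the affected metric; if the class is
    absent from both masks all three are undefined (returned as nan — the
    caller excludes them from averages).
    """
    pred_mask = np.asarray(pred_mask)
    true_mask = np.asarray(true_mask)
    if pred_mask.shape != true_mask.shape:
        raise ValueError("mask shapes differ")
    p = pred_mask == positive_class
    t = true_mask == positive_class
    if not p.any() and not t.any():
        return float("nan"), float("nan"), float("nan")
    tp = float(np.sum(p & t))
    fp = float(np.sum(p & ~t))
    fn = float(np.sum(~p & t))
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall > 0 else 0.0)
    return precision, recall, f1


def _boundary_points(binary: np.ndarray) -> np.ndarray:
    """Coordinates of boundary pixels: foreground with a 4-neighbour outside."""
    b = np.asarray(binary, dtype=bool)
    pad = np.pad(b, 1)
    all_neigh_fg = (pad[:-2, 1:-1] & pad[2:, 1:-1]
                    & pad[1:-1, :-2] & pad[1:-1, 2:])
    return np.argwhere(b & ~all_neigh_fg)


def assd(mask_a: np.ndarray, mask_b: np.ndarray,
         spacing: float | tuple[float, float] = 1.0) -> float:
    """Average symmetric surface distance between two binary masks.

    Mean of the two directed mean nearest-boundary distances.  An empty
    mask on either side makes the distance undefined; +inf is returned as
    a sentinel.
    """
    a_pts = _boundary_points(mask_a)
    b_pts = _boundary_points(mask_b)
    if len(a_pts) == 0 or len(b_pts) == 0:
        return float("inf")
    sp = np.asarray(spacing if np.ndim(spacing) else (spacing, spacing),
                    dtype=float)
    a_sc = a_pts * sp
    b_sc = b_pts * sp
    d_ab = cKDTree(b_sc).query(a_sc)[0]
    d_ba = cKDTree(a_sc).query(b_sc)[0]
    return float((d_ab.mean() + d_ba.mean()) / 2.0)


def expected_calibration_error(confidences, correctness,
                               n_bins: int = 10) -> float:
    """ECE with equal-width bins on (0, 1].

    ECE = sum_b (n_b / n) * |accuracy(b) - confidence(b)|.  Confidence 0
    falls in the first bin.
    """
    conf = np.asarray(confidences, dtype=float)
    corr = np.asarray(correctness, dtype=float)
    if conf.size == 0:
        raise ValueError("empty input")
    if conf.shape != corr.shape:
        raise ValueError("confidences and correctness shapes differ")
    if np.any(conf < 0) or np.any(conf > 1):
        raise ValueError("confidences must lie in [0, 1]")
    # bin b covers (b/n_bins, (b+1)/n_bins]; ceil maps conf to its bin
    idx = np.clip(np.ceil(conf * n_bins).astype(int) - 1, 0, n_bins - 1)
    ece = 0.0
    n = conf.size
    for b in range(n_bins):
        sel = idx == b
        nb = int(sel.sum())
        if nb == 0:
            continue
        ece += (nb / n) * abs(corr[sel].mean() - conf[sel].mean())
    return float(ece)


def negative_log_likelihood(prob_maps: np.ndarray,
                            true_labels: np.ndarray) -> float:
    """Mean -log p(true class); probabilities clamped at 1e-12.

    ``prob_maps`` is (C, ...) on the simplex; ``true_labels`` integer with
    matching trailing shape.
    """
    p = np.asarray(prob_maps, dtype=float)
    y = np.asarray(true_labels)
    if p.shape[1:] != y.shape:
        raise ValueError("probability map and label shapes differ")
    s = p.sum(axis=0)
    if np.any(p < -1e-5) or not np.allclose(s, 1.0, atol=1e-5):
        raise ValueError("prob_maps is not a simplex along axis 0")
    p_true = np.take_along_axis(p, y[None], axis=0)[0]
    return float(-np.log(np.maximum(p_true, 1e-12)).mean())


def auroc(scores, binary_labels) -> float:
    """Mann–Whitney AUROC: P(random positive outscores a random negative).

    Ties count 1/2.  Computed from midranks, so it is exact and invariant
    under strictly monotone transforms of the scores.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(binary_labels).astype(int)
    if s.shape != y.shape:
        raise ValueError("scores and labels shapes differ")
    n_pos = int(y.sum())
    n_neg = int(len(y) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(s)  # midranks handle ties as 1/2
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0)
                 / (n_pos * n_neg))


def paired_t_test(scores_a, scores_b) -> tuple[float, float]:
    """Two-sided paired t-test on per-fold metric differences.

    Returns (t, p).  Zero-variance differences are degenerate: t is 0 when
    the means agree (p = nan flag) and +/-inf otherwise.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need two equal-length sequences of length >= 2")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        t = 0.0 if np.allclose(d.mean(), 0.0) else float(np.sign(d.mean()) * np.inf)
        return t, float("nan")
    res = stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)


def segmentation_report(pred_masks, true_masks, n_classes: int,
                        spacing: float = 1.0) -> MetricReport:
    """Macro-averaged pixel metrics plus mean foreground ASSD over a dataset.

    Per-class scores are pooled over all images (pixel-level counts), then
    macro-averaged over foreground classes present somewhere; ASSD is
    averaged over (image, class) pairs where both masks are non-empty.
    """
    flags = []
    per_class = {}
    for c in range(1, n_classes):
        tp = fp = fn = 0.0
        assds = []
        present = False
        for pm, tm in zip(pred_masks, true_masks):
            p = pm == c
            t = tm == c
            if p.any() or t.any():
                present = True
            tp += float(np.sum(p & t))
            fp += float(np.sum(p & ~t))
            fn += float(np.sum(~p & t))
            if p.any() and t.any():
                assds.append(assd(p, t, spacing))
        if not present:
            flags.append(f"class {c} absent everywhere; excluded")
            continue
        prec = tp / (tp + fp) if tp + fp > 0 else 0.0
        rec = tp / (tp + fn) if tp + fn > 0 else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec > 0 else 0.0
        if tp + fp == 0:
            flags.append(f"class {c}: no predicted positives")
        per_class[c] = (prec, rec, f1,
                        float(np.mean(assds)) if assds else float("inf"))
        if not assds:
            flags.append(f"class {c}: ASSD undefined (empty surface)")
    if not per_class:
        raise ValueError("no foreground class present in any mask")
    arr = np.array([per_class[c][:3] for c in per_class])
    assd_vals = [per_class[c][3] for c in per_class if np.isfinite(per_class[c][3])]
    return MetricReport(
        assd=float(np.mean(assd_vals)) if assd_vals else float("inf"),
        precision=float(arr[:, 0].mean()),
        recall=float(arr[:, 1].mean()),
        f1=float(arr[:, 2].mean()),
        settings={"n_classes": n_classes, "spacing": spacing,
                  "averaging": "macro over foreground classes, pixel-pooled"},
        flags=flags,
    )
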