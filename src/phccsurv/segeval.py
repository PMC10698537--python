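"""Segmentation evaluation: per-slide metrics with exact binomial CIs, pooled ROC, heatmaps.

Metrics follow the usual pixel-level confusion-matrix definitions. Confidence
intervals use the Clopper–Pearson exact method, computed on the pooled pixel
counts of whichever proportion a metric is (accuracy over all evaluated
pixels, sensitivity over truth-positive pixels, and so on). Metrics whose
denominator is empty are reported as missing (NaN), never clamped to 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import beta as beta_dist
from sklearn.metrics import roc_curve

__all__ = [
    "SlideMetrics",
    "confusion_counts",
    "slide_metrics",
    "clopper_pearson",
    "pooled_roc",
    "render_heatmap",
]

_METRICS = ("accuracy", "specificity", "sensitivity", "precision", "f1")


@dataclass(frozen=True)
class SlideMetrics:
    """Pixel-level confusion counts and derived metrics for one slide.

    ``ci`` maps each defined metric (except F1, which is not a plain binomial
    proportion) to its Clopper–Pearson interval; undefined metrics are NaN
    and absent from ``ci``.
    """

    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    specificity: float
    sensitivity: float
    precision: float
    f1: float
    ci: dict

    @property
    def n_pixels(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion_counts(pred_mask: np.ndarray, truth_mask: np.ndarray,
                     valid: np.ndarray | None = None) -> tuple[int, int, int, int]:
    """(tp, fp, tn, fn) over evaluated pixels; ``valid`` excludes no-data pixels."""
    pred = np.asarray(pred_mask).astype(bool)
    truth = np.asarray(truth_mask).astype(bool)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    if valid is not None:
        pred, truth = pred[valid], truth[valid]
    tp = int(np.sum(pred & truth))
    fp = int(np.sum(pred & ~truth))
    tn = int(np.sum(~pred & ~truth))
    fn = int(np.sum(~pred & truth))
    return tp, fp, tn, fn


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else np.nan


def slide_metrics(pred_mask: np.ndarray, truth_mask: np.ndarray,
                  valid: np.ndarray | None = None, alpha: float = 0.05) -> SlideMetrics:
    """Accuracy/specificity/sensitivity/precision/F1 with exact binomial CIs."""
    tp, fp, tn, fn = confusion_counts(pred_mask, truth_mask, valid)
    n = tp + fp + tn + fn
    acc = _ratio(tp + tn, n)
    spec = _ratio(tn, tn + fp)
    sens = _ratio(tp, tp + fn)
    prec = _ratio(tp, tp + fp)
    f1 = np.nan
    if not np.isnan(prec) and not np.isnan(sens):
        f1 = 0.0 if prec + sens == 0 else 2 * prec * sens / (prec + sens)
    ci = {}
    for name, (s, t) in {
        "accuracy": (tp + tn, n),
        "specificity": (tn, tn + fp),
        "sensitivity": (tp, tp + fn),
        "precision": (tp, tp + fp),
    }.items():
        if t > 0:
            ci[name] = clopper_pearson(s, t, alpha)
    return SlideMetrics(tp=tp, fp=fp, tn=tn, fn=fn, accuracy=acc, specificity=spec,
                        sensitivity=sens, precision=prec, f1=f1, ci=ci)


def clopper_pearson(successes: int, trials: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact (Clopper–Pearson) two-sided binomial confidence interval.

    Beta-quantile form: low = B(alpha/2; s, n-s+1), high = B(1-alpha/2; s+1, n-s),
    with low = 0 at s = 0 and high = 1 at s = n.
    """
    s, n = int(successes), int(trials)
    if n < 1 or not 0 <= s <= n:
        raise ValueError(f"invalid counts: successes={successes}, trials={trials}")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    low = 0.0 if s == 0 else float(beta_dist.ppf(alpha / 2, s, n - s + 1))
    high = 1.0 if s == n else float(beta_dist.ppf(1 - alpha / 2, s + 1, n - s))
    return low, high


def pooled_roc(prob_maps: list[np.ndarray], truth_masks: list[np.ndarray]):
    """ROC over all evaluated pixels pooled across slides.

    NaN probabilities (unvisited pixels) are excluded. Returns
    (fpr, tpr, thresholds, auc) with AUC by trapezoidal integration over the
    unique-threshold operating points.
    """
    if len(prob_maps) != len(truth_masks):
        raise ValueError("prob_maps and truth_masks must be aligned")
    ps, ys = [], []
    for p, y in zip(prob_maps, truth_masks):
        p = np.asarray(p, dtype=float).ravel()
        y = np.asarray(y).ravel()
        if p.shape != y.shape:
            raise ValueError("probability map and truth mask shapes differ")
        ok = ~np.isnan(p)
        ps.append(p[ok])
        ys.append(y[ok].astype(int))
    p_all, y_all = np.concatenate(ps), np.concatenate(ys)
    if len(np.unique(y_all)) < 2:
        raise ValueError("pooled truth contains a single class; AUC undefined")
    fpr, tpr, thr = roc_curve(y_all, p_all)
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, thr, auc


def render_heatmap(prob_map: np.ndarray, truth_mask: np.ndarray | None = None,
                   binarize_at: float | None = None) -> np.ndarray:
    """Render a white(low)-to-red(high) probability heatmap with a green truth overlay.

    Unvisited (NaN) pixels render as light gray. With ``binarize_at`` set the
    probabilities are first thresholded, giving the binary-panel rendering.
    Returns an (H, W, 3) uint8 image; redness is non-decreasing in probability.
    """
    p = np.asarray(prob_map, dtype=float)
    nodata = np.isnan(p)
    p = np.where(nodata, 0.0, p)
    if binarize_at is not None:
        p = (p >= binarize_at).astype(float)
    img = np.empty(p.shape + (3,), dtype=np.float64)
    img[..., 0] = 1.0  # red channel saturated: white -> red ramp
    img[..., 1] = 1.0 - p
    img[..., 2] = 1.0 - p
    img[nodata] = 0.85
    out = np.clip(np.rint(img * 255), 0, 255).astype(np.uint8)
    if truth_mask is not None:
        truth = np.asarray(truth_mask).astype(bool)
        if truth.shape != p.shape:
            raise ValueError("truth mask shape differs from probability map")
        # contour of the truth region (boundary pixels) in pure green
        from scipy.ndimage import binary_erosion

        contour = truth & ~binary_erosion(truth, border_value=0)
        out[contour] = (0, 255, 0)
    return out
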