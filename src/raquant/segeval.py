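"""Segmentation-quality metrics and clinical-consistency statistics.

Voxel-wise confusion counts give accuracy, Dice similarity coefficient
(DSC), sensitivity and specificity; the combined soft-Dice + cross-entropy
loss mirrors the training objective of segmentation networks.  Agreement
between raters or between model scores and clinical disease activity is
quantified with ICC(2,1) (two-way random effects, absolute agreement,
single measure), the Pearson correlation with a Fisher-z confidence
interval, and seeded percentile-bootstrap intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import stats

EPS = 1e-6  # division guard in Dice-style ratios


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class SegMetrics:
    """Confusion-derived fractions; a metric is None when its denominator is 0."""

    accuracy: float
    dsc: float
    sensitivity: float | None
    specificity: float | None
    empty_masks: bool = False  # both masks empty: DSC = 1 by the eps-guard convention


def confusion(pred_mask: np.ndarray, gold_mask: np.ndarray) -> ConfusionCounts:
    """Voxel-wise confusion counts between two binary masks of equal shape."""
    pred = np.asarray(pred_mask).astype(bool)
    gold = np.asarray(gold_mask).astype(bool)
    if pred.shape != gold.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {gold.shape}")
    tp = int(np.count_nonzero(pred & gold))
    fp = int(np.count_nonzero(pred & ~gold))
    fn = int(np.count_nonzero(~pred & gold))
    tn = pred.size - tp - fp - fn
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def metrics(counts: ConfusionCounts) -> SegMetrics:
    """Accuracy, DSC (eps-guarded), sensitivity and specificity."""
    if counts.total <= 0:
        raise ValueError("empty confusion table")
    dsc = (2.0 * counts.tp + EPS) / (2.0 * counts.tp + counts.fp + counts.fn + EPS)
    return SegMetrics(
        accuracy=(counts.tp + counts.tn) / counts.total,
        dsc=dsc,
        sensitivity=counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else None,
        specificity=counts.tn / (counts.tn + counts.fp) if counts.tn + counts.fp else None,
        empty_masks=(counts.tp + counts.fp + counts.fn) == 0,
    )


def dice_ce_loss(
    prob_map: np.ndarray,
    gold_mask: np.ndarray,
    weight_ratio: tuple[float, float] = (1.0, 1.0),
    eps: float = EPS,
) -> float:
    """Equally weighted soft-Dice + mean binary cross-entropy loss.

    Dice term: 1 - (2 sum(p*y) + eps) / (sum(p) + sum(y) + eps).  CE term:
    mean of -[y log p + (1-y) log(1-p)] with probabilities clipped away from
    0 and 1.  Zero at a perfect hard prediction.
    """
    p = np.asarray(prob_map, dtype=float)
    y = np.asarray(gold_mask, dtype=float)
    if p.shape != y.shape:
        raise ValueError("probability map and gold mask shapes differ")
    if p.min() < 0 or p.max() > 1:
        raise ValueError("probabilities must lie in [0, 1]")
    dice = 1.0 - (2.0 * float((p * y).sum()) + eps) / (float(p.sum()) + float(y.sum()) + eps)
    pc = np.clip(p, 1e-12, 1.0 - 1e-12)
    ce = float(-(y * np.log(pc) + (1.0 - y) * np.log(1.0 - pc)).mean())
    w_dice, w_ce = weight_ratio
    return w_dice * dice + w_ce * ce


def icc_agreement(ratings: np.ndarray, alpha: float = 0.05) -> tuple[float, tuple[float, float]]:
    """ICC(2,1) with its F-based confidence interval.

    ``ratings`` is n_subjects x k_raters with no missing cells (n >= 3).
    Two-way random effects, absolute agreement, single measure, computed
    from the two-way ANOVA mean squares; the CI follows the standard
    F-distribution construction for this ICC form.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2 or x.shape[0] < 3 or x.shape[1] < 2:
        raise ValueError("ratings must be n_subjects (>=3) x k_raters (>=2)")
    if np.isnan(x).any():
        raise ValueError("missing cells are not supported")
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((x - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    icc = (msr - mse) / denom if denom != 0 else 1.0

    # McGraw & Wong F-based CI for ICC(A,1)
    a = k * icc / (n * (1.0 - icc)) if icc < 1.0 else np.inf
    b = 1.0 + k * icc * (n - 1.0) / (n * (1.0 - icc)) if icc < 1.0 else np.inf
    if not np.isfinite(a) or mse == 0:
        return float(icc), (float(icc), float(icc))
    v = (a * msc + b * mse) ** 2 / (
        (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    )
    f_l = stats.f.ppf(1.0 - alpha / 2.0, n - 1, v)
    f_u = stats.f.ppf(1.0 - alpha / 2.0, v, n - 1)
    lower = n * (msr - f_l * mse) / (f_l * (k * msc + (k * n - k - n) * mse) + n * msr)
    upper = n * (f_u * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f_u * msr)
    return float(icc), (float(lower), float(upper))


def pearson_ci(
    x: Sequence[float], y: Sequence[float], alpha: float = 0.05
) -> tuple[float, tuple[float, float], float]:
    """Pearson r with Fisher-z CI and two-sided p from the t distribution.

    Returns (r, (lo, hi), p); n >= 3 required, |r| = 1 gives a degenerate CI.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    n = len(xa)
    if n < 3 or len(ya) != n:
        raise ValueError("need >= 3 paired observations")
    r = float(stats.pearsonr(xa, ya).statistic)
    if abs(r) >= 1.0 - 1e-15:
        return r, (r, r), 0.0
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), n - 2)
    if n > 3:
        z = math.atanh(r)
        half = stats.norm.ppf(1.0 - alpha / 2.0) / math.sqrt(n - 3)
        ci = (math.tanh(z - half), math.tanh(z + half))
    else:
        ci = (-1.0, 1.0)
    return r, ci, float(p)


def bootstrap_ci(
    pairs: Sequence[tuple[float, float]],
    statistic: Callable[[np.ndarray, np.ndarray], float],
    n_boot: int = 1000,
    seed: int | None = None,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Seeded percentile bootstrap interval for a paired statistic.

    Resamples pairs with replacement ``n_boot`` times and returns the
    (alpha/2, 1-alpha/2) percentiles of the statistic.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 3 or arr.shape[1] != 2:
        raise ValueError("need >= 3 (x, y) pairs")
    if seed is None:
        raise ValueError("a seed is required for reproducibility")
    rng = np.random.default_rng(seed)
    n = arr.shape[0]
    values = np.empty(n_boot)
    for i in range(n_boot):
        idx = rng.integers(0, n, size=n)
        values[i] = statistic(arr[idx, 0], arr[idx, 1])
    lo, hi = np.percentile(values, [100 * alpha / 2.0, 100 * (1.0 - alpha / 2.0)])
    return float(lo), float(hi)
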