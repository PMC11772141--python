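"""Agreement statistics between two measurement sets (manual vs automated,
or synthetic truth vs automated).

Percent accuracy of a summary quantity is
``(1 - |manual - automated| / manual) × 100``. Object-level agreement uses a
greedy one-to-one matching by mask overlap (IoU), with a nearest-centroid
fallback for objects lacking masks; unmatched detections are false
positives, unmatched references false negatives, both expressed as a
percentage of the reference count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats


def percent_accuracy(manual: float, automated: float) -> float:
    """(1 - |manual - automated| / manual) × 100. Symmetric in the sign of
    the disagreement; requires a nonzero manual value."""
    if manual == 0:
        raise ValueError("percent accuracy undefined for manual == 0")
    return (1.0 - abs(manual - automated) / abs(manual)) * 100.0


@dataclass
class MatchObject:
    """One object to match: a centroid and optionally a boolean mask."""

    centroid: tuple[float, float]
    mask: Optional[np.ndarray] = None


@dataclass
class Matching:
    pairs: list[tuple[int, int]] = field(default_factory=list)  # (ref, det)
    unmatched_ref: list[int] = field(default_factory=list)
    unmatched_det: list[int] = field(default_factory=list)


def _iou(a: np.ndarray, b: np.ndarray) -> float:
    inter = np.logical_and(a, b).sum()
    if inter == 0:
        return 0.0
    union = np.logical_or(a, b).sum()
    return float(inter) / float(union)


def match_objects(
    reference: Sequence[MatchObject],
    detected: Sequence[MatchObject],
    min_iou: float = 0.1,
    centroid_radius: float = 15.0,
) -> Matching:
    """Greedy one-to-one matching, best overlap first.

    Pairs with mask IoU ≥ *min_iou* are matched in decreasing IoU order;
    objects without masks (on either side) fall back to nearest-centroid
    matching within *centroid_radius* pixels. Each object is used at most
    once.
    """
    m = Matching()
    used_ref: set[int] = set()
    used_det: set[int] = set()

    both_masks = [(i, j) for i, r in enumerate(reference) if r.mask is not None
                  for j, d in enumerate(detected) if d.mask is not None]
    scored = []
    for i, j in both_masks:
        iou = _iou(reference[i].mask, detected[j].mask)
        if iou >= min_iou:
            scored.append((iou, i, j))
    for iou, i, j in sorted(scored, key=lambda t: (-t[0], t[1], t[2])):
        if i in used_ref or j in used_det:
            continue
        m.pairs.append((i, j))
        used_ref.add(i)
        used_det.add(j)

    # centroid fallback for whatever remains
    rem_ref = [i for i in range(len(reference)) if i not in used_ref]
    rem_det = [j for j in range(len(detected)) if j not in used_det]
    dists = []
    for i in rem_ref:
        for j in rem_det:
            d = float(np.hypot(
                reference[i].centroid[0] - detected[j].centroid[0],
                reference[i].centroid[1] - detected[j].centroid[1]))
            if d <= centroid_radius:
                dists.append((d, i, j))
    for d, i, j in sorted(dists, key=lambda t: (t[0], t[1], t[2])):
        if i in used_ref or j in used_det:
            continue
        m.pairs.append((i, j))
        used_ref.add(i)
        used_det.add(j)

    m.unmatched_ref = [i for i in range(len(reference)) if i not in used_ref]
    m.unmatched_det = [j for j in range(len(detected)) if j not in used_det]
    return m


def fp_fn_rates(matching: Matching, n_reference: int) -> tuple[float, float]:
    """False-positive and false-negative percentages, both relative to the
    reference (manual) object count."""
    if n_reference <= 0:
        raise ValueError("n_reference must be > 0")
    fp = len(matching.unmatched_det) / n_reference * 100.0
    fn = len(matching.unmatched_ref) / n_reference * 100.0
    return fp, fn


def paired_regression(x: Sequence[float], y: Sequence[float]
                      ) -> tuple[float, float, float]:
    """Ordinary least-squares fit of y on x: (slope, intercept, r²), with
    r² the squared Pearson correlation. Needs ≥ 3 pairs and var(x) > 0."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.var(x) == 0:
        raise ValueError("x has zero variance")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue ** 2)


def binned_histogram(values: Sequence[float], bin_width: float
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Counts of nonnegative values in left-closed right-open bins of the
    given width anchored at 0 (e.g. 300 μm² CSA bins or 15 AU MFI bins).
    Returns (counts, edges); the total count always equals len(values)."""
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    values = np.asarray(list(values), dtype=float)
    if values.size and values.min() < 0:
        raise ValueError("negative values not allowed (CSA/MFI are nonnegative)")
    if values.size == 0:
        edges = np.array([0.0, bin_width])
        return np.zeros(1, dtype=int), edges
    n_bins = int(np.floor(values.max() / bin_width)) + 1
    edges = np.arange(n_bins + 1, dtype=float) * bin_width
    idx = np.floor(values / bin_width).astype(int)
    counts = np.bincount(idx, minlength=n_bins)
    return counts.astype(int), edges


@dataclass
class AgreementReport:
    """Bundle of the validation statistics for one comparison."""

    percent_accuracy_count: float
    percent_accuracy_mean: Optional[float]
    fp_percent: float
    fn_percent: float
    slope: Optional[float] = None
    intercept: Optional[float] = None
    r_squared: Optional[float] = None


def compare_measurements(
    reference: Sequence[MatchObject],
    detected: Sequence[MatchObject],
    reference_values: Optional[Sequence[float]] = None,
    detected_values: Optional[Sequence[float]] = None,
    min_iou: float = 0.1,
    centroid_radius: float = 15.0,
) -> tuple[AgreementReport, Matching]:
    """Full object-level comparison: match, then count accuracy, FP/FN
    rates and — when per-object values are supplied — accuracy of the mean
    value and the paired regression over matched objects."""
    matching = match_objects(reference, detected, min_iou, centroid_radius)
    fp, fn = fp_fn_rates(matching, len(reference))
    acc_count = percent_accuracy(len(reference), len(detected))
    acc_mean = slope = intercept = r2 = None
    if reference_values is not None and detected_values is not None:
        rv = np.asarray(list(reference_values), dtype=float)
        dv = np.asarray(list(detected_values), dtype=float)
        acc_mean = percent_accuracy(float(rv.mean()), float(dv.mean()))
        if len(matching.pairs) >= 3:
            xs = [rv[i] for i, _ in matching.pairs]
            ys = [dv[j] for _, j in matching.pairs]
            if np.var(xs) > 0:
                slope, intercept, r2 = paired_regression(xs, ys)
    return AgreementReport(
        percent_accuracy_count=acc_count, percent_accuracy_mean=acc_mean,
        fp_percent=fp, fn_percent=fn,
        slope=slope, intercept=intercept, r_squared=r2), matching
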