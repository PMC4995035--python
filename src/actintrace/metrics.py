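"""Evaluation against ground truth and orientation analysis.

Pixel-level scoring uses the standard confusion-matrix rates: accuracy
``(TP+TN)/(TP+TN+FP+FN)``, sensitivity ``TP/(TP+FN)`` and specificity
``TN/(TN+FP)``.  A match tolerance (in pixels) is available because
rasterized filament masks have inherently ambiguous one-pixel boundaries;
the default is strict pixelwise comparison.

Fiber-level orientation analysis reports the normalized angular histogram
(counts per orientation bin divided by the maximal count) and linear
mean/variance of orientations in degrees on [0, 180), the descriptive
statistics used to contrast aligned and isotropic fiber populations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import distance_transform_edt

__all__ = [
    "ConfusionCounts",
    "AngularHistogram",
    "OrientationStats",
    "UndefinedMetricWarning",
    "confusion_counts",
    "acc_sn_sp",
    "angular_distribution",
    "orientation_stats",
]


class UndefinedMetricWarning(UserWarning):
    """Raised (as a warning) when a requested ratio has a zero denominator."""


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


def confusion_counts(
    predicted: np.ndarray, truth: np.ndarray, match_tol_px: float = 0.0
) -> ConfusionCounts:
    """Pixel confusion counts between predicted and truth masks.

    With a positive ``match_tol_px``, a predicted-positive pixel within
    that distance of any truth-positive pixel counts as TP, and a
    truth-positive pixel with no predicted positive within the tolerance
    counts as FN; the remainder of the image is TN.  ``match_tol_px = 0``
    is exact pixelwise comparison.
    """
    predicted = np.asarray(predicted, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if predicted.shape != truth.shape:
        raise ValueError(f"shape mismatch: {predicted.shape} vs {truth.shape}")
    if match_tol_px == 0:
        tp = int(np.sum(predicted & truth))
        fp = int(np.sum(predicted & ~truth))
        fn = int(np.sum(~predicted & truth))
        tn = int(np.sum(~predicted & ~truth))
    else:
        near_truth = (
            distance_transform_edt(~truth) <= match_tol_px
            if truth.any()
            else np.zeros_like(truth)
        )
        near_pred = (
            distance_transform_edt(~predicted) <= match_tol_px
            if predicted.any()
            else np.zeros_like(predicted)
        )
        tp = int(np.sum(predicted & near_truth))
        fp = int(np.sum(predicted & ~near_truth))
        fn = int(np.sum(truth & ~near_pred))
        tn = int(predicted.size - tp - fp - fn)
    return ConfusionCounts(TP=tp, FP=fp, TN=tn, FN=fn)


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined: zero denominator", UndefinedMetricWarning)
        return float("nan")
    return num / den


def acc_sn_sp(c: ConfusionCounts) -> tuple[float, float, float]:
    """Accuracy, sensitivity and specificity from confusion counts.

    An undefined ratio (zero denominator) is returned as NaN with an
    :class:`UndefinedMetricWarning`, never as a silent zero.
    """
    acc = _ratio(c.TP + c.TN, c.total, "accuracy")
    sn = _ratio(c.TP, c.TP + c.FN, "sensitivity")
    sp = _ratio(c.TN, c.TN + c.FP, "specificity")
    return acc, sn, sp


@dataclass
class AngularHistogram:
    bin_edges: np.ndarray  # degrees, len(counts) + 1, covering [0, 180]
    counts: np.ndarray
    normalized: np.ndarray

    def table(self):
        import pandas as pd

        return pd.DataFrame(
            dict(
                bin_start=self.bin_edges[:-1],
                bin_end=self.bin_edges[1:],
                count=self.counts,
                normalized=self.normalized,
            )
        )


@dataclass
class OrientationStats:
    mean_deg: float
    variance_deg2: float


def angular_distribution(fibers, bin_width_deg: float = 10.0) -> AngularHistogram:
    """Fibers per orientation bin, normalized by the maximal bin count."""
    if 180.0 % bin_width_deg != 0:
        raise ValueError("bin_width_deg must divide 180")
    edges = np.arange(0.0, 180.0 + bin_width_deg, bin_width_deg)
    thetas = np.array([f.theta_deg % 180.0 for f in fibers])
    counts, _ = np.histogram(thetas, bins=edges)
    if counts.max() > 0:
        normalized = counts / counts.max()
    else:
        warnings.warn(
            "empty fiber list: normalized histogram undefined", UndefinedMetricWarning
        )
        normalized = np.zeros_like(counts, dtype=float)
    return AngularHistogram(bin_edges=edges, counts=counts, normalized=normalized)


def orientation_stats(
    fibers, weighting: str = "none", circular: bool = False
) -> OrientationStats:
    """Mean and population variance of fiber orientations in degrees.

    Statistics are linear on [0, 180) by default, matching the common
    reporting convention for fiber alignment; set ``circular`` for the
    axial (period-180) alternative, where the mean is derived from the
    resultant of doubled angles.
    """
    if weighting not in ("none", "by-length"):
        raise ValueError("weighting must be 'none' or 'by-length'")
    thetas = np.array([f.theta_deg % 180.0 for f in fibers], dtype=float)
    if thetas.size == 0:
        raise ValueError("orientation statistics undefined for an empty fiber list")
    w = (
        np.array([f.length_px for f in fibers], dtype=float)
        if weighting == "by-length"
        else np.ones_like(thetas)
    )
    w = w / w.sum()
    if circular:
        ang = np.deg2rad(2.0 * thetas)
        C = np.sum(w * np.cos(ang))
        S = np.sum(w * np.sin(ang))
        mean = (np.degrees(np.arctan2(S, C)) / 2.0) % 180.0
        R = np.hypot(C, S)
        var = np.degrees(np.sqrt(max(-2.0 * np.log(max(R, 1e-300)), 0.0)) / 2.0) ** 2
        return OrientationStats(mean_deg=float(mean), variance_deg2=float(var))
    mean = float(np.sum(w * thetas))
    var = float(np.sum(w * (thetas - mean) ** 2))
    return OrientationStats(mean_deg=mean, variance_deg2=var)
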