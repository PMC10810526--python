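"""Circular-error metrics for the orientation-estimation task.

Errors are minimal signed angular deviations on the 180°-periodic orientation
circle, in (−90, 90]. Precision is the reciprocal of the non-parametric
circular standard deviation of mean-subtracted errors, computed after angle
doubling. The recency/primacy bias statistic is the signed area under a
sliding-median bias curve (error vs relative orientation of the biasing
stimulus), evaluated over ±[10°, 60°] of relative orientation with the sign
flipped on the negative branch so that attraction is positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .circular import circ_mean_resultant, circ_sd, signed_ori_diff, vm_a

#: Circular-SD floor (dispersion units) used to cap precision for degenerate,
#: zero-dispersion error sets.
PRECISION_EPSILON = 0.01


def signed_error(report, truth):
    """Signed estimation error report − truth on the orientation circle,
    in (−90, 90]; both inputs must lie in [0, 180)."""
    report = np.asarray(report, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if np.any((report < 0) | (report >= 180)) or np.any((truth < 0) | (truth >= 180)):
        raise ValueError("orientations must lie in [0, 180)")
    return signed_ori_diff(report, truth)


def mae(errors) -> float:
    """Mean absolute estimation error in degrees."""
    errors = np.asarray(errors, dtype=float)
    if errors.size == 0:
        raise ValueError("mae of an empty error set")
    return float(np.mean(np.abs(errors)))


def precision(errors):
    """Reciprocal circular SD of mean-subtracted signed errors.

    Returns (precision, capped_flag). Doubling maps orientation errors onto the
    360° circle; the circular SD is sqrt(−2 ln R̄) there, and R̄ — hence the
    precision — is invariant to rotating all errors by a constant.
    """
    errors = np.asarray(errors, dtype=float)
    if errors.size < 2:
        raise ValueError("precision needs at least 2 errors")
    mean, _ = circ_mean_resultant(errors)
    centred = signed_ori_diff(errors, mean)
    sd = circ_sd(centred)
    if sd < PRECISION_EPSILON:
        return 1.0 / PRECISION_EPSILON, True
    return 1.0 / sd, False


def fit_von_mises_errors(errors) -> float:
    """ML von Mises concentration of the error distribution in doubled-angle
    space (the display-overlay fit)."""
    errors = np.asarray(errors, dtype=float)
    if errors.size < 10:
        raise ValueError("need at least 10 samples")
    _, rbar = circ_mean_resultant(errors)
    if rbar <= 1e-12:
        return 0.0
    if rbar >= 1.0 - 1e-12:
        rbar = 1.0 - 1e-12
    sol = optimize.brentq(lambda k: vm_a(k) - rbar, 0.0, 1e6)
    return float(sol)


@dataclass
class ErrorSample:
    """One estimation trial's error paired with the biasing stimulus geometry."""

    signed_error: float
    relative_bias_orientation: float  # biasing − probed orientation, (−90, 90]
    location_class: str = "ST"  # or "SA"
    trial_type: str = "double_set"
    probed_set: str = "initial"


@dataclass
class BiasCurve:
    """Sliding-median bias curve: median signed error per 60°-wide bin of
    relative orientation, stepped by 1°; empty bins are NaN."""

    bin_centers: np.ndarray
    median_error: np.ndarray
    bin_width: float = 60.0
    step: float = 1.0


def bias_curve(relative_orientation, errors, bin_width: float = 60.0,
               step: float = 1.0) -> BiasCurve:
    """Median signed error as a function of biasing-stimulus relative
    orientation, in sliding bins (wraparound on the 180° circle)."""
    rel = np.asarray(relative_orientation, dtype=float)
    err = np.asarray(errors, dtype=float)
    centers = np.arange(-90.0, 90.0 + 1e-9, step)
    med = np.full(len(centers), np.nan)
    for i, c in enumerate(centers):
        d = np.abs(signed_ori_diff(rel, c))
        inbin = d <= bin_width / 2.0
        if inbin.any():
            med[i] = np.median(err[inbin])
    return BiasCurve(bin_centers=centers, median_error=med,
                     bin_width=bin_width, step=step)


def signed_auc_bias(curve: BiasCurve, lo: float = 10.0, hi: float = 60.0) -> float:
    """Signed area under the bias curve over ±[lo, hi] of relative orientation.

    The negative branch's area enters with flipped sign, so an attractive
    (odd, same-sign) curve gives a positive bias and a repulsive curve a
    negative one. Missing bins inside the range are an error.
    """
    c, m = curve.bin_centers, curve.median_error
    pos = (c >= lo) & (c <= hi)
    neg = (c >= -hi) & (c <= -lo)
    if not pos.any() or not neg.any():
        raise ValueError("bias curve does not cover the ±[lo, hi] range")
    if np.isnan(m[pos]).any() or np.isnan(m[neg]).any():
        raise ValueError("empty bias-curve bins inside the integration range")
    area_pos = np.trapezoid(m[pos], c[pos])
    area_neg = np.trapezoid(m[neg], c[neg])
    return float(area_pos - area_neg)
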