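"""Pairwise agreement statistics for device-versus-reference glucose values.

Implements the standard method-comparison toolkit for glucose monitors:
ordinary (unweighted) least-squares regression of device on reference with
r-squared, the mean absolute relative difference (MARD), Bland-Altman bias
with limits of agreement at bias +/- 2.0 sample SD of the differences, and
the small-sample-corrected population coefficient of variation
PCV = (1 + 1/(4N)) * CV.

Differences are oriented device minus reference throughout; all SDs use the
n-1 denominator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

#: limits-of-agreement multiplier (2.0 by convention here, not 1.96)
LOA_FACTOR = 2.0


@dataclass(frozen=True)
class AgreementSummary:
    n_pairs: int
    slope: float
    intercept: float
    r2: float
    mard_pct: float
    bias_mg_dl: float
    sd_bias_mg_dl: float
    loa_low_mg_dl: float
    loa_high_mg_dl: float
    pcv_pct: float


def _as_pair_arrays(ref, cgm) -> tuple[np.ndarray, np.ndarray]:
    ref = np.asarray(ref, dtype=float).ravel()
    cgm = np.asarray(cgm, dtype=float).ravel()
    if ref.shape != cgm.shape:
        raise ValueError(f"length mismatch: {ref.size} vs {cgm.size}")
    if not (np.isfinite(ref).all() and np.isfinite(cgm).all()):
        raise ValueError("non-finite glucose values")
    return ref, cgm


def fit_regression(ref, cgm) -> tuple[float, float, float]:
    """Unweighted OLS of device value on reference value.

    Returns ``(slope, intercept, r2)`` with r-squared the squared Pearson
    correlation of the paired values.
    """
    ref, cgm = _as_pair_arrays(ref, cgm)
    if ref.size < 3:
        raise ValueError("need at least 3 pairs for regression")
    if np.ptp(ref) == 0:
        raise ValueError("reference values are all identical")
    res = stats.linregress(ref, cgm)
    return float(res.slope), float(res.intercept), float(res.rvalue ** 2)


def mard(ref, cgm) -> float:
    """Mean absolute relative difference, %, denominated on the reference."""
    ref, cgm = _as_pair_arrays(ref, cgm)
    if ref.size == 0:
        raise ValueError("no pairs")
    if (ref <= 0).any():
        raise ValueError("reference values must be positive")
    return float(100.0 * np.mean(np.abs(cgm - ref) / ref))


def bland_altman(ref, cgm) -> tuple[float, float, float, float]:
    """Bias and limits of agreement of device minus reference.

    Returns ``(bias, sd_bias, loa_low, loa_high)`` with limits at
    bias -/+ 2.0 * SD (sample SD, n-1).
    """
    ref, cgm = _as_pair_arrays(ref, cgm)
    if ref.size < 2:
        raise ValueError("need at least 2 pairs")
    d = cgm - ref
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return bias, sd, bias - LOA_FACTOR * sd, bias + LOA_FACTOR * sd


def pcv(values) -> float:
    """Population coefficient of variation, %: (1 + 1/(4N)) * CV."""
    values = np.asarray(values, dtype=float).ravel()
    if values.size < 2:
        raise ValueError("need at least 2 values")
    mean = values.mean()
    if mean <= 0:
        raise ValueError("mean must be positive")
    cv = 100.0 * np.std(values, ddof=1) / mean
    return float((1.0 + 1.0 / (4.0 * values.size)) * cv)


class AgreementAnalysis(BaseEstimator):
    """Paired-sample agreement evaluator.

    ``fit(ref, cgm)`` consumes matched reference/device glucose values (mg/dl)
    and exposes the full agreement summary as fitted attributes.  The PCV is
    computed on the per-pair device/reference ratios (dispersion of the device
    relative to the reference) with N = number of pairs.

    Parameters
    ----------
    loa_factor : float, default 2.0
        Multiplier on the SD of differences for the limits of agreement.

    Attributes
    ----------
    n_pairs_, slope_, intercept_, r2_, mard_pct_, bias_mg_dl_,
    sd_bias_mg_dl_, loa_low_mg_dl_, loa_high_mg_dl_, pcv_pct_
    """

    def __init__(self, loa_factor: float = LOA_FACTOR):
        self.loa_factor = loa_factor

    def fit(self, ref, cgm) -> "AgreementAnalysis":
        ref, cgm = _as_pair_arrays(ref, cgm)
        self.n_pairs_ = int(ref.size)
        self.slope_, self.intercept_, self.r2_ = fit_regression(ref, cgm)
        self.mard_pct_ = mard(ref, cgm)
        d = cgm - ref
        self.bias_mg_dl_ = float(np.mean(d))
        self.sd_bias_mg_dl_ = float(np.std(d, ddof=1))
        self.loa_low_mg_dl_ = self.bias_mg_dl_ - self.loa_factor * self.sd_bias_mg_dl_
        self.loa_high_mg_dl_ = self.bias_mg_dl_ + self.loa_factor * self.sd_bias_mg_dl_
        self.pcv_pct_ = pcv(cgm / ref)
        return self

    def summary(self) -> AgreementSummary:
        return AgreementSummary(
            n_pairs=self.n_pairs_,
            slope=self.slope_,
            intercept=self.intercept_,
            r2=self.r2_,
            mard_pct=self.mard_pct_,
            bias_mg_dl=self.bias_mg_dl_,
            sd_bias_mg_dl=self.sd_bias_mg_dl_,
            loa_low_mg_dl=self.loa_low_mg_dl_,
            loa_high_mg_dl=self.loa_high_mg_dl_,
            pcv_pct=self.pcv_pct_,
        )
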