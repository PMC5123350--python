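"""Device accuracy against the three point-accuracy standards.

Each standard is expressed as one or two reusable accuracy bands.  A band
splits the reference range at a threshold: below it an absolute tolerance in
mg/dl applies, at/above it a relative tolerance in percent; the standard
requires a stated fraction of measurements inside the band.

* ISO 15197:2013 — 95% within 15 mg/dl (ref < 100) or 15% (ref >= 100).
* FDA 2014 draft guidance — 99% within 7 mg/dl (ref <= 70) or 10% (ref > 70),
  and additionally 100% within 15 mg/dl / 20%.
* 2013 consensus recommendation for CGM — 98% within 10 mg/dl (ref < 100) or
  12.5% (ref >= 100), with the remaining measurements all within 20%.

Strata boundary conventions (the texts use strict inequalities that leave the
threshold itself unassigned): the exact split value joins the relative-
tolerance stratum for 100 mg/dl splits and the absolute-tolerance stratum for
70 mg/dl splits; tolerance comparisons are inclusive ("within 15 mg/dl" means
|difference| <= 15).
"""

from __future__ import annotations

from dataclasses import dataclass


import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator


@dataclass(frozen=True)
class AccuracyBand:
    """Split-tolerance accuracy band.

    ``split_in_low`` controls which stratum the exact split value joins
    (True: the absolute-tolerance stratum below the split).
    """

    ref_split_mg_dl: float
    low_abs_tol_mg_dl: float
    high_rel_tol_pct: float
    required_pct: float
    split_in_low: bool = False

    def __post_init__(self) -> None:
        if self.low_abs_tol_mg_dl <= 0 or self.high_rel_tol_pct <= 0:
            raise ValueError("tolerances must be positive")
        if not 0 < self.required_pct <= 100:
            raise ValueError("required_pct must be in (0, 100]")

    def low_mask(self, ref: np.ndarray) -> np.ndarray:
        if self.split_in_low:
            return ref <= self.ref_split_mg_dl
        return ref < self.ref_split_mg_dl

    def within(self, ref: np.ndarray, cgm: np.ndarray) -> np.ndarray:
        err = np.abs(cgm - ref)
        low = self.low_mask(ref)
        return np.where(low, err <= self.low_abs_tol_mg_dl,
                        err <= ref * self.high_rel_tol_pct / 100.0)


ISO_15197_BAND = AccuracyBand(100.0, 15.0, 15.0, 95.0, split_in_low=False)
FDA_2014_PRIMARY = AccuracyBand(70.0, 7.0, 10.0, 99.0, split_in_low=True)
FDA_2014_SECONDARY = AccuracyBand(70.0, 15.0, 20.0, 100.0, split_in_low=True)
CONSENSUS_2013_BAND = AccuracyBand(100.0, 10.0, 12.5, 98.0, split_in_low=False)
#: consensus remainder rule: everything outside the primary band within 20%
CONSENSUS_REMAINDER_REL_PCT = 20.0


@dataclass(frozen=True)
class BandResult:
    """Observed performance against one accuracy band."""

    criterion: str
    n: int
    n_within: int
    pct_within: float
    required_pct: float
    passed: bool
    n_low: int
    n_low_within: int
    pct_low_within: float
    n_high: int
    n_high_within: int
    pct_high_within: float


@dataclass(frozen=True)
class StandardResult:
    standard: str
    bands: tuple[BandResult, ...]
    passed: bool


@dataclass(frozen=True)
class StandardsResult:
    iso15197: StandardResult
    fda2014: StandardResult
    consensus2013: StandardResult

    def as_frame(self) -> pd.DataFrame:
        """Long-format report: standard,criterion,stratum,n,percent_within,required,pass."""
        rows = []
        for res in (self.iso15197, self.fda2014, self.consensus2013):
            for b in res.bands:
                for stratum, n, pct in (
                        ("low", b.n_low, b.pct_low_within),
                        ("high", b.n_high, b.pct_high_within),
                        ("combined", b.n, b.pct_within)):
                    rows.append({
                        "standard": res.standard, "criterion": b.criterion,
                        "stratum": stratum, "n": n, "percent_within": pct,
                        "required": b.required_pct if stratum == "combined" else "",
                        "pass": b.passed if stratum == "combined" else "",
                    })
        return pd.DataFrame(rows)


def _pct(num: int, den: int) -> float:
    return 100.0 * num / den if den else 100.0


def _band_result(criterion: str, band: AccuracyBand,
                 ref: np.ndarray, cgm: np.ndarray) -> BandResult:
    within = band.within(ref, cgm)
    low = band.low_mask(ref)
    n = int(ref.size)
    n_within = int(within.sum())
    pct = _pct(n_within, n)
    return BandResult(
        criterion=criterion, n=n, n_within=n_within, pct_within=pct,
        required_pct=band.required_pct, passed=pct >= band.required_pct,
        n_low=int(low.sum()), n_low_within=int((within & low).sum()),
        pct_low_within=_pct(int((within & low).sum()), int(low.sum())),
        n_high=int((~low).sum()), n_high_within=int((within & ~low).sum()),
        pct_high_within=_pct(int((within & ~low).sum()), int((~low).sum())),
    )


def _check(ref, cgm) -> tuple[np.ndarray, np.ndarray]:
    ref = np.asarray(ref, dtype=float).ravel()
    cgm = np.asarray(cgm, dtype=float).ravel()
    if ref.size == 0:
        raise ValueError("no pairs")
    if ref.shape != cgm.shape:
        raise ValueError("length mismatch")
    if (ref <= 0).any() or (cgm <= 0).any():
        raise ValueError("glucose values must be positive")
    return ref, cgm


def evaluate_iso15197(ref, cgm) -> StandardResult:
    """ISO 15197:2013 — 95% within 15 mg/dl (ref < 100) / 15% (ref >= 100)."""
    ref, cgm = _check(ref, cgm)
    band = _band_result("within 15 mg/dl or 15%", ISO_15197_BAND, ref, cgm)
    return StandardResult("ISO 15197:2013", (band,), band.passed)


def evaluate_fda2014(ref, cgm) -> StandardResult:
    """FDA 2014 draft — 99% within 7 mg/dl / 10% and 100% within 15 mg/dl / 20%."""
    ref, cgm = _check(ref, cgm)
    primary = _band_result("within 7 mg/dl or 10%", FDA_2014_PRIMARY, ref, cgm)
    secondary = _band_result("within 15 mg/dl or 20%", FDA_2014_SECONDARY, ref, cgm)
    return StandardResult("FDA 2014 draft", (primary, secondary),
                          primary.passed and secondary.passed)


def evaluate_consensus2013(ref, cgm) -> StandardResult:
    """2013 consensus — 98% within 10 mg/dl / 12.5%, remainder all within 20%."""
    ref, cgm = _check(ref, cgm)
    primary = _band_result("within 10 mg/dl or 12.5%", CONSENSUS_2013_BAND,
                           ref, cgm)
    outside = ~CONSENSUS_2013_BAND.within(ref, cgm)
    rel_ok = np.abs(cgm - ref) <= ref * CONSENSUS_REMAINDER_REL_PCT / 100.0
    n_out = int(outside.sum())
    n_out_ok = int((outside & rel_ok).sum())
    remainder = BandResult(
        criterion="remainder within 20%", n=n_out, n_within=n_out_ok,
        pct_within=_pct(n_out_ok, n_out), required_pct=100.0,
        passed=n_out_ok == n_out,
        n_low=0, n_low_within=0, pct_low_within=100.0,
        n_high=n_out, n_high_within=n_out_ok, pct_high_within=_pct(n_out_ok, n_out),
    )
    return StandardResult("2013 consensus", (primary, remainder),
                          primary.passed and remainder.passed)


class AccuracyStandards(BaseEstimator):
    """Evaluate paired values against all three standards.

    Fitted attributes: ``iso15197_``, ``fda2014_``, ``consensus2013_``
    (:class:`StandardResult` each) and ``result_`` bundling them.
    """

    def fit(self, ref, cgm) -> "AccuracyStandards":
        self.iso15197_ = evaluate_iso15197(ref, cgm)
        self.fda2014_ = evaluate_fda2014(ref, cgm)
        self.consensus2013_ = evaluate_consensus2013(ref, cgm)
        self.result_ = StandardsResult(self.iso15197_, self.fda2014_,
                                       self.consensus2013_)
        return self
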