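"""Glycemic states, time in range, and glycemic-variability indices.

State thresholds (mg/dl): severe hypoglycemia < 40, mild hypoglycemia 40-70,
below target 70-80 (exclusive), in target 80-150 (inclusive), above target
150-180, severe hyperglycemia > 180.  Time in range is the count-based
percentage of readings inside [80, 150].

Six per-patient variability indices, each computed over a window (for the
device trace, the interval spanned by the reference draws):

* SD — sample standard deviation of the readings, mg/dl.
* MAGE — mean amplitude of glycemic excursions: mean amplitude of swings
  between consecutive turning points exceeding one window SD, counted in the
  direction of the first qualifying excursion.
* MGC — maximal glucose change: window range max - min, mg/dl.
* J-index — 0.001 * (mean + SD)^2, (mg/dl)^2.
* GVI — glucose variability index: traced path length over the straight
  chord, with time in minutes and glucose in mg/dl on the two axes;
  dimensionless, >= 1.
* GLI — glucose lability index: sum over consecutive readings of
  (delta glucose)^2 / (delta t in hours); reported as the raw window sum, a
  per-hour-normalized variant behind a flag.

Cross-cadence comparison: per index, Pearson correlation across patients of
(device-derived, reference-derived) values plus Bland-Altman bias with
limits at 2.0 SD.  Time-weighted indices (GVI, GLI) degrade much faster under
sparse sampling than the time-independent SD, MGC and J-index.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

from .io import GlucoseTrace

TARGET_RANGE_MG_DL = (80.0, 150.0)

INDEX_NAMES = ("sd", "mage", "mgc", "j_index", "gvi", "gli")


class GlycemicState(str, Enum):
    SEVERE_HYPO = "severe_hypo"
    MILD_HYPO = "mild_hypo"
    BELOW_TARGET = "below_target"
    IN_TARGET = "in_target"
    ABOVE_TARGET = "above_target"
    SEVERE_HYPER = "severe_hyper"


def classify_state(value: float) -> GlycemicState:
    """Map one glucose value (mg/dl) to its glycemic state."""
    if value <= 0:
        raise ValueError(f"non-positive glucose {value}")
    if value < 40:
        return GlycemicState.SEVERE_HYPO
    if value <= 70:
        return GlycemicState.MILD_HYPO
    if value < 80:
        return GlycemicState.BELOW_TARGET
    if value <= 150:
        return GlycemicState.IN_TARGET
    if value <= 180:
        return GlycemicState.ABOVE_TARGET
    return GlycemicState.SEVERE_HYPER


def time_in_range(values) -> float:
    """Percent of readings inside the [80, 150] mg/dl target, bounds inclusive."""
    values = _values_array(values, minimum=1)
    lo, hi = TARGET_RANGE_MG_DL
    return float(100.0 * np.mean((values >= lo) & (values <= hi)))


def _values_array(values, minimum: int) -> np.ndarray:
    if isinstance(values, GlucoseTrace):
        values = values.values()
    values = np.asarray(values, dtype=float).ravel()
    if values.size < minimum:
        raise ValueError(f"need at least {minimum} readings, got {values.size}")
    return values


def sd_index(values) -> float:
    """Sample SD (n-1) of the window's readings, mg/dl."""
    return float(np.std(_values_array(values, 2), ddof=1))


def mgc(values) -> float:
    """Maximal glucose change: window max minus min, mg/dl."""
    v = _values_array(values, 1)
    return float(v.max() - v.min())


def j_index(values) -> float:
    """J-index 0.001 * (mean + SD)^2, in (mg/dl)^2."""
    v = _values_array(values, 2)
    return float(0.001 * (v.mean() + np.std(v, ddof=1)) ** 2)


def _turning_points(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Collapse equal runs, then keep endpoints plus interior direction
    changes.  Returns (turning values, interior flag per turning point)."""
    v = values[np.concatenate(([True], np.diff(values) != 0))]
    if v.size <= 2:
        return v, np.zeros(v.size, dtype=bool)
    d = np.sign(np.diff(v))
    interior = np.concatenate(([False], d[1:] != d[:-1], [False]))
    keep = interior.copy()
    keep[0] = keep[-1] = True
    return v[keep], interior[keep]


def mage(values) -> float:
    """Mean amplitude of glycemic excursions.

    Excursions are swings between consecutive turning points (at least one of
    which is a genuine interior peak/nadir, so a monotone series has none)
    with amplitude exceeding one sample SD of the window; their amplitudes are
    averaged in the direction — rise or fall — of the first qualifying
    excursion.  Returns 0 when no excursion qualifies.
    """
    v = _values_array(values, 3)
    sd = np.std(v, ddof=1)
    tp, interior = _turning_points(v)
    amps, dirs = [], []
    for i in range(tp.size - 1):
        if not (interior[i] or interior[i + 1]):
            continue
        amp = tp[i + 1] - tp[i]
        if abs(amp) > sd:
            amps.append(abs(amp))
            dirs.append(np.sign(amp))
    if not amps:
        return 0.0
    first_dir = dirs[0]
    sel = [a for a, s in zip(amps, dirs) if s == first_dir]
    return float(np.mean(sel))


def _times_values(trace) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(trace, GlucoseTrace):
        return trace.times(), trace.values()
    times, values = trace
    return (np.asarray(times, dtype=float).ravel(),
            np.asarray(values, dtype=float).ravel())


def gvi(trace) -> float:
    """Glucose variability index: path length / chord length, time axis in
    minutes, glucose axis in mg/dl."""
    t, v = _times_values(trace)
    if t.size < 2:
        raise ValueError("need at least 2 timestamped readings")
    span = t[-1] - t[0]
    if span <= 0:
        raise ValueError("zero total time span")
    path = float(np.sum(np.hypot(np.diff(t), np.diff(v))))
    chord = float(np.hypot(span, v[-1] - v[0]))
    return path / chord


def gli(trace, per_hour: bool = False) -> float:
    """Glucose lability index: sum of (delta glucose)^2 / delta t (hours).

    ``per_hour=True`` divides the window sum by the window duration in hours.
    """
    t, v = _times_values(trace)
    if t.size < 2:
        raise ValueError("need at least 2 timestamped readings")
    dt_h = np.diff(t) / 60.0
    if (dt_h <= 0).any():
        raise ValueError("time gaps must be positive")
    total = float(np.sum(np.diff(v) ** 2 / dt_h))
    if per_hour:
        total /= float((t[-1] - t[0]) / 60.0)
    return total


@dataclass(frozen=True)
class VariabilityIndices:
    """The six indices plus window bookkeeping for one patient and source."""

    patient_id: str
    source: str
    sd_mg_dl: float
    mage_mg_dl: float
    mgc_mg_dl: float
    j_index: float
    gvi: float
    gli: float
    window_h: float
    n_readings: int

    def by_name(self, name: str) -> float:
        return {
            "sd": self.sd_mg_dl, "mage": self.mage_mg_dl,
            "mgc": self.mgc_mg_dl, "j_index": self.j_index,
            "gvi": self.gvi, "gli": self.gli,
        }[name]


class GlycemicVariability(BaseEstimator):
    """Variability-index extractor for one timestamped glucose window.

    ``fit(times_min, values)`` exposes ``sd_``, ``mage_``, ``mgc_``,
    ``j_index_``, ``gvi_``, ``gli_`` plus ``window_h_`` and ``n_readings_``.

    Parameters
    ----------
    gli_per_hour : bool, default False
        Report GLI normalized by the window duration instead of the raw sum.
    """

    def __init__(self, gli_per_hour: bool = False):
        self.gli_per_hour = gli_per_hour

    def fit(self, times_min, values) -> "GlycemicVariability":
        t = np.asarray(times_min, dtype=float).ravel()
        v = np.asarray(values, dtype=float).ravel()
        if t.size != v.size:
            raise ValueError("times and values must have equal length")
        if t.size < 2:
            raise ValueError("need at least 2 readings in the window")
        self.n_readings_ = int(t.size)
        self.window_h_ = float((t[-1] - t[0]) / 60.0)
        self.sd_ = sd_index(v)
        self.mage_ = mage(v) if t.size >= 3 else 0.0
        self.mgc_ = mgc(v)
        self.j_index_ = j_index(v)
        self.gvi_ = gvi((t, v))
        self.gli_ = gli((t, v), per_hour=self.gli_per_hour)
        return self


def indices_for_patient(trace: GlucoseTrace,
                        window: tuple[float, float] | None = None,
                        gli_per_hour: bool = False) -> VariabilityIndices:
    """All six indices for one source over a window.

    For the device trace pass the interval spanned by the patient's reference
    draws so both sources cover the same period; for the reference source the
    draws themselves are the readings and the window defaults to their span.
    """
    if window is not None:
        trace = trace.restrict(window[0], window[1])
    t, v = trace.times(), trace.values()
    if t.size < 2:
        raise ValueError(
            f"window holds {t.size} readings for {trace.patient_id}; need >= 2")
    gv = GlycemicVariability(gli_per_hour=gli_per_hour).fit(t, v)
    return VariabilityIndices(
        patient_id=trace.patient_id, source=trace.source,
        sd_mg_dl=gv.sd_, mage_mg_dl=gv.mage_, mgc_mg_dl=gv.mgc_,
        j_index=gv.j_index_, gvi=gv.gvi_, gli=gv.gli_,
        window_h=gv.window_h_, n_readings=gv.n_readings_,
    )


@dataclass(frozen=True)
class IndexAgreement:
    index: str
    pearson_r: float
    mean_diff: float
    loa_low: float
    loa_high: float


@dataclass(frozen=True)
class IndexComparison:
    """Per-index accuracy (Pearson r) and bias (Bland-Altman, 2.0 SD limits)
    of device-derived against reference-derived per-patient indices."""

    n_patients: int
    per_index: dict[str, IndexAgreement]

    def correlations(self) -> dict[str, float]:
        return {k: v.pearson_r for k, v in self.per_index.items()}


def compare_indices(
    pairs: Sequence[tuple[VariabilityIndices, VariabilityIndices]],
) -> IndexComparison:
    """Compare per-patient index pairs (device-derived, reference-derived).

    Differences are device minus reference; limits of agreement at
    mean +/- 2.0 sample SD.
    """
    if len(pairs) < 3:
        raise ValueError("need at least 3 patients with both sources")
    out: dict[str, IndexAgreement] = {}
    for name in INDEX_NAMES:
        a = np.array([p[0].by_name(name) for p in pairs], dtype=float)
        b = np.array([p[1].by_name(name) for p in pairs], dtype=float)
        if np.ptp(a) == 0 and np.ptp(b) == 0:
            r = 1.0
        elif np.ptp(a) == 0 or np.ptp(b) == 0:
            r = float("nan")
        else:
            r = float(stats.pearsonr(a, b).statistic)
        d = a - b
        mean_diff = float(d.mean())
        sd = float(np.std(d, ddof=1))
        out[name] = IndexAgreement(name, r, mean_diff,
                                   mean_diff - 2.0 * sd, mean_diff + 2.0 * sd)
    return IndexComparison(n_patients=len(pairs), per_index=out)


@dataclass(frozen=True)
class GlycemiaSummary:
    """Per-source glycemic-state tallies and time in range."""

    source: str
    n_values: int
    state_counts: dict[str, int]
    state_percents: dict[str, float]
    patients_per_state: dict[str, int]
    tir_pct: float


def summarize_glycemia(per_patient_values: dict[str, Sequence[float]],
                       source: str) -> GlycemiaSummary:
    """State tallies pooled over measurements plus patient-level counts."""
    state_counts = {s.value: 0 for s in GlycemicState}
    patients = {s.value: 0 for s in GlycemicState}
    all_values = []
    for values in per_patient_values.values():
        seen = set()
        for v in values:
            s = classify_state(float(v)).value
            state_counts[s] += 1
            seen.add(s)
        for s in seen:
            patients[s] += 1
        all_values.extend(float(v) for v in values)
    n = len(all_values)
    if n == 0:
        raise ValueError("no values to summarize")
    percents = {s: 100.0 * c / n for s, c in state_counts.items()}
    return GlycemiaSummary(source=source, n_values=n, state_counts=state_counts,
                           state_percents=percents, patients_per_state=patients,
                           tir_pct=time_in_range(np.array(all_values)))
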