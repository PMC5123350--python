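"""Core data types, CSV readers/writers, pairing and downtime accounting.

Glucose time series live on a per-patient clock in minutes since the start of
monitoring.  Two sources exist: a continuous monitor (``cgm``) that reads on a
nominal fixed cadence (15 min by default) and a laboratory ``reference``
analyzer sampled intermittently, each draw measured in duplicate.  The unit of
analysis downstream is the *paired sample*: one reference draw matched to the
nearest in-time valid CGM reading.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

Status = Literal["ok", "no_read", "down"]
Source = Literal["cgm", "reference"]

#: physiologically admissible glucose range, mg/dl (open interval)
GLUCOSE_RANGE = (0.0, 1000.0)


class TraceFormatError(ValueError):
    """Raised when a trace/reference CSV violates the expected dialect."""


@dataclass(frozen=True)
class GlucoseReading:
    """One timestamped glucose observation from a single source.

    ``value`` is present iff ``status == "ok"``; a ``no_read`` is a monitor
    failure at an expected reading slot, ``down`` any other cause of a missing
    reading (cartridge, catheter, disconnection).
    """

    time_min: float
    value: float | None
    status: Status = "ok"

    def __post_init__(self) -> None:
        if self.time_min < 0:
            raise ValueError(f"negative time {self.time_min}")
        if self.status == "ok":
            if self.value is None:
                raise ValueError("ok reading requires a value")
            if not (GLUCOSE_RANGE[0] < self.value < GLUCOSE_RANGE[1]):
                raise ValueError(f"glucose {self.value} mg/dl out of range")
        elif self.value is not None:
            raise ValueError(f"status {self.status!r} must not carry a value")


@dataclass
class GlucoseTrace:
    """Time-sorted readings from one source for one patient."""

    patient_id: str
    source: Source
    readings: list[GlucoseReading]
    expected_cadence_min: float | None = None

    def __post_init__(self) -> None:
        times = [r.time_min for r in self.readings]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("reading times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.readings)

    @property
    def ok_readings(self) -> list[GlucoseReading]:
        return [r for r in self.readings if r.status == "ok"]

    def times(self, ok_only: bool = True) -> np.ndarray:
        rs = self.ok_readings if ok_only else self.readings
        return np.array([r.time_min for r in rs], dtype=float)

    def values(self) -> np.ndarray:
        return np.array([r.value for r in self.ok_readings], dtype=float)

    def restrict(self, start_min: float, end_min: float) -> "GlucoseTrace":
        """Trace restricted to readings with start_min <= t <= end_min."""
        kept = [r for r in self.readings if start_min <= r.time_min <= end_min]
        return GlucoseTrace(self.patient_id, self.source, kept,
                            self.expected_cadence_min)


@dataclass(frozen=True)
class ReferenceDraw:
    """One reference blood draw measured in replicate on the same analyzer."""

    time_min: float
    replicate_values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.replicate_values) < 1:
            raise ValueError("a draw needs at least one replicate")
        if any(v <= 0 for v in self.replicate_values):
            raise ValueError("replicate values must be positive")

    @property
    def mean_value(self) -> float:
        return float(np.mean(self.replicate_values))


@dataclass(frozen=True)
class PairedSample:
    """A reference draw time-matched with a CGM reading."""

    time_min: float
    ref_value: float
    cgm_value: float

    def __post_init__(self) -> None:
        if self.ref_value <= 0 or self.cgm_value <= 0:
            raise ValueError("paired glucose values must be positive")


@dataclass
class PairedSampleSet:
    """All paired samples for one patient plus unmatched-draw bookkeeping."""

    patient_id: str
    pairs: list[PairedSample]
    n_no_read: int = 0

    def __post_init__(self) -> None:
        times = [p.time_min for p in self.pairs]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("pair times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.pairs)

    def ref_values(self) -> np.ndarray:
        return np.array([p.ref_value for p in self.pairs], dtype=float)

    def cgm_values(self) -> np.ndarray:
        return np.array([p.cgm_value for p in self.pairs], dtype=float)


@dataclass(frozen=True)
class DowntimeSummary:
    """Slot-based availability accounting for one CGM trace.

    ``downtime_pct`` is the percentage of expected reading slots without a
    valid value; ``no_read_pct`` the subset attributable to monitor no-reads.
    """

    downtime_pct: float
    no_read_pct: float
    monitored_hours: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.no_read_pct <= self.downtime_pct <= 100.0):
            raise ValueError("need 0 <= no_read_pct <= downtime_pct <= 100")


# ---------------------------------------------------------------------------
# CSV dialect
#
# Trace CSV:      patient_id,time_min,value,status   (blank status == ok)
# Reference CSV:  patient_id,time_min,replicate,value
# ---------------------------------------------------------------------------

TRACE_COLUMNS = ["patient_id", "time_min", "value", "status"]
REFERENCE_COLUMNS = ["patient_id", "time_min", "replicate", "value"]


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TraceFormatError(f"{path}: missing required columns {missing}")


def read_trace_csv(
    path: str | Path,
    source: Source,
    expected_cadence_min: float | None = 15.0,
) -> GlucoseTrace | list[ReferenceDraw]:
    """Read a per-patient glucose CSV.

    For ``source="cgm"`` returns a :class:`GlucoseTrace`; for
    ``source="reference"`` returns the list of :class:`ReferenceDraw` (rows
    with identical ``time_min`` are the replicates of one draw).  Malformed
    rows raise :class:`TraceFormatError` naming the offending row.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if source == "cgm":
        _require_columns(df, TRACE_COLUMNS, path)
        return _parse_cgm(df, path, expected_cadence_min)
    if source == "reference":
        _require_columns(df, REFERENCE_COLUMNS, path)
        return _parse_reference(df, path)
    raise ValueError(f"unknown source {source!r}")


def _parse_float(raw: str, path, row: int, col: str) -> float:
    try:
        return float(raw)
    except ValueError:
        raise TraceFormatError(
            f"{path}: row {row}: non-numeric {col} {raw!r}") from None


def _parse_cgm(df: pd.DataFrame, path, cadence) -> GlucoseTrace:
    if df.empty:
        raise TraceFormatError(f"{path}: no data rows")
    patient_ids = df["patient_id"].unique()
    if len(patient_ids) != 1:
        raise TraceFormatError(
            f"{path}: expected one patient per file, got {list(patient_ids)}")
    rows: list[tuple[float, GlucoseReading]] = []
    for i, rec in enumerate(df.itertuples(index=False), start=2):
        t = _parse_float(rec.time_min, path, i, "time_min")
        if t < 0:
            raise TraceFormatError(f"{path}: row {i}: negative time {t}")
        status = rec.status.strip() or "ok"
        if status not in ("ok", "no_read", "down"):
            raise TraceFormatError(f"{path}: row {i}: bad status {status!r}")
        value = None
        if status == "ok":
            value = _parse_float(rec.value, path, i, "value")
        try:
            reading = GlucoseReading(t, value, status)  # type: ignore[arg-type]
        except ValueError as exc:
            raise TraceFormatError(f"{path}: row {i}: {exc}") from None
        rows.append((t, reading))
    times = [t for t, _ in rows]
    if times != sorted(times):
        logger.warning("%s: rows not time-sorted; sorting", path)
        rows.sort(key=lambda tr: tr[0])
    return GlucoseTrace(str(patient_ids[0]), "cgm", [r for _, r in rows],
                        expected_cadence_min=cadence)


def _parse_reference(df: pd.DataFrame, path) -> list[ReferenceDraw]:
    if df.empty:
        raise TraceFormatError(f"{path}: no data rows")
    by_time: dict[float, list[float]] = {}
    for i, rec in enumerate(df.itertuples(index=False), start=2):
        t = _parse_float(rec.time_min, path, i, "time_min")
        if t < 0:
            raise TraceFormatError(f"{path}: row {i}: negative time {t}")
        v = _parse_float(rec.value, path, i, "value")
        if v <= 0:
            raise TraceFormatError(f"{path}: row {i}: non-positive value {v}")
        by_time.setdefault(t, []).append(v)
    return [ReferenceDraw(t, tuple(by_time[t])) for t in sorted(by_time)]


def write_trace_csv(trace: GlucoseTrace, path: str | Path) -> None:
    records = [
        {
            "patient_id": trace.patient_id,
            "time_min": r.time_min,
            "value": "" if r.value is None else repr(r.value),
            "status": "" if r.status == "ok" else r.status,
        }
        for r in trace.readings
    ]
    pd.DataFrame.from_records(records, columns=TRACE_COLUMNS).to_csv(
        path, index=False)


def write_reference_csv(
    patient_id: str, draws: Sequence[ReferenceDraw], path: str | Path
) -> None:
    records = [
        {"patient_id": patient_id, "time_min": d.time_min,
         "replicate": k, "value": repr(v)}
        for d in draws
        for k, v in enumerate(d.replicate_values, start=1)
    ]
    pd.DataFrame.from_records(records, columns=REFERENCE_COLUMNS).to_csv(
        path, index=False)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def average_reference_duplicates(
    draws: Sequence[ReferenceDraw],
    patient_id: str = "",
) -> GlucoseTrace:
    """Collapse replicate readings to one value per draw (arithmetic mean)."""
    readings = [GlucoseReading(d.time_min, d.mean_value, "ok")
                for d in sorted(draws, key=lambda d: d.time_min)]
    return GlucoseTrace(patient_id, "reference", readings,
                        expected_cadence_min=None)


def validate_draw_spacing(
    draws: Sequence[ReferenceDraw], min_gap_min: float = 60.0
) -> list[str]:
    """Warn (never drop) when consecutive draws are closer than the protocol
    minimum of one hour."""
    out = []
    for a, b in zip(draws, draws[1:]):
        gap = b.time_min - a.time_min
        if gap < min_gap_min:
            out.append(
                f"draws at {a.time_min:g} and {b.time_min:g} min are "
                f"{gap:g} min apart (< {min_gap_min:g} min)")
    return out


def pair_samples(
    cgm: GlucoseTrace,
    reference: GlucoseTrace,
    tolerance_min: float = 7.5,
) -> PairedSampleSet:
    """Match each reference reading to the nearest valid CGM reading in time.

    Greedy in reference-time order; each CGM reading is used at most once;
    equidistant candidates break toward the earlier reading.  A reference
    reading with no valid CGM reading within ``tolerance_min`` yields no pair
    and increments ``n_no_read`` (the study's "no call").
    """
    if cgm.patient_id != reference.patient_id:
        raise ValueError(
            f"patient mismatch: {cgm.patient_id!r} vs {reference.patient_id!r}")
    cgm_ok = cgm.ok_readings
    used = [False] * len(cgm_ok)
    pairs: list[PairedSample] = []
    n_no_read = 0
    for ref in reference.ok_readings:
        best = None
        best_dist = tolerance_min
        for j, c in enumerate(cgm_ok):
            if used[j]:
                continue
            dist = abs(c.time_min - ref.time_min)
            # strict < keeps the earlier of two equidistant neighbours
            if dist < best_dist or (best is None and dist == best_dist):
                best, best_dist = j, dist
        if best is None:
            n_no_read += 1
            continue
        used[best] = True
        pairs.append(PairedSample(ref.time_min, ref.value, cgm_ok[best].value))
    return PairedSampleSet(reference.patient_id, pairs, n_no_read)


def pool_pairs(sets: Iterable[PairedSampleSet]) -> tuple[np.ndarray, np.ndarray]:
    """Pool (reference, cgm) value arrays across patients."""
    refs, cgms = [], []
    for s in sets:
        refs.append(s.ref_values())
        cgms.append(s.cgm_values())
    if not refs:
        return np.empty(0), np.empty(0)
    return np.concatenate(refs), np.concatenate(cgms)


def compute_downtime(cgm: GlucoseTrace) -> DowntimeSummary:
    """Slot-based downtime on the nominal cadence grid anchored at the first
    reading.

    Expected slots are ``floor(span / cadence) + 1``; a slot counts as covered
    when an ok reading falls within half a cadence of it, as a no-read when the
    nearest flag within half a cadence is ``no_read`` and the slot is not
    covered.
    """
    if cgm.expected_cadence_min is None:
        raise ValueError("trace has no expected cadence")
    if not cgm.readings:
        raise ValueError("empty trace")
    cadence = cgm.expected_cadence_min
    all_times = cgm.times(ok_only=False)
    t0, t1 = all_times[0], all_times[-1]
    span = t1 - t0
    n_slots = int(np.floor(span / cadence + 1e-9)) + 1
    slots = t0 + cadence * np.arange(n_slots)
    half = cadence / 2.0

    ok_times = cgm.times(ok_only=True)
    nr_times = np.array(
        [r.time_min for r in cgm.readings if r.status == "no_read"], dtype=float)

    def _covered(times: np.ndarray) -> np.ndarray:
        if times.size == 0:
            return np.zeros(n_slots, dtype=bool)
        d = np.abs(slots[:, None] - times[None, :])
        return (d <= half + 1e-9).any(axis=1)

    ok_cov = _covered(ok_times)
    nr_cov = _covered(nr_times) & ~ok_cov
    down = n_slots - int(ok_cov.sum())
    return DowntimeSummary(
        downtime_pct=100.0 * down / n_slots,
        no_read_pct=100.0 * int(nr_cov.sum()) / n_slots,
        monitored_hours=span / 60.0,
    )
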