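"""End-to-end study evaluation over a directory of per-patient CSVs.

``run_study`` loads each patient's device trace and reference draws, averages
reference duplicates, pairs the samples, and computes every report section on
the same paired set: pooled agreement statistics, Clarke error-grid summary,
the three accuracy standards, per-source glycemic-state/TIR summaries
(device-side tallies use the paired device values, i.e. the measurements with
a matching reference value), per-patient variability indices over the
reference window, and the device-vs-reference index comparison.

Patients contributing fewer than two paired samples are excluded (logged).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as gio
from .agreement import AgreementAnalysis, AgreementSummary
from .error_grid import ErrorGridSummary, summarize_zones, zone_points
from .standards import AccuracyStandards, StandardsResult
from .variability import (
    GlycemiaSummary,
    IndexComparison,
    VariabilityIndices,
    compare_indices,
    indices_for_patient,
    summarize_glycemia,
)

logger = logging.getLogger(__name__)

MIN_PAIRS_PER_PATIENT = 2


@dataclass
class PatientData:
    patient_id: str
    cgm_trace: gio.GlucoseTrace
    reference_draws: list[gio.ReferenceDraw]


@dataclass
class StudyReport:
    n_patients: int
    n_excluded: int
    monitored_hours: float
    n_reference_draws: int
    n_pairs: int
    n_no_read: int
    downtime_pct: float
    no_read_pct: float
    agreement: AgreementSummary
    error_grid: ErrorGridSummary
    standards: StandardsResult
    glycemia: dict[str, GlycemiaSummary]
    indices: list[VariabilityIndices]
    index_comparison: IndexComparison | None
    points: list[tuple[float, float, str]]


def load_cohort_dir(data_dir: str | Path,
                    cadence_min: float = 15.0) -> list[PatientData]:
    """Load ``<pid>_cgm.csv`` / ``<pid>_reference.csv`` file pairs."""
    data_dir = Path(data_dir)
    cgm_files = sorted(data_dir.glob("*_cgm.csv"))
    if not cgm_files:
        raise FileNotFoundError(f"no *_cgm.csv files under {data_dir}")
    cohort = []
    for cgm_path in cgm_files:
        pid = cgm_path.name[: -len("_cgm.csv")]
        ref_path = data_dir / f"{pid}_reference.csv"
        if not ref_path.exists():
            raise FileNotFoundError(f"missing reference file {ref_path}")
        trace = gio.read_trace_csv(cgm_path, "cgm",
                                   expected_cadence_min=cadence_min)
        draws = gio.read_trace_csv(ref_path, "reference")
        cohort.append(PatientData(pid, trace, draws))
    return cohort


def run_study(cohort: list[PatientData],
              tolerance_min: float = 7.5,
              min_pairs: int = MIN_PAIRS_PER_PATIENT,
              gli_per_hour: bool = False,
              with_variability: bool = True) -> StudyReport:
    """Full evaluation; deterministic given the inputs."""
    if not cohort:
        raise ValueError("empty cohort")

    pair_sets: list[gio.PairedSampleSet] = []
    indices: list[VariabilityIndices] = []
    index_pairs = []
    glyc_ref: dict[str, list[float]] = {}
    glyc_cgm: dict[str, list[float]] = {}
    downtimes = []
    n_excluded = 0
    n_draws_total = 0

    for patient in cohort:
        for w in gio.validate_draw_spacing(patient.reference_draws):
            logger.warning("%s: %s", patient.patient_id, w)
        ref_trace = gio.average_reference_duplicates(
            patient.reference_draws, patient_id=patient.patient_id)
        n_draws_total += len(ref_trace)
        pairs = gio.pair_samples(patient.cgm_trace, ref_trace,
                                 tolerance_min=tolerance_min)
        if len(pairs) < min_pairs:
            logger.info("excluding %s: %d paired sample(s) < %d",
                        patient.patient_id, len(pairs), min_pairs)
            n_excluded += 1
            continue
        pair_sets.append(pairs)
        downtimes.append(gio.compute_downtime(patient.cgm_trace))
        glyc_ref[patient.patient_id] = list(ref_trace.values())
        glyc_cgm[patient.patient_id] = list(pairs.cgm_values())

        if with_variability:
            window = (ref_trace.readings[0].time_min,
                      ref_trace.readings[-1].time_min)
            try:
                cgm_idx = indices_for_patient(patient.cgm_trace, window,
                                              gli_per_hour=gli_per_hour)
                ref_idx = indices_for_patient(ref_trace, None,
                                              gli_per_hour=gli_per_hour)
            except ValueError as exc:
                logger.info("skipping variability for %s: %s",
                            patient.patient_id, exc)
                continue
            indices.extend([cgm_idx, ref_idx])
            index_pairs.append((cgm_idx, ref_idx))

    if not pair_sets:
        raise ValueError("no patient has enough paired samples")

    ref, cgm = gio.pool_pairs(pair_sets)
    n_no_read = sum(s.n_no_read for s in pair_sets)

    agreement = AgreementAnalysis().fit(ref, cgm).summary()
    grid = summarize_zones(ref, cgm, n_no_call=n_no_read)
    standards = AccuracyStandards().fit(ref, cgm).result_
    glycemia = {
        "reference": summarize_glycemia(glyc_ref, "reference"),
        "cgm": summarize_glycemia(glyc_cgm, "cgm"),
    }
    comparison = (compare_indices(index_pairs)
                  if with_variability and len(index_pairs) >= 3 else None)

    return StudyReport(
        n_patients=len(pair_sets),
        n_excluded=n_excluded,
        monitored_hours=float(sum(d.monitored_hours for d in downtimes)),
        n_reference_draws=n_draws_total,
        n_pairs=int(ref.size),
        n_no_read=n_no_read,
        downtime_pct=float(np.average(
            [d.downtime_pct for d in downtimes],
            weights=[d.monitored_hours for d in downtimes])),
        no_read_pct=float(np.average(
            [d.no_read_pct for d in downtimes],
            weights=[d.monitored_hours for d in downtimes])),
        agreement=agreement,
        error_grid=grid,
        standards=standards,
        glycemia=glycemia,
        indices=indices,
        index_comparison=comparison,
        points=zone_points(ref, cgm),
    )


# ---------------------------------------------------------------------------
# report rendering
# ---------------------------------------------------------------------------


def _fmt(x: float) -> str:
    return f"{x:.1f}"


def write_report(report: StudyReport, out_dir: str | Path) -> None:
    """Write the CSV bundle plus a human-readable summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    a = report.agreement
    pd.DataFrame([asdict(a)]).to_csv(out / "agreement.csv", index=False)

    rows = [{"zone": z, "count": report.error_grid.counts[z],
             "percent": _fmt(report.error_grid.percents[z])}
            for z in sorted(report.error_grid.counts)]
    pd.DataFrame(rows).to_csv(out / "error_grid.csv", index=False)
    pd.DataFrame(report.points, columns=["ref", "pred", "zone"]).to_csv(
        out / "error_grid_points.csv", index=False)

    report.standards.as_frame().to_csv(out / "standards.csv", index=False)

    grows = []
    for source, g in report.glycemia.items():
        for state, count in g.state_counts.items():
            grows.append({"source": source, "state": state, "count": count,
                          "percent": _fmt(g.state_percents[state]),
                          "patients": g.patients_per_state[state]})
        grows.append({"source": source, "state": "time_in_range", "count": "",
                      "percent": _fmt(g.tir_pct), "patients": ""})
    pd.DataFrame(grows).to_csv(out / "glycemia.csv", index=False)

    if report.indices:
        pd.DataFrame([
            {"patient_id": i.patient_id, "source": i.source, "sd": i.sd_mg_dl,
             "mage": i.mage_mg_dl, "mgc": i.mgc_mg_dl, "j_index": i.j_index,
             "gvi": i.gvi, "gli": i.gli, "window_h": i.window_h,
             "n_readings": i.n_readings}
            for i in report.indices
        ]).to_csv(out / "variability_indices.csv", index=False)

    if report.index_comparison is not None:
        pd.DataFrame([
            {"index": k, "pearson_r": v.pearson_r, "mean_diff": v.mean_diff,
             "loa_low": v.loa_low, "loa_high": v.loa_high}
            for k, v in report.index_comparison.per_index.items()
        ]).to_csv(out / "variability_comparison.csv", index=False)

    (out / "summary.txt").write_text(render_summary(report))


def render_summary(report: StudyReport) -> str:
    a = report.agreement
    g = report.error_grid
    lines = [
        "Device accuracy and glycemic variability report",
        "=" * 47,
        f"patients analyzed:    {report.n_patients} "
        f"(excluded: {report.n_excluded})",
        f"monitored hours:      {_fmt(report.monitored_hours)}",
        f"reference draws:      {report.n_reference_draws}",
        f"paired samples:       {report.n_pairs} "
        f"(no reading obtained: {report.n_no_read})",
        f"mean downtime:        {_fmt(report.downtime_pct)}% "
        f"(no-read {_fmt(report.no_read_pct)}%)",
        "",
        f"regression:           slope {a.slope:.3f}, "
        f"intercept {a.intercept:.1f} mg/dl, r2 {a.r2:.2f}",
        f"MARD:                 {_fmt(a.mard_pct)}%",
        f"bias (device-ref):    {a.bias_mg_dl:.1f} mg/dl, "
        f"LoA [{a.loa_low_mg_dl:.1f}, {a.loa_high_mg_dl:.1f}]",
        f"PCV:                  {_fmt(a.pcv_pct)}%",
        "",
        "Clarke error grid:    "
        + ", ".join(f"{z} {_fmt(g.percents[z])}%" for z in sorted(g.counts))
        + f"; A+B {_fmt(g.zone_ab_pct)}%; no calls {g.no_call}",
        "",
        "Accuracy standards:",
    ]
    for res in (report.standards.iso15197, report.standards.fda2014,
                report.standards.consensus2013):
        verdict = "PASS" if res.passed else "FAIL"
        parts = [f"{b.criterion}: {_fmt(b.pct_within)}% "
                 f"(required {_fmt(b.required_pct)}%)" for b in res.bands]
        lines.append(f"  {res.standard}: {verdict} — " + "; ".join(parts))
    lines.append("")
    for source, gl in report.glycemia.items():
        lines.append(f"TIR ({source}):       {_fmt(gl.tir_pct)}% "
                     f"of {gl.n_values} values in [80, 150] mg/dl")
    if report.index_comparison is not None:
        lines.append("")
        lines.append("Variability index agreement (device vs reference, "
                     f"n={report.index_comparison.n_patients} patients):")
        for k, v in report.index_comparison.per_index.items():
            lines.append(
                f"  {k:8s} r {v.pearson_r:+.2f}  bias {v.mean_diff:+.2f}  "
                f"LoA [{v.loa_low:.2f}, {v.loa_high:.2f}]")
    return "\n".join(lines) + "\n"
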