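"""Synthetic ICU glucose cohorts.

The generator stands in for clinical data: each simulated patient has a dense
"true" glucose trajectory at 1-min resolution, observed by (a) a continuous
monitor on a fixed cadence with proportional bias/noise and per-slot dropout,
and (b) an intermittent reference analyzer with duplicate readings per draw,
draws at least one hour apart and at most 12 per day.

The truth process is a mean-reverting (Ornstein-Uhlenbeck) diffusion around a
baseline near the 80-150 mg/dl insulin-protocol target band, with two
deterministic templates superimposed to reproduce the characteristic ICU
regimes: transient hyperglycemic spikes (linear rise then decay over 1-3 h)
and, in a configurable fraction of patients, one progressive hypoglycemic
downslope reaching a nadir of 55-70 mg/dl.

Both devices carry proportional (constant-CV) noise, the standard error
structure for glucose meters; with relative noise SD sigma and no bias the
pooled mean absolute relative difference converges to 100*sigma*sqrt(2/pi),
which downstream modules use as an analytic cross-check.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from scipy.signal import lfilter

from .io import (
    GlucoseReading,
    GlucoseTrace,
    ReferenceDraw,
    write_reference_csv,
    write_trace_csv,
)

#: truth is never allowed below this floor (mg/dl)
GLUCOSE_FLOOR = 20.0
#: hard protocol cap on reference draws per 24 h
MAX_DRAWS_PER_DAY = 12


@dataclass
class SimConfig:
    """Cohort-level simulation parameters.

    Defaults emulate the monitored-ICU setting the package targets: 88
    patients observed for about a day each, a 15-min monitor cadence,
    reference draws roughly every 2 h (never closer than 1 h, at most 12 per
    day) read in duplicate, proportional monitor noise of ~9.7% CV (pooled
    MARD near 7.7%), and ~14% of monitor slots lost to downtime of which a
    small fraction are monitor no-reads.
    """

    n_patients: int = 88
    duration_h: float = 24.0
    cgm_cadence_min: float = 15.0
    ref_mean_interval_min: float = 120.0
    baseline_mg_dl: float = 150.0
    reversion_rate_per_h: float = 0.3
    volatility_mg_dl_sqrt_h: float = 25.0
    spike_rate_per_day: float = 2.0
    spike_amp_mg_dl: float = 80.0
    downslope_prob: float = 0.05
    cgm_rel_sigma: float = 0.0965
    cgm_rel_bias: float = 0.0
    ref_rel_sigma: float = 0.02
    downtime_prob: float = 0.14
    no_read_frac: float = 0.12
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be non-negative")
        if self.duration_h <= 0:
            raise ValueError("duration_h must be positive")
        if self.ref_mean_interval_min < 60:
            raise ValueError("ref_mean_interval_min has a 60-min floor")
        for name in ("reversion_rate_per_h", "volatility_mg_dl_sqrt_h",
                     "spike_rate_per_day", "spike_amp_mg_dl",
                     "cgm_rel_sigma", "ref_rel_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("downslope_prob", "downtime_prob", "no_read_frac"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be a probability")

    @classmethod
    def from_mapping(cls, mapping: dict) -> "SimConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**mapping)


@dataclass
class Trajectory:
    """Dense true glucose path at 1-min resolution."""

    times_min: np.ndarray
    values_mg_dl: np.ndarray

    def at(self, t_min: np.ndarray | float) -> np.ndarray:
        return np.interp(t_min, self.times_min, self.values_mg_dl)

    @property
    def span_min(self) -> float:
        return float(self.times_min[-1])


@dataclass
class SimulatedPatient:
    patient_id: str
    truth: Trajectory
    cgm_trace: GlucoseTrace
    reference_draws: list[ReferenceDraw]


def _rng(config_seed: int, patient_seed: int, stream: int) -> np.random.Generator:
    # independent, reproducible substream per (patient, purpose)
    return np.random.default_rng(
        np.random.SeedSequence([config_seed, patient_seed, stream]))


def simulate_truth(config: SimConfig, patient_seed: int) -> Trajectory:
    """Simulate one patient's true glucose path.

    Exact AR(1) discretization of the OU process at 1-min steps starting at
    the baseline, plus spike and downslope templates, floored at 20 mg/dl.
    """
    rng = _rng(config.seed, patient_seed, 0)
    n = int(round(config.duration_h * 60)) + 1
    t = np.arange(n, dtype=float)
    dt_h = 1.0 / 60.0
    theta = config.reversion_rate_per_h
    a = np.exp(-theta * dt_h)
    if theta > 0:
        step_sd = config.volatility_mg_dl_sqrt_h * np.sqrt(
            (1 - a * a) / (2 * theta))
    else:
        step_sd = config.volatility_mg_dl_sqrt_h * np.sqrt(dt_h)
    noise = rng.normal(0.0, step_sd, size=n)
    noise[0] = 0.0
    # x[k] = a x[k-1] + noise[k]  via an IIR filter, then recentre on baseline
    x = lfilter([1.0], [1.0, -a], noise)
    g = config.baseline_mg_dl + x

    g = g + _spike_template(t, config, rng)
    if rng.random() < config.downslope_prob:
        g = _apply_downslope(t, g, rng)
    return Trajectory(t, np.maximum(g, GLUCOSE_FLOOR))


def _spike_template(t: np.ndarray, config: SimConfig,
                    rng: np.random.Generator) -> np.ndarray:
    """Sum of triangular hyperglycemic excursions from a Poisson process."""
    out = np.zeros_like(t)
    if config.spike_rate_per_day <= 0 or config.spike_amp_mg_dl <= 0:
        return out
    expected = config.spike_rate_per_day * (t[-1] / 1440.0)
    n_spikes = rng.poisson(expected)
    for _ in range(n_spikes):
        start = rng.uniform(0.0, t[-1])
        rise = rng.uniform(30.0, 90.0)       # 0.5-1.5 h up
        decay = rng.uniform(30.0, 90.0)      # 0.5-1.5 h down
        amp = config.spike_amp_mg_dl * rng.uniform(0.7, 1.3)
        peak = start + rise
        up = np.clip((t - start) / rise, 0.0, 1.0)
        down = np.clip((t - peak) / decay, 0.0, 1.0)
        out += amp * (up - down)
    return out


def _apply_downslope(t: np.ndarray, g: np.ndarray,
                     rng: np.random.Generator) -> np.ndarray:
    """Overwrite one window with a progressive fall to a hypoglycemic nadir
    (55-70 mg/dl over >= 2 h) and a 1-h linear recovery."""
    span = t[-1]
    fall = rng.uniform(120.0, min(240.0, max(120.0, span / 2)))
    recover = 60.0
    if span <= fall + recover:
        fall = max(span * 0.6, 1.0)
        recover = span - fall
    start = rng.uniform(0.0, span - fall - recover)
    nadir = rng.uniform(55.0, 70.0)
    i0 = int(np.searchsorted(t, start))
    i1 = int(np.searchsorted(t, start + fall))
    i2 = min(int(np.searchsorted(t, start + fall + recover)), len(t) - 1)
    out = g.copy()
    out[i0:i1 + 1] = np.linspace(out[i0], nadir, i1 - i0 + 1)
    if i2 > i1:
        out[i1:i2 + 1] = np.linspace(nadir, g[i2], i2 - i1 + 1)
    return out


def observe_cgm(truth: Trajectory, config: SimConfig,
                patient_seed: int, patient_id: str = "") -> GlucoseTrace:
    """Sample the monitor: one reading per cadence slot with proportional
    bias/noise; each slot independently lost with ``downtime_prob`` (a
    ``no_read_frac`` share of losses flagged as monitor no-reads)."""
    rng = _rng(config.seed, patient_seed, 1)
    slots = np.arange(0.0, truth.span_min + 1e-9, config.cgm_cadence_min)
    true_vals = truth.at(slots)
    eps = rng.normal(0.0, config.cgm_rel_sigma, size=slots.size)
    values = true_vals * (1.0 + config.cgm_rel_bias + eps)
    dropped = rng.random(slots.size) < config.downtime_prob
    no_read = dropped & (rng.random(slots.size) < config.no_read_frac)
    readings = []
    for t, v, d, nr in zip(slots, values, dropped, no_read):
        if d:
            readings.append(GlucoseReading(t, None, "no_read" if nr else "down"))
        else:
            readings.append(GlucoseReading(t, max(float(v), 1.0), "ok"))
    return GlucoseTrace(patient_id, "cgm", readings,
                        expected_cadence_min=config.cgm_cadence_min)


def observe_reference(truth: Trajectory, config: SimConfig,
                      patient_seed: int) -> list[ReferenceDraw]:
    """Sample the reference analyzer.

    Draw times follow a renewal process with gaps 60 min + Exp(mean - 60),
    snapped to the monitor's cadence grid (comparative samples are drawn while
    the monitor is sampling), capped at 12 per 24-h block; each draw yields
    two replicates with independent proportional noise.
    """
    rng = _rng(config.seed, patient_seed, 2)
    mean_extra = max(config.ref_mean_interval_min - 60.0, 0.0)
    cad = config.cgm_cadence_min

    def next_grid(x: float) -> float:
        return float(np.ceil((x - 1e-9) / cad) * cad)

    times: list[float] = []
    t = 0.0
    while True:
        gap = 60.0 + (rng.exponential(mean_extra) if mean_extra > 0 else 0.0)
        snapped = float(round((t + gap) / cad) * cad)
        if times:
            snapped = max(snapped, next_grid(times[-1] + 60.0))
        # rolling 24-h cap: at most 12 draws in any trailing 1440-min window
        while True:
            recent = [u for u in times if u > snapped - 1440.0 + 1e-9]
            if len(recent) < MAX_DRAWS_PER_DAY:
                break
            snapped = next_grid(recent[0] + 1440.0)
        if snapped > truth.span_min + 1e-9:
            break
        times.append(snapped)
        t = snapped
    draws = []
    for tt in times:
        true_val = float(truth.at(tt))
        reps = tuple(
            max(float(true_val * (1.0 + rng.normal(0.0, config.ref_rel_sigma))), 1.0)
            for _ in range(2))
        draws.append(ReferenceDraw(tt, reps))
    return draws


def generate_cohort(config: SimConfig) -> list[SimulatedPatient]:
    """Generate ``n_patients`` independent patients, reproducible from the
    config seed (per-patient substreams, so partial regeneration matches)."""
    cohort = []
    for k in range(config.n_patients):
        pid = f"P{k + 1:04d}"
        truth = simulate_truth(config, k)
        cgm = observe_cgm(truth, config, k, patient_id=pid)
        draws = observe_reference(truth, config, k)
        cohort.append(SimulatedPatient(pid, truth, cgm, draws))
    return cohort


def write_cohort(cohort: Sequence[SimulatedPatient], config: SimConfig,
                 out_dir: str | Path) -> None:
    """Write per-patient trace/reference CSVs plus a manifest of the config."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for p in cohort:
        write_trace_csv(p.cgm_trace, out / f"{p.patient_id}_cgm.csv")
        write_reference_csv(p.patient_id, p.reference_draws,
                            out / f"{p.patient_id}_reference.csv")
    manifest = {"config": asdict(config),
                "patients": [p.patient_id for p in cohort]}
    (out / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=True))


def load_config(path: str | Path, seed: int | None = None) -> SimConfig:
    """Read a key:value (YAML) config file; ``seed`` overrides the file."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: expected a key:value mapping")
    if seed is not None:
        raw["seed"] = int(seed)
    return SimConfig.from_mapping(raw)
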