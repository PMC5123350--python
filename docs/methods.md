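# Methods

This note records the models, conventions and numerical choices behind
`cgmeval`, in the order data flows through the pipeline.

## Data model and pairing

All times are real-valued minutes from the start of each patient's
monitoring; no calendar or timezone handling enters the analysis core.
A monitor (CGM) trace carries one reading per nominal 15-min slot with a
status of `ok`, `no_read` (monitor failure) or `down` (any other cause);
reference draws carry two or more replicate values from the same analyzer
and are collapsed to their unweighted arithmetic mean — the standard
convention for duplicate laboratory reads.

Pairing matches each reference reading to the nearest-in-time `ok` monitor
reading within ±7.5 min (half the monitor cadence, so each draw has at most
one eligible slot; configurable). Matching is greedy in draw order, each
monitor reading is used at most once, and an equidistant tie breaks toward
the earlier reading so results are deterministic. A draw with no eligible
reading is counted as a *no-read* ("no call") rather than dropped silently;
the number of pairs plus no-reads always equals the number of draws.

Downtime is slot-based: expected slots are `floor(span/cadence) + 1` on the
cadence grid anchored at the first reading; a slot is covered when an `ok`
reading lies within half a cadence of it. `downtime_pct` is the percentage
of uncovered slots, `no_read_pct` the subset explained by `no_read` flags.
Draw spacing below the 1-h protocol minimum produces warnings, never
exclusions.

Patients contributing fewer than two paired samples are excluded from the
study-level analysis (logged, count reported).

## Agreement statistics

Ordinary unweighted least squares of device value on reference value; r² is
the squared Pearson correlation of the paired values. MARD uses the
averaged reference value as denominator. Bland–Altman differences are
oriented device − reference; the SD uses the n−1 denominator and the limits
of agreement sit at bias ± 2.0 · SD (the factor is exactly 2.0 here, not
1.96). PCV = (1 + 1/(4N)) · CV. The PCV in the pooled agreement summary is
computed on the per-pair device/reference ratios with N = number of pairs:
the CV of the raw glucose distribution (~29% in a typical ICU cohort) is an
order of magnitude larger than the dispersion figure this statistic is meant
to convey, whereas the ratio CV directly measures the device's relative
scatter (≈ MARD / √(2/π) for unbiased proportional error). The generic
`pcv()` function applies the formula to any value sequence.

## Clarke error grid

The classical piecewise-linear boundaries, evaluated as a fixed decision
list — A if (ref ≤ 70 and pred ≤ 70) or 0.8·ref ≤ pred ≤ 1.2·ref; else E if
(ref ≥ 180, pred ≤ 70) or (ref ≤ 70, pred ≥ 180); else C if (70 ≤ ref ≤ 290,
pred ≥ ref + 110) or (130 ≤ ref ≤ 180, pred ≤ 1.4·ref − 182); else D if
(ref ≥ 240, 70 ≤ pred ≤ 180) or (ref ≤ 175/3, 70 ≤ pred ≤ 180) or
(175/3 ≤ ref ≤ 70, pred ≥ 1.2·ref); else B — with all comparisons inclusive.
The inclusive 20% A-boundary (rather than a strict one) follows the de-facto
reference formulation; the decision-list order makes the assignment
exhaustive and unique, which the test suite verifies against an independent
scalar oracle on every integer point of [1, 450]². Upper/lower sub-zones
(device reading high vs low — the ten-zone view) are available via
`classify_subzone`; summaries collapse to the five letters.

## Accuracy standards

Each standard is an `AccuracyBand`: an absolute tolerance below a reference
split, a relative tolerance at or above it, and a required percentage.
The published texts use strict inequalities (">100", "<100", ">70") that
leave the split value itself unassigned; `cgmeval` assigns ref = 100 to the
relative stratum and ref = 70 to the absolute stratum, and treats "within"
as inclusive (|diff| ≤ tol). Both conventions are configurable on the band.
The consensus standard's remainder rule is implemented literally: pass
requires ≥ 98% inside the primary band *and* every measurement outside it
within 20% relative. Stratum-level and combined percentages are both
reported, since published studies typically print the strata separately.

## Glycemic states, TIR and variability indices

State thresholds: < 40 severe hypoglycemia, 40–70 mild hypoglycemia (the
common "<40 / 41–70" phrasing leaves 40–41 open; the gap closes downward so
40 is mild), 70–80 below target, 80–150 in target (bounds inclusive),
150–180 above target, > 180 severe hyperglycemia. TIR is count-based —
the percentage of readings in [80, 150] — not time-weighted, because it is
compared between a 15-min and an intermittent source as percentages of
values. Device-side state tallies and TIR use the paired device readings
(the measurements with a matching reference value), the reference side uses
all averaged draws.

Per-patient indices are computed on the device trace restricted to the
window spanned by that patient's reference draws, so both sources cover the
same period; reference indices use the intermittent draw values themselves.

- **SD**: sample SD of the window's readings.
- **MAGE**: turning points are the collapsed series' endpoints plus interior
  direction changes (equal-value runs merged first, no smoothing); an
  excursion is a consecutive turning-point pair at least one of which is an
  interior peak/nadir — so a monotone window has none — and qualifies if its
  amplitude exceeds one sample SD of the window. MAGE is the mean amplitude
  of qualifying excursions in the direction (rise or fall) of the first
  qualifying one, 0 if none qualify. Verified against an exhaustive
  enumeration oracle on random series.
- **MGC**: window range (max − min), not the maximal consecutive change —
  both readings of that phrase exist in the literature; the range convention
  is fixed here and documented.
- **J-index**: 0.001 · (mean + SD)², (mg/dl)².
- **GVI**: traced path length over straight chord, with minutes on the time
  axis and mg/dl on the glucose axis. The value depends on this unit choice,
  so it is fixed rather than configurable; a straight line of any slope
  gives exactly 1.
- **GLI**: Σ (Δglucose)² / Δt(h) over consecutive readings, reported as the
  raw window sum (its very wide between-source limits of agreement are a
  known feature of unnormalized sums); a per-hour-normalized variant sits
  behind `gli_per_hour=True`.

The cross-cadence comparison computes, per index, the Pearson correlation
across patients between device-derived and reference-derived values, plus
Bland–Altman bias with 2.0 · SD limits. No within-patient clustering
correction is applied to the pooled agreement statistics — pairs are pooled
across patients, which matches how such studies report them.

## Synthetic cohort generator

The generator emulates a monitored-ICU validation study; its defaults *are*
the study conditions the test suite and acceptance script run under.

Truth process: exact AR(1) discretization of an Ornstein–Uhlenbeck diffusion
at 1-min steps, started at the baseline, floored at 20 mg/dl, with two
deterministic templates: triangular hyperglycemic spikes from a Poisson
process (linear rise 0.5–1.5 h, decay 0.5–1.5 h, amplitude ~ spike_amp
± 30%), and — with per-patient probability `downslope_prob` — one
progressive hypoglycemic ramp to a 55–70 mg/dl nadir over ≥ 2 h with a 1-h
recovery. These reproduce the three regimes seen in ICU traces:
well-controlled fluctuation, glycemic excursions, progressive hypoglycemia.

Observation processes: the monitor reads every `cgm_cadence_min` with
multiplicative error value = truth · (1 + bias + ε), ε ~ N(0, σ²) i.i.d. —
proportional (constant-CV) noise matches glucose-meter error structure and
makes the MARD ↔ σ relationship analytic: with zero bias, pooled MARD →
100 σ √(2/π). Slots drop independently with probability `downtime_prob`
(a `no_read_frac` share flagged as monitor no-reads); dropout is i.i.d., no
burst model. Reference draws follow a renewal process with gaps
60 min + Exp(mean − 60), snapped to the monitor grid (comparative samples
are drawn while the monitor samples — without this, a noise-free device
could not agree exactly with the reference), with a rolling cap of 12 draws
per 24 h; each draw yields two replicates with independent proportional
noise. Seeding uses one master seed with per-(patient, purpose) substreams,
so cohorts are bit-reproducible and stable under partial regeneration.

Defaults: 88 patients × 24 h, baseline 150 mg/dl, reversion 0.3/h,
volatility 25 mg/dl/√h (stationary SD ≈ 32 mg/dl), 2 spikes/day of ~80
mg/dl, downslope probability 0.05, monitor σ = 0.0965 (pooled MARD ≈ 7.7%,
the regime of a well-performing intravascular CGM; r² then lands near
0.85–0.89 given the cohort's glucose variance), zero monitor bias, reference
σ = 0.02 (duplicate-averaged YSI-class precision), draw interval mean 2 h,
downtime 14% with ~12% of losses as no-reads. Problem sizes elsewhere are
chosen for statistical resolution: the analytic-MARD check uses 1000
patients (~11,000 pairs, Monte-Carlo error ≈ 0.8% relative, well inside the
3% check), the cadence-sensitivity check 60 patients.

What the generator does *not* emulate: insulin–glucose pharmacokinetics and
treatment feedback, meal effects, spectroscopic interferents, burst
dropout, site differences (arterial vs venous), or heavy-tailed device
error. Passing tests therefore demonstrate correctness of the metrics and
the qualitative behavior of the pipeline under realistic magnitudes — not
clinical performance of any real device; in particular the low-glucose
strata contain few synthetic samples, so their percentages are noisy.

## Numerical choices and degenerate inputs

Regression requires ≥ 3 pairs and non-degenerate reference variance;
Bland–Altman ≥ 2 pairs; MAGE ≥ 3 readings; GVI a positive time span; GLI
strictly positive gaps; index windows ≥ 2 readings (patients failing this
are skipped from the index comparison with a log line). Constant traces
give SD = MAGE = MGC = GLI = 0, GVI = 1, and a perfect device yields MARD
0, r² 1, limits (0, 0) exactly — floating-point exactness is preserved by
construction (zero-scale noise draws return exactly 0). Percentages in
reports are rendered to one decimal. The Pearson correlation of two
constant index vectors is reported as 1 when both are constant (identical
agreement) and NaN when only one is.

## Known limitations

Repeated-measures corrections (within-patient clustering) are out of scope;
so are alternative error grids (Parkes, surveillance), time-weighted TIR,
and CONGA/MODD/ADRR/LBGI-HBGI indices. GVI/GLI magnitudes are convention-
dependent (units, normalization); compare them only within a fixed
convention.
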