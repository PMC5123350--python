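"""Glycemic states, TIR and the six variability indices."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cgmeval.io import GlucoseReading, GlucoseTrace
from cgmeval.variability import (
    GlycemicState,
    GlycemicVariability,
    VariabilityIndices,
    classify_state,
    compare_indices,
    gli,
    gvi,
    indices_for_patient,
    j_index,
    mage,
    mgc,
    sd_index,
    summarize_glycemia,
    time_in_range,
)


class TestStates:
    @pytest.mark.parametrize("value,state", [
        (39, GlycemicState.SEVERE_HYPO),
        (40, GlycemicState.MILD_HYPO),    # 40-41 gap closed downward
        (55, GlycemicState.MILD_HYPO),
        (70, GlycemicState.MILD_HYPO),
        (75, GlycemicState.BELOW_TARGET),
        (80, GlycemicState.IN_TARGET),
        (150, GlycemicState.IN_TARGET),
        (151, GlycemicState.ABOVE_TARGET),
        (180, GlycemicState.ABOVE_TARGET),
        (181, GlycemicState.SEVERE_HYPER),
    ])
    def test_threshold_boundaries(self, value, state):
        assert classify_state(value) is state

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            classify_state(0.0)

    @given(st.floats(min_value=0.1, max_value=999.0))
    @settings(max_examples=200, deadline=None)
    def test_states_partition_positive_reals(self, v):
        assert classify_state(v) in GlycemicState


class TestTir:
    def test_counting(self):
        assert time_in_range([100, 160, 120, 200]) == 50.0

    def test_all_in_target(self):
        assert time_in_range([100, 100, 100]) == 100.0

    def test_bounds_inclusive(self):
        assert time_in_range([80.0, 150.0]) == 100.0
        assert time_in_range([79.9, 150.1]) == 0.0

    @given(st.lists(st.floats(min_value=30, max_value=400), min_size=1,
                    max_size=20),
           st.lists(st.floats(min_value=30, max_value=400), min_size=1,
                    max_size=20))
    @settings(max_examples=100, deadline=None)
    def test_union_is_count_weighted_mean(self, a, b):
        combined = time_in_range(a + b)
        weighted = (time_in_range(a) * len(a) + time_in_range(b) * len(b)) \
            / (len(a) + len(b))
        assert combined == pytest.approx(weighted)


class TestSimpleIndices:
    def test_constant_series(self):
        v = [100.0] * 5
        assert sd_index(v) == 0.0
        assert mgc(v) == 0.0
        assert j_index(v) == pytest.approx(10.0)  # 0.001 * 100^2

    def test_mgc_is_window_range(self):
        assert mgc([100.0, 150.0, 90.0]) == 60.0

    def test_j_index_substitution(self):
        # mean 150, SD 50 -> 0.001 * 200^2 = 40
        v = np.array([100.0, 150.0, 200.0])
        assert v.std(ddof=1) == pytest.approx(50.0)
        assert j_index(v) == pytest.approx(0.001 * (150 + 50) ** 2)

    def test_minimum_readings_enforced(self):
        with pytest.raises(ValueError):
            sd_index([100.0])
        with pytest.raises(ValueError):
            mage([100.0, 120.0])


def mage_oracle(vals):
    """Independent turning-point enumeration (pure python, exhaustive)."""
    import statistics

    sd = statistics.stdev(vals)
    v = [vals[0]]
    for x in vals[1:]:
        if x != v[-1]:
            v.append(x)
    if len(v) < 3:
        return 0.0
    turn_idx = [i for i in range(1, len(v) - 1)
                if (v[i] - v[i - 1]) * (v[i + 1] - v[i]) < 0]
    pts = [0] + turn_idx + [len(v) - 1]
    interior = [False] + [True] * len(turn_idx) + [False]
    excursions = []
    for k in range(len(pts) - 1):
        if not (interior[k] or interior[k + 1]):
            continue
        amp = v[pts[k + 1]] - v[pts[k]]
        if abs(amp) > sd:
            excursions.append(amp)
    if not excursions:
        return 0.0
    rising = excursions[0] > 0
    chosen = [abs(a) for a in excursions if (a > 0) == rising]
    return statistics.mean(chosen)


class TestMage:
    def test_constant_series_zero(self):
        assert mage([100.0] * 5) == 0.0

    def test_square_wave(self):
        # swings of 80 with window SD ~43.8; first qualifying swing rises
        assert mage([100.0, 180.0, 100.0, 180.0, 100.0]) == pytest.approx(80.0)

    def test_monotone_no_complete_excursion(self):
        assert mage([100.0, 110.0, 120.0]) == 0.0

    def test_plateaus_collapsed(self):
        assert mage([100.0, 100.0, 180.0, 180.0, 100.0, 180.0, 100.0]) == \
            pytest.approx(80.0)

    def test_small_swings_filtered_by_sd(self):
        # large swings set the SD; the 10-unit ripple does not qualify
        series = [100, 200, 100, 200, 100, 110, 100]
        got = mage(series)
        assert got == pytest.approx(mage_oracle(series))
        assert got > 0

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=200, deadline=None)
    def test_agrees_with_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 31))
        if rng.random() < 0.15:          # monotone / constant edge cases
            base = np.sort(rng.integers(80, 200, n).astype(float))
            if rng.random() < 0.5:
                base = np.full(n, 120.0)
            vals = base
        else:
            vals = rng.integers(40, 300, n).astype(float)
        assert mage(vals) == pytest.approx(mage_oracle(list(vals)))


class TestGvi:
    def test_straight_line_is_one(self):
        assert gvi(([0.0, 30.0, 60.0], [100.0, 120.0, 140.0])) == \
            pytest.approx(1.0)

    def test_triangle_geometry(self):
        # up 60 then down 60 over two 60-min legs: L = 2*sqrt(2)*60, L0 = 120
        assert gvi(([0.0, 60.0, 120.0], [100.0, 160.0, 100.0])) == \
            pytest.approx(np.sqrt(2.0))

    def test_collinear_midpoint_invariance(self):
        base = gvi(([0.0, 120.0], [100.0, 160.0]))
        split = gvi(([0.0, 60.0, 120.0], [100.0, 130.0, 160.0]))
        assert split == pytest.approx(base)

    def test_constant_trace_unit_ratio(self):
        assert gvi(([0.0, 60.0, 90.0], [100.0, 100.0, 100.0])) == \
            pytest.approx(1.0)

    def test_zero_span_rejected(self):
        with pytest.raises(ValueError):
            gvi(([5.0], [100.0]))


class TestGli:
    def test_constant_trace_zero(self):
        assert gli(([0.0, 60.0, 120.0], [100.0, 100.0, 100.0])) == 0.0

    def test_single_step(self):
        assert gli(([0.0, 60.0], [100.0, 150.0])) == pytest.approx(2500.0)

    def test_window_sum(self):
        # 50^2/1h + 20^2/2h = 2700
        assert gli(([0.0, 60.0, 180.0], [100.0, 150.0, 130.0])) == \
            pytest.approx(2700.0)

    def test_per_hour_normalization_flag(self):
        raw = gli(([0.0, 60.0, 180.0], [100.0, 150.0, 130.0]))
        assert gli(([0.0, 60.0, 180.0], [100.0, 150.0, 130.0]),
                   per_hour=True) == pytest.approx(raw / 3.0)

    def test_chord_split_invariance_and_superadditivity(self):
        # splitting at a point on the chord leaves GLI unchanged ...
        base = gli(([0.0, 120.0], [100.0, 160.0]))
        on_chord = gli(([0.0, 60.0, 120.0], [100.0, 130.0, 160.0]))
        assert on_chord == pytest.approx(base)
        # ... any off-chord split strictly increases it
        off_chord = gli(([0.0, 60.0, 120.0], [100.0, 150.0, 160.0]))
        assert off_chord > base

    def test_nonpositive_gap_rejected(self):
        with pytest.raises(ValueError):
            gli(([0.0, 0.0], [100.0, 120.0]))


def _trace(times, values, pid="p", source="cgm"):
    readings = [GlucoseReading(float(t), float(v)) for t, v in zip(times, values)]
    return GlucoseTrace(pid, source, readings, expected_cadence_min=15.0)


class TestPatientIndices:
    def test_window_restriction_changes_indices(self):
        t = np.arange(0, 600, 15.0)
        v = np.full(t.size, 120.0)
        v[0] = 300.0  # excursion before the reference window
        full = indices_for_patient(_trace(t, v))
        windowed = indices_for_patient(_trace(t, v), window=(60.0, 585.0))
        assert full.mgc_mg_dl == 180.0
        assert windowed.mgc_mg_dl == 0.0

    def test_identical_traces_identical_indices(self):
        t = np.arange(0, 300, 15.0)
        rng = np.random.default_rng(0)
        v = 120 + rng.normal(0, 20, t.size)
        a = indices_for_patient(_trace(t, v, source="cgm"))
        b = indices_for_patient(_trace(t, v, source="reference"))
        for name in ("sd", "mage", "mgc", "j_index", "gvi", "gli"):
            assert a.by_name(name) == pytest.approx(b.by_name(name))

    def test_subsampling_shrinks_time_weighted_indices(self):
        # hourly subsampling of a dense wiggly trace: GLI and GVI drop,
        # SD nearly unchanged
        t = np.arange(0, 1440.0, 15.0)
        rng = np.random.default_rng(5)
        v = 140 + 40 * np.sin(2 * np.pi * t / 360.0) + rng.normal(0, 10, t.size)
        dense = indices_for_patient(_trace(t, v))
        sparse = indices_for_patient(_trace(t[::4], v[::4]))
        assert sparse.gli < dense.gli
        assert sparse.gvi < dense.gvi
        assert sparse.sd_mg_dl == pytest.approx(dense.sd_mg_dl, rel=0.15)

    def test_sparse_window_rejected(self):
        with pytest.raises(ValueError):
            indices_for_patient(_trace([0.0, 15.0], [100.0, 110.0]),
                                window=(5.0, 10.0))


def _indices(pid, **kw):
    base = dict(sd_mg_dl=10.0, mage_mg_dl=20.0, mgc_mg_dl=30.0, j_index=25.0,
                gvi=1.2, gli=500.0, window_h=24.0, n_readings=90)
    base.update(kw)
    return VariabilityIndices(patient_id=pid, source="cgm", **base)


class TestComparison:
    def test_identical_indices_perfect_agreement(self):
        pairs = [(_indices(f"p{i}", sd_mg_dl=10.0 + i),
                  _indices(f"p{i}", sd_mg_dl=10.0 + i)) for i in range(4)]
        comp = compare_indices(pairs)
        sd = comp.per_index["sd"]
        assert sd.pearson_r == pytest.approx(1.0)
        assert sd.mean_diff == 0.0
        assert (sd.loa_low, sd.loa_high) == (0.0, 0.0)

    def test_anticorrelated_sign(self):
        pairs = [(_indices(f"p{i}", sd_mg_dl=10.0 + i),
                  _indices(f"p{i}", sd_mg_dl=20.0 - i)) for i in range(4)]
        assert compare_indices(pairs).per_index["sd"].pearson_r == \
            pytest.approx(-1.0)

    def test_requires_three_patients(self):
        with pytest.raises(ValueError):
            compare_indices([(_indices("a"), _indices("a"))] * 2)


class TestGlycemiaSummary:
    def test_counts_sum_and_patient_tallies(self):
        summary = summarize_glycemia(
            {"p1": [100, 200, 150], "p2": [35, 100]}, "reference")
        assert summary.n_values == 5
        assert sum(summary.state_counts.values()) == 5
        assert summary.state_counts["severe_hyper"] == 1
        assert summary.patients_per_state["severe_hypo"] == 1
        assert summary.patients_per_state["in_target"] == 2
        assert summary.tir_pct == pytest.approx(100 * 3 / 5)
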