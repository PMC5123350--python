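import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from cgmeval.io import GlucoseReading, GlucoseTrace, ReferenceDraw
from cgmeval.pipeline import PatientData
from cgmeval.simulate import SimConfig, generate_cohort


def cohort_to_patient_data(cohort):
    return [PatientData(p.patient_id, p.cgm_trace, p.reference_draws)
            for p in cohort]


@pytest.fixture(scope="session")
def perfect_cohort():
    """Noise-free, bias-free, fully available monitor: device == truth."""
    config = SimConfig(n_patients=8, duration_h=24.0, cgm_rel_sigma=0.0,
                       cgm_rel_bias=0.0, ref_rel_sigma=0.0,
                       downtime_prob=0.0, seed=11)
    return generate_cohort(config)


@pytest.fixture
def simple_cgm_trace():
    readings = [GlucoseReading(15.0 * k, 100.0 + 5 * k, "ok")
                for k in range(11)]
    return GlucoseTrace("p1", "cgm", readings, expected_cadence_min=15.0)


@pytest.fixture
def simple_draws():
    return [ReferenceDraw(0.0, (100.0, 102.0)),
            ReferenceDraw(90.0, (200.0, 198.0))]
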