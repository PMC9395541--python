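"""Shared fixtures: tiny hand-built patients and small simulated cohorts."""
import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from inflarec.cohort import Cohort, LabSeries, PatientRecord
from inflarec.synth import SimConfig, generate_cohort


def make_patient(pid="P1", age=60.0, los=8.0, death30=False, event_time=0.0,
                 wbc=None, plt=None, **extra_series):
    """Build a PatientRecord from (times, values) tuples."""
    series = {}
    for analyte, data in dict(WBC=wbc, PLT=plt, **extra_series).items():
        if data is None:
            continue
        t, v = data
        series[analyte] = LabSeries(analyte, np.asarray(t, float), np.asarray(v, float))
    return PatientRecord(patient_id=pid, age=age, gender="F",
                         event_time=event_time, discharge_time=los,
                         death30=death30, los=los, series=series)


@pytest.fixture
def simple_patient():
    return make_patient(
        wbc=([-1.0, 0.0, 1.0, 2.0, 3.0], [7.0, 9.0, 16.0, 13.0, 11.0]),
        plt=([-1.0, 0.0, 1.0, 2.0, 3.0], [220.0, 200.0, 160.0, 160.0, 185.0]),
    )


@pytest.fixture(scope="session")
def clean_cohort():
    """200 zero-noise good-outcome patients (session-scoped: read-only)."""
    cfg = SimConfig(n_patients=200, noise_cv=0.0, adverse_fraction=0.0,
                    muted_wbc_fraction=0.0, seed=11)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def noisy_cohort():
    """200 patients at the default 3% analytic CV, no adverse dynamics."""
    cfg = SimConfig(n_patients=200, noise_cv=0.03, adverse_fraction=0.0,
                    muted_wbc_fraction=0.0, seed=12)
    return generate_cohort(cfg)
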