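"""Data model, I/O, resampling, alignment windows and exclusion filters."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from inflarec.cohort import (Cohort, FormatError, LabSeries, apply_exclusions,
                             baseline_mean, find_peak_wbc, modeling_subset,
                             read_cohort, resample_12h, write_cohort)
from .conftest import make_patient


# ---------------------------------------------------------------------------
# LabSeries / I/O
# ---------------------------------------------------------------------------

def test_labseries_rejects_bad_input():
    with pytest.raises(ValueError):
        LabSeries("WBC", [0.0, 0.0], [1.0, 2.0])  # non-increasing times
    with pytest.raises(ValueError):
        LabSeries("WBC", [0.0, 1.0], [1.0, -2.0])  # negative value
    with pytest.raises(ValueError):
        LabSeries("WBC", [0.0, 1.0], [1.0, np.nan])


def _write_series(path, rows):
    pd.DataFrame(rows, columns=["patient_id", "analyte", "time_days", "value",
                                "units"]).to_csv(path, index=False)


def _write_patients(path, pids):
    pd.DataFrame([
        {"patient_id": p, "age": 60, "gender": "F", "event_time": 0.0,
         "discharge_time": 8.0, "death30": 0, "los": 8.0} for p in pids
    ]).to_csv(path, index=False)


def test_read_cohort_basic(tmp_path):
    s, p = tmp_path / "s.csv", tmp_path / "p.csv"
    _write_series(s, [("A", "WBC", -1.0, 7.0, ""), ("A", "WBC", 0.0, 9.0, ""),
                      ("A", "WBC", 1.0, 16.0, "")])
    _write_patients(p, ["A"])
    cohort = read_cohort(s, p, "surgical")
    assert len(cohort) == 1
    assert len(cohort.patients[0].get("WBC")) == 3


def test_read_cohort_duplicate_timestamp_keeps_first(tmp_path):
    s, p = tmp_path / "s.csv", tmp_path / "p.csv"
    _write_series(s, [("A", "WBC", 1.0, 10.0, ""), ("A", "WBC", 1.0, 12.0, ""),
                      ("A", "WBC", 2.0, 9.0, "")])
    _write_patients(p, ["A"])
    cohort = read_cohort(s, p, "surgical")
    wbc = cohort.patients[0].get("WBC")
    assert wbc.values[wbc.times == 1.0] == [10.0]


def test_read_cohort_missing_column_is_format_error(tmp_path):
    s, p = tmp_path / "s.csv", tmp_path / "p.csv"
    pd.DataFrame({"patient_id": ["A"], "analyte": ["WBC"],
                  "time_days": [1.0], "units": [""]}).to_csv(s, index=False)
    _write_patients(p, ["A"])
    with pytest.raises(FormatError):
        read_cohort(s, p, "surgical")


def test_read_cohort_drops_nonfinite_rows(tmp_path):
    s, p = tmp_path / "s.csv", tmp_path / "p.csv"
    _write_series(s, [("A", "WBC", 0.0, 9.0, ""), ("A", "WBC", 1.0, np.nan, ""),
                      ("A", "WBC", 2.0, 8.0, "")])
    _write_patients(p, ["A"])
    cohort = read_cohort(s, p, "surgical")
    assert len(cohort.patients[0].get("WBC")) == 2


def test_write_read_roundtrip(tmp_path, clean_cohort):
    cohort, _ = clean_cohort
    from dataclasses import replace
    small = replace(cohort, patients=cohort.patients[:5])
    write_cohort(small, tmp_path / "s.csv", tmp_path / "p.csv")
    back = read_cohort(tmp_path / "s.csv", tmp_path / "p.csv", "surgical")
    assert len(back) == 5
    for a, b in zip(small.patients, back.patients):
        assert a.patient_id == b.patient_id
        np.testing.assert_allclose(a.get("WBC").values, b.get("WBC").values)
        assert a.death30 == b.death30
        assert a.los == pytest.approx(b.los, rel=1e-12)


# ---------------------------------------------------------------------------
# Resampling / baselines
# ---------------------------------------------------------------------------

def test_resample_linear_midpoint():
    s = LabSeries("WBC", [0.0, 1.0], [10.0, 20.0])
    g = resample_12h(s)
    assert g.times.tolist() == [0.0, 0.5, 1.0]
    assert g.values.tolist() == [10.0, 15.0, 20.0]


def test_resample_single_point_no_extrapolation():
    s = LabSeries("WBC", [0.7], [9.0])
    g = resample_12h(s)
    assert g.times.tolist() == [0.7] and g.values.tolist() == [9.0]


def test_resample_truncates_to_observed_span():
    s = LabSeries("WBC", [0.3, 2.2], [10.0, 20.0])
    g = resample_12h(s, start=0.0, end=5.0)
    assert g.times[0] == 0.5 and g.times[-1] == 2.0


@settings(max_examples=50, deadline=None)
@given(st.lists(st.floats(0.0, 50.0), min_size=2, max_size=12))
def test_resample_idempotent_on_gridded_input(values):
    times = 0.5 * np.arange(len(values))
    s = LabSeries("X", times, values)
    once = resample_12h(s)
    twice = resample_12h(once)
    np.testing.assert_array_equal(once.times, twice.times)
    np.testing.assert_array_equal(once.values, twice.values)


def test_baseline_mean_and_fallback():
    p = make_patient(wbc=([-2.0, -1.0, 0.5], [6.0, 8.0, 12.0]))
    assert baseline_mean(p, "WBC") == 7.0
    q = make_patient(wbc=([0.5, 1.0], [9.0, 12.0]))
    assert baseline_mean(q, "WBC") == 9.0  # first post-event value
    single = make_patient(wbc=([-1.0, 1.0], [7.0, 12.0]))
    assert baseline_mean(single, "WBC") == 7.0
    with pytest.raises(KeyError):
        baseline_mean(p, "PLT")


# ---------------------------------------------------------------------------
# Exclusions
# ---------------------------------------------------------------------------

def test_apply_exclusions_rules():
    ok = make_patient("ok", wbc=([0.0, 1.0], [9.0, 12.0]))
    minor = make_patient("minor", age=17.0, wbc=([0.0, 1.0], [9.0, 12.0]))
    short = make_patient("short", los=1.0, wbc=([0.0, 1.0], [9.0, 12.0]))
    one_cbc = make_patient("one", wbc=([0.0], [9.0]))
    cohort = Cohort("surgical", [ok, minor, short, one_cbc])
    out, counts = apply_exclusions(cohort)
    assert [p.patient_id for p in out.patients] == ["ok"]
    assert counts == {"age_lt_18": 1, "los_lt_2": 1, "lt_2_cbcs": 1}


def test_apply_exclusions_never_grows_and_idempotent(noisy_cohort):
    cohort, _ = noisy_cohort
    out, _ = apply_exclusions(cohort)
    assert len(out) <= len(cohort)
    again, counts = apply_exclusions(out)
    assert len(again) == len(out) and sum(counts.values()) == 0


# ---------------------------------------------------------------------------
# Peak alignment and modeling subset
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("cohort_class,mode,expected", [
    ("surgical", "modeling", 1.0),   # day-5 value is outside the 3-day window
    ("ischemic", "modeling", 1.0),
    ("infectious", "modeling", 5.0),  # entire stay
    ("infectious", "risk", 1.0),      # first 72 h only
])
def test_find_peak_wbc_windows(cohort_class, mode, expected):
    p = make_patient(wbc=([0.0, 1.0, 2.0, 5.0], [12.0, 16.0, 14.0, 18.0]))
    assert find_peak_wbc(p, cohort_class, mode) == expected


def test_find_peak_wbc_tie_breaks_earliest():
    p = make_patient(wbc=([0.0, 1.0, 2.0], [12.0, 16.0, 16.0]))
    assert find_peak_wbc(p, "surgical") == 1.0


def test_find_peak_wbc_requires_window_data():
    p = make_patient(wbc=([-2.0, -1.0], [9.0, 9.0]))
    with pytest.raises(ValueError):
        find_peak_wbc(p, "surgical")


def test_find_peak_matches_window_maximum(noisy_cohort):
    cohort, _ = noisy_cohort
    for p in cohort.patients[:40]:
        t = find_peak_wbc(p, "surgical")
        s = p.get("WBC")
        win = (s.times >= 0) & (s.times <= 3.0)
        assert s.values[s.times == t] == s.values[win].max()


def _pt(pid, rise, days_post_peak):
    times = [0.0, 1.0] + [1.0 + d for d in np.arange(0.5, days_post_peak + 1e-9, 0.5)]
    wbc = [8.0, 8.0 + rise] + [8.0 + rise * np.exp(-0.7 * d)
                               for d in np.arange(0.5, days_post_peak + 1e-9, 0.5)]
    plt = [200.0] * len(times)
    return make_patient(pid, los=times[-1], wbc=(times, wbc), plt=(times, plt))


def test_modeling_subset_rules():
    low_rise = _pt("low", rise=1.5, days_post_peak=7.0)
    short = _pt("short", rise=6.0, days_post_peak=4.9)
    good = _pt("good", rise=6.0, days_post_peak=7.0)
    out = modeling_subset(Cohort("surgical", [low_rise, short, good]))
    assert [p.patient_id for p in out.patients] == ["good"]
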