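"""Cohort data model, CSV I/O, resampling, normalization, alignment and filters.

Conventions
-----------
Time axis
    Real-valued **days relative to the inflammatory event** (end of surgery for
    surgical cohorts, hospital admission for ischemic/infectious cohorts).
    ``t = 0`` is the event; negative times are pre-event (baseline) draws.
Units
    WBC and PLT are reported in 10^3 cells/uL throughout; other analytes keep
    their conventional clinical units.
Cohort classes
    ``surgical`` and ``ischemic`` cohorts align recovery at the peak WBC within
    the first 3 days after the event; ``infectious`` cohorts, whose inflammatory
    onset is uncertain, align at the peak over the entire stay for kinetic
    modeling and at the peak within the first 72 h for risk scoring.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger("inflarec")

COHORT_CLASSES = ("surgical", "ischemic", "infectious")

#: Analyte codes routinely collected for hospitalized patients.
KNOWN_ANALYTES = frozenset(
    {"WBC", "PLT", "HCT", "HGB", "RBC", "RDW", "ANION", "BUN", "CRE", "GLU"}
)

GRID_STEP_DAYS = 0.5  # 12-h resampling grid
PEAK_WINDOW_DAYS = 3.0  # peak-WBC search window after the event

# Cohort exclusion thresholds
MIN_AGE_YEARS = 18.0
MIN_LOS_DAYS = 2.0
MIN_CBC_COUNT = 2

# Kinetic-modeling inclusion thresholds
RISE_THRESHOLD = 2.0  # 10^3/uL minimum inflammation-induced WBC rise
POST_PEAK_SPAN_DAYS = 5.0  # minimum follow-up after peak WBC

SERIES_COLUMNS = ["patient_id", "analyte", "time_days", "value", "units"]
PATIENT_COLUMNS = [
    "patient_id", "age", "gender", "event_time", "discharge_time", "death30", "los",
]


class FormatError(ValueError):
    """Raised when an input file does not match the expected layout."""


@dataclass
class LabSeries:
    """One analyte's longitudinal results for one patient.

    ``times`` are days relative to the event and must be strictly increasing
    (duplicates are resolved at read time, first value wins); ``values`` must be
    finite and non-negative.
    """

    analyte: str
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError(f"{self.analyte}: times must be strictly increasing")
        if self.values.size and (not np.all(np.isfinite(self.values)) or np.any(self.values < 0)):
            raise ValueError(f"{self.analyte}: values must be finite and >= 0")

    def __len__(self) -> int:
        return self.times.size

    def shifted(self, offset: float) -> "LabSeries":
        """Return a copy with ``offset`` subtracted from all times."""
        return LabSeries(self.analyte, self.times - offset, self.values.copy())


@dataclass
class PatientRecord:
    """One patient's demographics, outcomes and analyte series."""

    patient_id: str
    age: float
    gender: str
    event_time: float  # absolute date (days on an arbitrary calendar origin)
    discharge_time: float  # days relative to the event
    death30: bool
    los: float  # length of stay, days
    series: dict = field(default_factory=dict)

    def get(self, analyte: str) -> LabSeries:
        if analyte not in self.series:
            raise KeyError(f"patient {self.patient_id} has no {analyte} series")
        return self.series[analyte]

    def has(self, analyte: str) -> bool:
        return analyte in self.series and len(self.series[analyte]) > 0


@dataclass
class Cohort:
    """A set of patients sharing a cohort class.

    The cohort class controls the peak-WBC alignment window; the cohort's own
    mean LOS controls the long-stay threshold used in outcome definitions
    (adverse if LOS > 10 days when mean LOS < 7 days, LOS > 14 days otherwise).
    """

    cohort_class: str
    patients: list

    def __post_init__(self):
        if self.cohort_class not in COHORT_CLASSES:
            raise ValueError(f"unknown cohort_class {self.cohort_class!r}")

    def __len__(self) -> int:
        return len(self.patients)

    @property
    def mean_los(self) -> float:
        return float(np.mean([p.los for p in self.patients])) if self.patients else float("nan")

    @property
    def los_threshold(self) -> float:
        """Long-stay threshold (days): 10 if the cohort mean LOS < 7, else 14."""
        return 10.0 if self.mean_los < 7.0 else 14.0


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_cohort(series_path, patients_path, cohort_class: str) -> Cohort:
    """Read a cohort from a long-format series CSV and a patient-metadata CSV.

    Duplicate (patient, analyte, timestamp) rows keep the first value; rows
    with non-finite values are dropped; both are logged. Unknown analyte codes
    are logged and retained.
    """
    sdf = pd.read_csv(series_path)
    missing = set(SERIES_COLUMNS) - set(sdf.columns)
    if missing:
        raise FormatError(f"series file missing columns: {sorted(missing)}")
    pdf = pd.read_csv(patients_path)
    missing = set(PATIENT_COLUMNS) - set(pdf.columns)
    if missing:
        raise FormatError(f"patient file missing columns: {sorted(missing)}")

    sdf = sdf.copy()
    sdf["value"] = pd.to_numeric(sdf["value"], errors="coerce")
    bad = ~np.isfinite(sdf["value"].to_numpy(dtype=float))
    if bad.any():
        logger.info("read_cohort: dropped %d non-finite value rows", int(bad.sum()))
        sdf = sdf.loc[~bad]

    ndup = int(sdf.duplicated(subset=["patient_id", "analyte", "time_days"]).sum())
    if ndup:
        logger.info("read_cohort: resolved %d duplicate-timestamp rows (first kept)", ndup)
        sdf = sdf.drop_duplicates(subset=["patient_id", "analyte", "time_days"], keep="first")

    unknown = sorted(set(sdf["analyte"].unique()) - KNOWN_ANALYTES)
    if unknown:
        logger.info("read_cohort: unknown analyte codes retained: %s", unknown)

    series_by_patient: dict[str, dict] = {}
    for (pid, analyte), grp in sdf.groupby(["patient_id", "analyte"], sort=False):
        grp = grp.sort_values("time_days")
        series_by_patient.setdefault(str(pid), {})[analyte] = LabSeries(
            analyte, grp["time_days"].to_numpy(), grp["value"].to_numpy()
        )

    patients = []
    for row in pdf.itertuples(index=False):
        pid = str(row.patient_id)
        patients.append(
            PatientRecord(
                patient_id=pid,
                age=float(row.age),
                gender=str(row.gender),
                event_time=float(row.event_time),
                discharge_time=float(row.discharge_time),
                death30=bool(int(row.death30)),
                los=float(row.los),
                series=series_by_patient.get(pid, {}),
            )
        )
    return Cohort(cohort_class=cohort_class, patients=patients)


def write_cohort(cohort: Cohort, series_path, patients_path) -> None:
    """Write a cohort to the long-format series CSV and patient-metadata CSV."""
    srows = []
    for p in cohort.patients:
        for analyte, s in p.series.items():
            units = "10^3/uL" if analyte in ("WBC", "PLT") else ""
            for t, v in zip(s.times, s.values):
                srows.append((p.patient_id, analyte, t, v, units))
    pd.DataFrame(srows, columns=SERIES_COLUMNS).to_csv(series_path, index=False)
    prows = [
        (p.patient_id, p.age, p.gender, p.event_time, p.discharge_time,
         int(p.death30), p.los)
        for p in cohort.patients
    ]
    pd.DataFrame(prows, columns=PATIENT_COLUMNS).to_csv(patients_path, index=False)


# ---------------------------------------------------------------------------
# Resampling and normalization
# ---------------------------------------------------------------------------

def resample_12h(series: LabSeries, start: float = 0.0, end: float | None = None) -> LabSeries:
    """Linearly interpolate a series onto a 12-h grid anchored at ``start``.

    The grid is truncated to the observed span (no extrapolation). A
    single-point series is returned as-is; an already-gridded series is
    returned unchanged (idempotence).
    """
    if len(series) == 0:
        raise ValueError("cannot resample an empty series")
    if len(series) == 1:
        return LabSeries(series.analyte, series.times.copy(), series.values.copy())
    lo = max(start, series.times[0])
    hi = min(end, series.times[-1]) if end is not None else series.times[-1]
    if hi < lo:
        return LabSeries(series.analyte, np.empty(0), np.empty(0))
    k0 = int(np.ceil((lo - start) / GRID_STEP_DAYS - 1e-9))
    k1 = int(np.floor((hi - start) / GRID_STEP_DAYS + 1e-9))
    grid = start + GRID_STEP_DAYS * np.arange(k0, k1 + 1)
    vals = np.interp(grid, series.times, series.values)
    return LabSeries(series.analyte, grid, vals)


def baseline_mean(patient: PatientRecord, analyte: str) -> float:
    """Mean of all pre-event (t < 0) values of an analyte.

    Falls back (with a log message) to the first post-event value when the
    patient has no pre-event draws.
    """
    s = patient.get(analyte)
    pre = s.values[s.times < 0]
    if pre.size:
        return float(pre.mean())
    logger.info(
        "baseline_mean: patient %s has no pre-event %s; using first post-event value",
        patient.patient_id, analyte,
    )
    return float(s.values[0])


# ---------------------------------------------------------------------------
# Exclusions and alignment
# ---------------------------------------------------------------------------

def apply_exclusions(cohort: Cohort):
    """Apply the cohort exclusion rules; returns (cohort, per-rule counts).

    Removes patients under 18 years, with stays under 2 days, or with fewer
    than 2 WBC measurements. Counts are per rule (a patient failing several
    rules is counted under each), so the rules are order-independent.
    """
    counts = {"age_lt_18": 0, "los_lt_2": 0, "lt_2_cbcs": 0}
    kept = []
    for p in cohort.patients:
        n_wbc = len(p.series.get("WBC", ())) if "WBC" in p.series else 0
        fail = False
        if p.age < MIN_AGE_YEARS:
            counts["age_lt_18"] += 1
            fail = True
        if p.los < MIN_LOS_DAYS:
            counts["los_lt_2"] += 1
            fail = True
        if n_wbc < MIN_CBC_COUNT:
            counts["lt_2_cbcs"] += 1
            fail = True
        if not fail:
            kept.append(p)
    logger.info("apply_exclusions: removed %d of %d (%s)",
                len(cohort) - len(kept), len(cohort), counts)
    return replace(cohort, patients=kept), counts


def find_peak_wbc(patient: PatientRecord, cohort_class: str, mode: str = "modeling") -> float:
    """Time of the peak WBC in the class-specific alignment window.

    Windows: first 3 days after the event for surgical and ischemic cohorts;
    the entire stay for infectious cohorts in ``modeling`` mode, but the first
    72 h in ``risk`` mode (uncertain inflammatory onset). Ties break to the
    earliest time.
    """
    if mode not in ("modeling", "risk"):
        raise ValueError(f"unknown mode {mode!r}")
    if cohort_class not in COHORT_CLASSES:
        raise ValueError(f"unknown cohort_class {cohort_class!r}")
    s = patient.get("WBC")
    if cohort_class == "infectious" and mode == "modeling":
        sel = s.times >= 0
    else:
        sel = (s.times >= 0) & (s.times <= PEAK_WINDOW_DAYS)
    if not np.any(sel):
        raise ValueError(f"patient {patient.patient_id}: no WBC data in alignment window")
    t, v = s.times[sel], s.values[sel]
    return float(t[np.argmax(v)])  # argmax returns the first (earliest) maximum


def modeling_subset(cohort: Cohort) -> Cohort:
    """Patients eligible for kinetic model fitting.

    Keeps patients whose windowed peak WBC exceeds their first observed WBC by
    at least 2 x 10^3/uL (a confident inflammation-induced rise) and who have
    at least 5 days of WBC and PLT data after the peak.
    """
    kept = []
    for p in cohort.patients:
        if not (p.has("WBC") and p.has("PLT")):
            continue
        try:
            t_peak = find_peak_wbc(p, cohort.cohort_class, mode="modeling")
        except ValueError:
            continue
        wbc = p.get("WBC")
        wbc_max = float(wbc.values[np.argmin(np.abs(wbc.times - t_peak))])
        rise = wbc_max - float(wbc.values[0])
        follow_up = min(wbc.times[-1], p.get("PLT").times[-1]) - t_peak
        if rise >= RISE_THRESHOLD and follow_up >= POST_PEAK_SPAN_DAYS:
            kept.append(p)
    logger.info("modeling_subset: kept %d of %d", len(kept), len(cohort))
    return replace(cohort, patients=kept)
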