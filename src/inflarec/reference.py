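"""Favorable mean WBC-PLT trajectory and directional percentile bands.

The reference recovery shape is the pointwise mean of baseline-normalized,
12-h-resampled WBC and PLT series over good-outcome patients (survivors with
LOS under the cohort's long-stay threshold) in an exploratory cohort.
Available-case averaging is used: a patient contributes at a gridpoint only
while in hospital with data spanning it; gridpoints supported by fewer than a
configurable minimum of patients are trimmed, since late-time means would
otherwise be dominated by long-stay patients.

Daily directional bands are the empirical percentiles (midpoint interpolation)
of the angles between each good-outcome patient's 24-h normalized WBC-PLT
change vector and the reference's own daily change vector.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import (Cohort, GRID_STEP_DAYS, LabSeries, baseline_mean,
                     find_peak_wbc, resample_12h)

logger = logging.getLogger("inflarec")

DEFAULT_MAX_DAYS = 14.0
DEFAULT_MIN_PATIENTS = 10
DEFAULT_PERCENTILES = (50.0, 80.0, 90.0)


@dataclass
class ReferenceTrajectory:
    grid: np.ndarray  # days since alignment origin, 12-h spacing
    mean_wbc_norm: np.ndarray
    mean_plt_norm: np.ndarray
    n_contributing: np.ndarray
    alignment: str = "event_time"
    #: day -> (delta WBC_norm, delta PLT_norm) over the preceding 24 h
    daily_change: dict = field(default_factory=dict)
    #: day -> {percentile: angle in degrees}
    direction_percentiles: dict = field(default_factory=dict)

    def value_at(self, t: float) -> tuple[float, float]:
        """Normalized (WBC, PLT) of the mean trajectory at gridpoint ``t``."""
        idx = np.flatnonzero(np.isclose(self.grid, t))
        if idx.size == 0:
            raise KeyError(f"t={t} is not on the reference grid")
        i = int(idx[0])
        return float(self.mean_wbc_norm[i]), float(self.mean_plt_norm[i])


def good_outcome_mask(cohort: Cohort) -> np.ndarray:
    """True for survivors with LOS under the cohort's long-stay threshold."""
    thr = cohort.los_threshold
    return np.array([(not p.death30) and p.los < thr for p in cohort.patients])


def adverse_outcome_mask(cohort: Cohort, los_threshold: float | None = None) -> np.ndarray:
    """True for 30-day deaths or stays longer than the long-stay threshold.

    Pass ``los_threshold`` explicitly to apply an exploratory-cohort-derived
    threshold to a validation cohort.
    """
    thr = cohort.los_threshold if los_threshold is None else los_threshold
    return np.array([p.death30 or p.los > thr for p in cohort.patients])


def _alignment_origin(patient, cohort_class: str, alignment: str) -> float:
    if alignment == "event_time":
        return 0.0
    if alignment == "peak_wbc":
        return find_peak_wbc(patient, cohort_class, mode="modeling")
    raise ValueError(f"unknown alignment {alignment!r}")


def normalized_series(patient, analyte: str, origin: float = 0.0,
                      max_days: float = DEFAULT_MAX_DAYS) -> LabSeries:
    """Baseline-normalized, 12-h-resampled series aligned at ``origin``."""
    base = baseline_mean(patient, analyte)
    if base <= 0:
        raise ValueError(f"patient {patient.patient_id}: non-positive {analyte} baseline")
    s = patient.get(analyte).shifted(origin)
    s = LabSeries(analyte, s.times, s.values / base)
    return resample_12h(s, start=0.0, end=max_days)


def mean_trajectory(cohort: Cohort, mask, alignment: str = "event_time",
                    max_days: float = DEFAULT_MAX_DAYS,
                    min_patients: int = DEFAULT_MIN_PATIENTS) -> ReferenceTrajectory:
    """Pointwise-mean normalized WBC-PLT path of the masked patients."""
    mask = np.asarray(mask, dtype=bool)
    grid = GRID_STEP_DAYS * np.arange(int(round(max_days / GRID_STEP_DAYS)) + 1)
    sums = np.zeros((2, grid.size))
    counts = np.zeros(grid.size, dtype=int)
    n_used = 0
    for p, keep in zip(cohort.patients, mask):
        if not keep or not (p.has("WBC") and p.has("PLT")):
            continue
        origin = _alignment_origin(p, cohort.cohort_class, alignment)
        try:
            w = normalized_series(p, "WBC", origin, max_days)
            q = normalized_series(p, "PLT", origin, max_days)
        except ValueError:
            continue
        # indices on the common grid; both analytes must cover a gridpoint
        iw = np.round(w.times / GRID_STEP_DAYS).astype(int)
        ip = np.round(q.times / GRID_STEP_DAYS).astype(int)
        common, wi, pi = np.intersect1d(iw, ip, return_indices=True)
        if common.size == 0:
            continue
        sums[0, common] += w.values[wi]
        sums[1, common] += q.values[pi]
        counts[common] += 1
        n_used += 1
    if n_used == 0:
        raise ValueError("no usable patients under the mask")
    keep = counts >= max(int(min_patients), 1)
    if not keep.any():
        raise ValueError("no gridpoint reaches the minimum contributing count")
    grid, counts = grid[keep], counts[keep]
    mean_w = sums[0, keep] / counts
    mean_p = sums[1, keep] / counts

    ref = ReferenceTrajectory(grid=grid, mean_wbc_norm=mean_w, mean_plt_norm=mean_p,
                              n_contributing=counts, alignment=alignment)
    step_per_day = int(round(1.0 / GRID_STEP_DAYS))
    idx = {int(round(t / GRID_STEP_DAYS)): i for i, t in enumerate(grid)}
    for day in range(1, int(max_days) + 1):
        j, i = idx.get(day * step_per_day), idx.get((day - 1) * step_per_day)
        if i is not None and j is not None:
            ref.daily_change[day] = np.array([mean_w[j] - mean_w[i],
                                              mean_p[j] - mean_p[i]])
    return ref


def daily_deltas(patient, cohort_class: str, alignment: str = "event_time",
                 max_days: float = DEFAULT_MAX_DAYS,
                 origin: float | None = None) -> dict:
    """day -> (normalized 24-h change vector, normalized position) for a patient.

    ``origin`` overrides the alignment rule (used for risk-mode 72-h peak
    alignment in infectious cohorts).
    """
    if origin is None:
        origin = _alignment_origin(patient, cohort_class, alignment)
    w = normalized_series(patient, "WBC", origin, max_days)
    q = normalized_series(patient, "PLT", origin, max_days)
    iw = {int(round(t / GRID_STEP_DAYS)): v for t, v in zip(w.times, w.values)}
    ip = {int(round(t / GRID_STEP_DAYS)): v for t, v in zip(q.times, q.values)}
    step = int(round(1.0 / GRID_STEP_DAYS))
    out = {}
    for day in range(1, int(max_days) + 1):
        k, k0 = day * step, (day - 1) * step
        if k in iw and k in ip:
            delta = None
            if k0 in iw and k0 in ip:
                delta = np.array([iw[k] - iw[k0], ip[k] - ip[k0]])
            out[day] = (delta, np.array([iw[k], ip[k]]))
    return out


def direction_bands(cohort: Cohort, mask, reference: ReferenceTrajectory,
                    percentiles=DEFAULT_PERCENTILES,
                    max_days: float = DEFAULT_MAX_DAYS) -> dict:
    """Empirical percentile bands of daily angles versus the reference.

    Returns day -> {percentile: angle degrees} and stores the result on the
    reference. Patient-days with an undefined (zero or missing) change vector
    are excluded.
    """
    from .risk import direction_score  # local import to avoid a cycle

    mask = np.asarray(mask, dtype=bool)
    angles: dict[int, list] = {}
    for p, keep in zip(cohort.patients, mask):
        if not keep or not (p.has("WBC") and p.has("PLT")):
            continue
        try:
            deltas = daily_deltas(p, cohort.cohort_class, reference.alignment, max_days)
        except ValueError:
            continue
        for day, (delta, _pos) in deltas.items():
            if delta is None or day not in reference.daily_change:
                continue
            ang = direction_score(delta, reference.daily_change[day])
            if np.isfinite(ang):
                angles.setdefault(day, []).append(ang)
    if not any(angles.values()):
        raise ValueError("no patient with two consecutive days of data")
    bands = {}
    for day, vals in sorted(angles.items()):
        bands[day] = {
            pct: float(np.percentile(vals, pct, method="midpoint"))
            for pct in percentiles
        }
    reference.direction_percentiles = bands
    return bands


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def reference_to_csv(reference: ReferenceTrajectory, path) -> None:
    """Serialize so risk scoring can run without the exploratory cohort."""
    df = pd.DataFrame({
        "time": reference.grid,
        "mean_wbc_norm": reference.mean_wbc_norm,
        "mean_plt_norm": reference.mean_plt_norm,
        "n": reference.n_contributing,
    })
    df["alignment"] = reference.alignment
    for col in ("dwbc_24h", "dplt_24h"):
        df[col] = np.nan
    pcts = sorted({p for b in reference.direction_percentiles.values() for p in b})
    for p in pcts:
        df[f"band_p{p:g}"] = np.nan
    step = int(round(1.0 / GRID_STEP_DAYS))
    for day, vec in reference.daily_change.items():
        rows = np.flatnonzero(np.isclose(reference.grid, day))
        if rows.size:
            df.loc[rows[0], ["dwbc_24h", "dplt_24h"]] = vec
            for p, ang in reference.direction_percentiles.get(day, {}).items():
                df.loc[rows[0], f"band_p{p:g}"] = ang
    df.to_csv(path, index=False)


def reference_from_csv(path) -> ReferenceTrajectory:
    df = pd.read_csv(path)
    ref = ReferenceTrajectory(
        grid=df["time"].to_numpy(),
        mean_wbc_norm=df["mean_wbc_norm"].to_numpy(),
        mean_plt_norm=df["mean_plt_norm"].to_numpy(),
        n_contributing=df["n"].to_numpy(dtype=int),
        alignment=str(df["alignment"].iloc[0]) if "alignment" in df else "event_time",
    )
    band_cols = {c: float(c[len("band_p"):]) for c in df.columns if c.startswith("band_p")}
    for _, row in df.iterrows():
        if np.isfinite(row.get("dwbc_24h", np.nan)):
            day = int(round(row["time"]))
            ref.daily_change[day] = np.array([row["dwbc_24h"], row["dplt_24h"]])
            bands = {p: float(row[c]) for c, p in band_cols.items()
                     if np.isfinite(row[c])}
            if bands:
                ref.direction_percentiles[day] = bands
    return ref
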