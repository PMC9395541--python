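"""Positional and directional risk scoring against the reference trajectory.

Each in-hospital patient-day is scored in the baseline-normalized WBC-PLT
plane against the favorable mean trajectory:

* **position** — Euclidean distance from the reference point, with WBC below
  and PLT above the reference contributing zero (only the unfavorable
  quadrant counts);
* **direction** — the angle (degrees) between the patient's 24-h change
  vector and the reference's daily change vector.

Scores are converted to percentiles against per-day exploratory-cohort
distributions; thresholds (default 50th/80th) derive only from the
exploratory half, and all reported rates come from the validation half.
Strata are compared by relative risk (Katz log-normal CI), Pearson chi-squared
tests (no continuity correction), and binomial sensitivity/specificity.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binomtest, chi2_contingency

from .cohort import Cohort, find_peak_wbc
from .reference import (ReferenceTrajectory, adverse_outcome_mask, daily_deltas,
                        direction_bands, good_outcome_mask, mean_trajectory)

logger = logging.getLogger("inflarec")

DEFAULT_THRESHOLDS = (50.0, 80.0)
DEFAULT_MAX_DAY = 7

STRATA = ("both_lt50", "mixed", "both_gt80")


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

def position_score(patient_point, reference_point) -> float:
    """Distance from the reference, zeroing the favorable half-planes.

    Only WBC above and PLT below the reference contribute:
    ||(max(wbc_pat - wbc_ref, 0), max(plt_ref - plt_pat, 0))||.
    """
    pw, pp = (float(v) for v in patient_point)
    rw, rp = (float(v) for v in reference_point)
    if not all(np.isfinite([pw, pp, rw, rp])):
        raise ValueError("position_score requires finite inputs")
    return float(np.hypot(max(pw - rw, 0.0), max(rp - pp, 0.0)))


def direction_score(patient_delta, reference_delta) -> float:
    """Angle in degrees between two daily change vectors, in [0, 180].

    A zero-length vector makes the angle undefined: returns NaN (the
    patient-day is excluded from directional percentiles, since 0 deg would
    spuriously signal a good recovery).
    """
    u = np.asarray(patient_delta, dtype=float)
    v = np.asarray(reference_delta, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0 or not (np.isfinite(nu) and np.isfinite(nv)):
        return float("nan")
    cos = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(cos)))


def percentile_transform(scores, exploratory_distribution) -> np.ndarray:
    """Empirical-CDF percentiles in [0, 100] with midpoint tie handling."""
    ref = np.sort(np.asarray(exploratory_distribution, dtype=float))
    if ref.size == 0:
        raise ValueError("exploratory distribution must be nonempty")
    s = np.asarray(scores, dtype=float)
    left = np.searchsorted(ref, s, side="left")
    right = np.searchsorted(ref, s, side="right")
    pct = 100.0 * (left + 0.5 * (right - left)) / ref.size
    pct[~np.isfinite(s)] = np.nan
    return pct


# ---------------------------------------------------------------------------
# Per-patient-day assessment
# ---------------------------------------------------------------------------

def _risk_origin(patient, cohort_class: str) -> float:
    """Risk-mode alignment origin: t=0 except peak-within-72h for infection."""
    if cohort_class == "infectious":
        return find_peak_wbc(patient, cohort_class, mode="risk")
    return 0.0


def _raw_deltas(patient, origin: float, max_day: int) -> dict:
    """Non-interpolated scoring: last two non-repeat draws at each day."""
    w = patient.get("WBC").shifted(origin)
    q = patient.get("PLT").shifted(origin)
    from .cohort import baseline_mean
    bw, bp = baseline_mean(patient, "WBC"), baseline_mean(patient, "PLT")
    out = {}
    for day in range(1, max_day + 1):
        res = []
        for s, b in ((w, bw), (q, bp)):
            sel = (s.times >= 0) & (s.times <= day)
            vals = s.values[sel] / b
            keep = np.ones(vals.size, dtype=bool)
            keep[1:] = vals[1:] != vals[:-1]  # exclude repeats
            vals = vals[keep]
            res.append(vals)
        wv, pv = res
        if wv.size == 0 or pv.size == 0:
            continue
        pos = np.array([wv[-1], pv[-1]])
        delta = (np.array([wv[-1] - wv[-2], pv[-1] - pv[-2]])
                 if wv.size >= 2 and pv.size >= 2 else None)
        out[day] = (delta, pos)
    return out


def assess_cohort(cohort: Cohort, reference: ReferenceTrajectory,
                  max_day: int = DEFAULT_MAX_DAY, mode: str = "interpolated") -> pd.DataFrame:
    """Position and direction scores for every patient-day.

    ``mode='interpolated'`` takes values at exact 24-h gridpoints of the 12-h
    interpolation; ``mode='raw'`` uses the last two non-repeat measurements.
    """
    if mode not in ("interpolated", "raw"):
        raise ValueError(f"unknown scoring mode {mode!r}")
    rows = []
    for p in cohort.patients:
        if not (p.has("WBC") and p.has("PLT")):
            continue
        try:
            origin = _risk_origin(p, cohort.cohort_class)
            if mode == "interpolated":
                deltas = daily_deltas(p, cohort.cohort_class,
                                      max_days=float(max_day), origin=origin)
            else:
                deltas = _raw_deltas(p, origin, max_day)
        except (ValueError, KeyError):
            continue
        for day, (delta, pos) in deltas.items():
            try:
                ref_pos = reference.value_at(float(day))
            except KeyError:
                continue
            position = position_score(pos, ref_pos)
            direction = (direction_score(delta, reference.daily_change[day])
                         if delta is not None and day in reference.daily_change
                         else float("nan"))
            rows.append({"patient_id": p.patient_id, "day": day,
                         "position": position, "direction": direction})
    return pd.DataFrame(rows, columns=["patient_id", "day", "position", "direction"])


def attach_percentiles(assessments: pd.DataFrame,
                       exploratory: pd.DataFrame) -> pd.DataFrame:
    """Add position/direction percentiles versus per-day exploratory distributions."""
    out = assessments.copy()
    out["position_pct"] = np.nan
    out["direction_pct"] = np.nan
    for day, grp in out.groupby("day"):
        expl = exploratory[exploratory["day"] == day]
        if expl.empty:
            continue
        pos_dist = expl["position"].to_numpy()
        out.loc[grp.index, "position_pct"] = percentile_transform(
            grp["position"].to_numpy(), pos_dist)
        dir_dist = expl["direction"].to_numpy()
        dir_dist = dir_dist[np.isfinite(dir_dist)]
        if dir_dist.size:
            out.loc[grp.index, "direction_pct"] = percentile_transform(
                grp["direction"].to_numpy(), dir_dist)
    return out


def stratify(assessments: pd.DataFrame,
             thresholds=DEFAULT_THRESHOLDS) -> pd.DataFrame:
    """Assign each patient-day a joint position/direction stratum.

    ``both_lt50``: both percentiles below the lower threshold; ``both_gt80``:
    both above the upper; everything else ``mixed``. Days with an undefined
    direction get no stratum.
    """
    lo, hi = thresholds
    out = assessments.copy()
    strata = []
    for pos, dirn in zip(out["position_pct"], out["direction_pct"]):
        if not (np.isfinite(pos) and np.isfinite(dirn)):
            strata.append(None)
        elif pos < lo and dirn < lo:
            strata.append("both_lt50")
        elif pos > hi and dirn > hi:
            strata.append("both_gt80")
        else:
            strata.append("mixed")
    out["stratum"] = strata
    return out


def strata_table(stratified: pd.DataFrame, outcomes: dict, day: int) -> pd.DataFrame:
    """Counts of stratum x adverse outcome for one post-event day.

    ``outcomes`` maps patient_id -> bool (adverse). Margins are conserved:
    every stratified patient-day at ``day`` lands in exactly one cell.
    """
    sub = stratified[(stratified["day"] == day) & stratified["stratum"].notna()]
    rows = []
    for stratum in STRATA:
        ids = sub.loc[sub["stratum"] == stratum, "patient_id"]
        adverse = sum(bool(outcomes[i]) for i in ids)
        rows.append({"stratum": stratum, "adverse": adverse,
                     "ok": len(ids) - adverse, "n": len(ids)})
    return pd.DataFrame(rows).set_index("stratum")


# ---------------------------------------------------------------------------
# Effect measures and tests
# ---------------------------------------------------------------------------

@dataclass
class RelativeRisk:
    rr: float
    ci_low: float | None = None
    ci_high: float | None = None
    infinite: bool = False


def relative_risk(r1: float, r0: float) -> RelativeRisk:
    """Relative risk from two event rates (CI omitted without counts)."""
    if r0 == 0:
        return RelativeRisk(rr=float("inf"), infinite=True)
    return RelativeRisk(rr=float(r1) / float(r0))


def relative_risk_from_counts(a: int, n1: int, c: int, n0: int,
                              alpha: float = 0.05) -> RelativeRisk:
    """RR of group 1 (a/n1) versus group 0 (c/n0) with a Katz log-normal CI."""
    if n1 <= 0 or n0 <= 0:
        raise ValueError("group sizes must be positive")
    if c == 0:
        return RelativeRisk(rr=float("inf"), infinite=True)
    rr = (a / n1) / (c / n0)
    if a == 0:
        return RelativeRisk(rr=0.0)
    from scipy.stats import norm
    z = norm.ppf(1.0 - alpha / 2.0)
    se = np.sqrt(1.0 / a - 1.0 / n1 + 1.0 / c - 1.0 / n0)
    return RelativeRisk(rr=float(rr),
                        ci_low=float(rr * np.exp(-z * se)),
                        ci_high=float(rr * np.exp(z * se)))


def chi2_2x2(counts) -> tuple[float, float, int]:
    """Pearson chi-squared on a 2x2 table, no continuity correction."""
    table = np.asarray(counts, dtype=float)
    if table.shape != (2, 2) or (table < 0).any():
        raise ValueError("expected a nonnegative 2x2 table")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("all margins must be positive")
    res = chi2_contingency(table, correction=False)
    return float(res.statistic), float(res.pvalue), 1


def sensitivity_specificity(flagged_deaths: int, total_deaths: int,
                            true_negatives: int, total_survivor_like: int):
    """Percent sensitivity and specificity with exact binomial 95% CIs.

    Returns ((sens_pct, (lo, hi)), (spec_pct, (lo, hi))), all in percent.
    """
    if total_deaths <= 0 or total_survivor_like <= 0:
        raise ValueError("totals must be positive")
    out = []
    for k, n in ((flagged_deaths, total_deaths),
                 (true_negatives, total_survivor_like)):
        ci = binomtest(k, n).proportion_ci(confidence_level=0.95, method="exact")
        out.append((100.0 * k / n, (100.0 * ci.low, 100.0 * ci.high)))
    return tuple(out)


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------

def run_risk_analysis(exploratory: Cohort, validation: Cohort,
                      thresholds=DEFAULT_THRESHOLDS, max_day: int = DEFAULT_MAX_DAY,
                      min_patients: int = 10, mode: str = "interpolated") -> dict:
    """Full exploratory/validation risk pipeline.

    Builds the good-outcome reference and score distributions from the
    exploratory cohort only, scores the validation cohort against them, and
    returns per-day strata tables with relative risks and chi-squared tests.
    """
    mask = good_outcome_mask(exploratory)
    reference = mean_trajectory(exploratory, mask, alignment="event_time",
                                min_patients=min_patients)
    direction_bands(exploratory, mask, reference)
    expl_scores = assess_cohort(exploratory, reference, max_day=max_day, mode=mode)
    val_scores = assess_cohort(validation, reference, max_day=max_day, mode=mode)
    val_scores = attach_percentiles(val_scores, expl_scores)
    stratified = stratify(val_scores, thresholds)

    los_threshold = exploratory.los_threshold
    adverse = dict(zip([p.patient_id for p in validation.patients],
                       adverse_outcome_mask(validation, los_threshold)))
    tables, rrs, chi2s = {}, {}, {}
    for day in range(1, max_day + 1):
        tab = strata_table(stratified, adverse, day)
        tables[day] = tab
        hi, lo = tab.loc["both_gt80"], tab.loc["both_lt50"]
        if hi["n"] > 0 and lo["n"] > 0:
            rrs[day] = relative_risk_from_counts(int(hi["adverse"]), int(hi["n"]),
                                                 int(lo["adverse"]), int(lo["n"]))
            table2 = [[int(hi["adverse"]), int(hi["ok"])],
                      [int(lo["adverse"]), int(lo["ok"])]]
            try:
                chi2s[day] = chi2_2x2(table2)
            except ValueError:
                pass
    return {"reference": reference, "exploratory_scores": expl_scores,
            "assessments": stratified, "strata_tables": tables,
            "relative_risks": rrs, "chi2": chi2s,
            "los_threshold": los_threshold}
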