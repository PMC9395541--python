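"""Synthetic hospital cohorts with the statistical structure the analysis assumes.

Real inflammatory-recovery cohorts are IRB-restricted EHR extracts, so every
downstream stage is exercised on simulated patients instead. Each patient gets

* baseline WBC/PLT setpoints drawn around cardiac-surgery cohort means
  (WBC 7.9 +/- 3.1, PLT 217.9 +/- 71.7, both 10^3/uL),
* an inflammatory perturbation: a linear WBC ramp to a peak 0.5-2.5 days after
  the event and a PLT dip below setpoint,
* recovery following the kinetic model — exponential WBC decay
  (k ~ U(0.5, 1.0) day^-1) and linear PLT regrowth (slope ~ U(13, 22)
  10^3/(uL*day)) starting tau ~ N(2.0, 0.3) days after the peak, capped at a
  modest overshoot above the PLT setpoint,
* multiplicative lognormal measurement noise (default CV 3%), irregular
  12-24 h sampling, 1-3 pre-event baseline draws, and discharge censoring,
* with a configurable adverse subpopulation whose dynamics diverge
  (WBC re-rise, PLT decline, or stalled WBC clearance) and whose outcome
  labels (30-day death, long LOS) follow the divergence, plus a small muted
  fraction (~0.5%) who never mount a 2-unit WBC rise.

Auxiliary markers (HCT, HGB, RBC, RDW, ANION, BUN, CRE, GLU) are noisy AR(1)
deviations around baseline — enough to exercise the clustering filters, with
no mechanistic chemistry. All output is a pure function of (config, seed).
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.stats import norm

from .cohort import Cohort, LabSeries, PatientRecord

ADVERSE_MODES = ("wbc_rebound", "plt_decline", "stalled_recovery")

#: Auxiliary-marker baselines: (mean, SD between patients, AR(1) deviation SD).
AUX_BASELINES = {
    "HCT": (38.1, 6.1, 0.04),
    "RDW": (14.2, 2.2, 0.02),
    "ANION": (12.0, 2.5, 0.08),
    "BUN": (20.0, 8.0, 0.10),
    "CRE": (1.0, 0.3, 0.08),
    "GLU": (110.0, 25.0, 0.12),
}
_AR1_PHI = 0.8


@dataclass
class SimConfig:
    """Generator parameters; defaults emulate a cardiac-surgery cohort."""

    n_patients: int = 200
    cohort_class: str = "surgical"
    baseline_wbc_mean: float = 7.9
    baseline_wbc_sd: float = 3.1
    baseline_plt_mean: float = 217.9
    baseline_plt_sd: float = 71.7
    peak_rise_mean: float = 8.0  # WBC excess at peak, 10^3/uL
    peak_rise_sd: float = 3.0
    k_wbc_range: tuple = (0.5, 1.0)  # day^-1
    k_plt_range: tuple = (13.0, 22.0)  # 10^3/(uL*day)
    tau_delay_mean: float = 2.0  # days
    tau_delay_sd: float = 0.3
    plt_dip_fraction: float = 0.30
    overshoot_fraction: float = 0.30
    noise_cv: float = 0.03
    sampling_interval_hours: tuple = (12.0, 24.0)
    adverse_fraction: float = 0.10
    adverse_modes: dict = field(default_factory=lambda: dict(
        wbc_rebound=0.4, plt_decline=0.3, stalled_recovery=0.3))
    muted_wbc_fraction: float = 0.005
    los_median: float = 7.5  # lognormal LOS draw, days
    los_sigma: float = 0.35
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        for name in ("baseline_wbc_mean", "baseline_plt_mean", "peak_rise_mean",
                     "tau_delay_mean", "los_median"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("k_wbc_range", "k_plt_range", "sampling_interval_hours"):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi < lo:
                raise ValueError(f"{name} must be a positive interval")
        if not 0.0 <= self.plt_dip_fraction < 1.0:
            raise ValueError("plt_dip_fraction must be in [0, 1)")
        if self.overshoot_fraction < 0:
            raise ValueError("overshoot_fraction must be >= 0")
        if not 0.0 <= self.adverse_fraction <= 1.0:
            raise ValueError("adverse_fraction must be in [0, 1]")
        if not 0.0 <= self.muted_wbc_fraction <= 1.0:
            raise ValueError("muted_wbc_fraction must be in [0, 1]")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")


@dataclass
class TruthRecord:
    """Ground-truth kinetic parameters and labels for one simulated patient."""

    patient_id: str
    wbc_setpoint: float
    plt_setpoint: float
    wbc_max: float
    t_wbc_max: float
    k_wbc: float
    k_plt: float
    tau: float
    rise_days: float
    plt_dip_fraction: float
    overshoot_fraction: float
    mode: str  # none | muted | wbc_rebound | plt_decline | stalled_recovery
    adverse: bool
    death30: bool
    los: float
    # mode-specific distortion parameters (NaN when unused)
    onset: float = float("nan")
    rebound_amp: float = float("nan")
    rebound_rate: float = float("nan")
    decline_rate: float = float("nan")

    def __post_init__(self):
        core = (self.wbc_setpoint, self.plt_setpoint, self.wbc_max,
                self.t_wbc_max, self.k_wbc, self.k_plt, self.tau)
        if not np.all(np.isfinite(core)):
            raise ValueError("truth parameters must be finite")
        if self.mode != "muted" and self.wbc_max <= self.wbc_setpoint:
            raise ValueError("WBC_max must exceed the setpoint for non-muted patients")
        if self.mode in ADVERSE_MODES and not self.adverse:
            raise ValueError("divergence-mode patients must carry an adverse label")


# ---------------------------------------------------------------------------
# Noiseless curves
# ---------------------------------------------------------------------------

def simulate_recovery_curve(truth: TruthRecord, times) -> tuple[np.ndarray, np.ndarray]:
    """Noiseless WBC and PLT values (10^3/uL) at the requested times.

    Pre-peak, WBC ramps linearly from the setpoint to the peak over
    ``rise_days`` while PLT dips linearly to ``(1 - dip) * setpoint``.
    Post-peak, WBC decays exponentially toward the setpoint; PLT stays at the
    dipped level until ``t_wbc_max + tau`` and then grows linearly at
    ``k_plt``, capped at ``(1 + overshoot) * setpoint``. Adverse divergence
    modes recorded on the truth are superimposed after their onset.
    """
    t = np.asarray(times, dtype=float)
    tp = truth.t_wbc_max
    ramp0 = tp - truth.rise_days

    # WBC: setpoint -> linear ramp -> exponential decay
    wbc = np.full_like(t, truth.wbc_setpoint)
    amp = truth.wbc_max - truth.wbc_setpoint
    rising = (t > ramp0) & (t < tp)
    wbc[rising] = truth.wbc_setpoint + amp * (t[rising] - ramp0) / truth.rise_days
    after = t >= tp
    wbc[after] = truth.wbc_setpoint + amp * np.exp(-truth.k_wbc * (t[after] - tp))

    # PLT: setpoint -> linear dip -> plateau -> delayed linear growth
    dipped = truth.plt_setpoint * (1.0 - truth.plt_dip_fraction)
    plt = np.full_like(t, truth.plt_setpoint)
    plt[rising] = truth.plt_setpoint - (truth.plt_setpoint - dipped) * (
        (t[rising] - ramp0) / truth.rise_days)
    plt[after] = dipped
    growing = t >= tp + truth.tau
    plt[growing] = dipped + truth.k_plt * (t[growing] - tp - truth.tau)
    cap = truth.plt_setpoint * (1.0 + truth.overshoot_fraction)
    np.minimum(plt, cap, out=plt)

    if truth.mode == "wbc_rebound":
        late = t >= truth.onset
        wbc[late] += truth.rebound_amp * (
            1.0 - np.exp(-truth.rebound_rate * (t[late] - truth.onset)))
    elif truth.mode == "plt_decline":
        late = t >= truth.onset
        at_onset = float(np.interp(truth.onset, t, plt)) if t.size else dipped
        plt[late] = np.maximum(at_onset - truth.decline_rate * (t[late] - truth.onset), 20.0)
    return wbc, plt


# ---------------------------------------------------------------------------
# Patient-level simulation
# ---------------------------------------------------------------------------

def _truncnorm(rng, mean, sd, lo, hi):
    """Inverse-CDF truncated normal draw (exact, no rejection loop)."""
    if sd == 0:
        return float(np.clip(mean, lo, hi))
    a, b = norm.cdf((lo - mean) / sd), norm.cdf((hi - mean) / sd)
    return float(mean + sd * norm.ppf(a + (b - a) * rng.uniform()))


def draw_truth(config: SimConfig, rng: np.random.Generator, patient_id: str) -> TruthRecord:
    """Draw one patient's ground-truth parameters and outcome labels."""
    wbc_sp = _truncnorm(rng, config.baseline_wbc_mean, config.baseline_wbc_sd, 3.0, 20.0)
    plt_sp = _truncnorm(rng, config.baseline_plt_mean, config.baseline_plt_sd, 150.0, 450.0)
    k_wbc = float(rng.uniform(*config.k_wbc_range))
    k_plt = float(rng.uniform(*config.k_plt_range))
    tau = _truncnorm(rng, config.tau_delay_mean, config.tau_delay_sd, 0.0, np.inf)
    t_peak = float(rng.uniform(0.5, 2.5))
    rise_days = float(rng.uniform(0.5, 2.0))

    muted = rng.uniform() < config.muted_wbc_fraction
    if muted:
        rise = float(rng.uniform(0.2, 1.5))  # never reaches the 2-unit threshold
    else:
        rise = _truncnorm(rng, config.peak_rise_mean, config.peak_rise_sd, 2.5, 25.0)

    adverse = rng.uniform() < config.adverse_fraction
    mode = "muted" if muted else "none"
    onset = rebound_amp = rebound_rate = decline_rate = float("nan")
    magnitude = 0.0
    if adverse:
        names = list(config.adverse_modes)
        weights = np.array([config.adverse_modes[m] for m in names], dtype=float)
        mode = str(rng.choice(names, p=weights / weights.sum()))
        onset = t_peak + float(rng.uniform(1.0, 4.0))
        if mode == "wbc_rebound":
            rebound_amp = float(rng.uniform(4.0, 10.0))
            rebound_rate = float(rng.uniform(0.8, 1.5))
            magnitude = rebound_amp / 10.0
        elif mode == "plt_decline":
            decline_rate = float(rng.uniform(15.0, 35.0))
            magnitude = decline_rate / 35.0
        else:  # stalled_recovery: WBC clearance slows five-fold
            k_wbc *= 0.2
            magnitude = 0.8

    # LOS and outcome labels. Good patients stay below the long-stay threshold
    # (truncated lognormal); adverse labels follow the divergence magnitude.
    recovery_time = t_peak + 5.0 + float(rng.uniform(0.0, 1.0))
    death30 = False
    if adverse:
        p_death = 1.0 / (1.0 + np.exp(-(-1.5 + 2.5 * magnitude)))
        death30 = bool(rng.uniform() < p_death)
        los = 14.5 + float(rng.uniform(0.0, 20.0)) * magnitude + float(rng.uniform(0.0, 6.0))
    else:
        mu = np.log(config.los_median)
        cap = norm.cdf((np.log(13.4) - mu) / config.los_sigma)
        base = float(np.exp(mu + config.los_sigma * norm.ppf(rng.uniform() * cap)))
        los = max(recovery_time, base)

    return TruthRecord(
        patient_id=patient_id, wbc_setpoint=wbc_sp, plt_setpoint=plt_sp,
        wbc_max=wbc_sp + rise, t_wbc_max=t_peak, k_wbc=k_wbc, k_plt=k_plt,
        tau=tau, rise_days=rise_days, plt_dip_fraction=config.plt_dip_fraction,
        overshoot_fraction=config.overshoot_fraction, mode=mode,
        adverse=adverse, death30=death30, los=los, onset=onset,
        rebound_amp=rebound_amp, rebound_rate=rebound_rate, decline_rate=decline_rate,
    )


def _noise_factors(rng, cv: float, n: int) -> np.ndarray:
    """Mean-one multiplicative lognormal noise with coefficient of variation cv."""
    if cv == 0.0:
        return np.ones(n)
    sigma = float(np.sqrt(np.log(1.0 + cv * cv)))
    return np.exp(rng.normal(-0.5 * sigma * sigma, sigma, size=n))


def sample_patient(truth: TruthRecord, config: SimConfig,
                   rng: np.random.Generator) -> PatientRecord:
    """Sample a PatientRecord from a TruthRecord: irregular draws, noise, censoring."""
    lo = config.sampling_interval_hours[0] / 24.0
    hi = config.sampling_interval_hours[1] / 24.0
    post = [0.0]
    while post[-1] < truth.los:
        post.append(post[-1] + float(rng.uniform(lo, hi)))
    post = np.array(post[:-1]) if post[-1] > truth.los else np.array(post)
    n_pre = int(rng.integers(1, 4))
    pre = np.sort(rng.uniform(-3.0, -0.25, size=n_pre))
    times = np.concatenate([pre, post])

    wbc, plt = simulate_recovery_curve(truth, times)
    series = {
        "WBC": LabSeries("WBC", times, wbc * _noise_factors(rng, config.noise_cv, times.size)),
        "PLT": LabSeries("PLT", times, plt * _noise_factors(rng, config.noise_cv, times.size)),
    }

    # Auxiliary markers: AR(1) relative deviations around a patient baseline.
    hct_rel = None
    for marker, (mean, sd, dev_sd) in AUX_BASELINES.items():
        base = _truncnorm(rng, mean, sd, 0.2 * mean, 2.0 * mean)
        dev = np.empty(times.size)
        x = 0.0
        innov_sd = dev_sd * np.sqrt(1.0 - _AR1_PHI ** 2)
        for i in range(times.size):
            x = _AR1_PHI * x + float(rng.normal(0.0, innov_sd))
            dev[i] = x
        vals = base * (1.0 + dev) * _noise_factors(rng, config.noise_cv, times.size)
        series[marker] = LabSeries(marker, times, np.maximum(vals, 0.0))
        if marker == "HCT":
            hct_rel = series["HCT"].values / base
    # HGB and RBC track HCT almost exactly (exercises the correlation collapse).
    for marker, scale in (("HGB", 13.0), ("RBC", 4.3)):
        vals = scale * hct_rel * (1.0 + rng.normal(0.0, 0.01, size=times.size))
        series[marker] = LabSeries(marker, times, np.maximum(vals, 0.0))

    age = _truncnorm(rng, 63.9, 13.0, 18.0, 95.0)
    gender = "M" if rng.uniform() < 0.713 else "F"
    return PatientRecord(
        patient_id=truth.patient_id, age=age, gender=gender,
        event_time=float(rng.uniform(0.0, 730.0)), discharge_time=truth.los,
        death30=truth.death30, los=truth.los, series=series,
    )


def simulate_patient(config: SimConfig, rng: np.random.Generator,
                     patient_id: str = "P0") -> tuple[PatientRecord, TruthRecord]:
    config.validate()
    truth = draw_truth(config, rng, patient_id)
    return sample_patient(truth, config, rng), truth


# ---------------------------------------------------------------------------
# Cohort-level generation
# ---------------------------------------------------------------------------

def generate_cohort(config: SimConfig) -> tuple[Cohort, list[TruthRecord]]:
    """Generate a full synthetic cohort; bitwise-reproducible given the config."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    width = max(4, len(str(config.n_patients)))
    patients, truths = [], []
    for i in range(config.n_patients):
        pid = f"P{i:0{width}d}"
        truth = draw_truth(config, rng, pid)
        patients.append(sample_patient(truth, config, rng))
        truths.append(truth)
    return Cohort(cohort_class=config.cohort_class, patients=patients), truths


def split_cohort(cohort: Cohort) -> tuple[Cohort, Cohort]:
    """Split by event date: earlier half exploratory, later half validation."""
    order = sorted(cohort.patients, key=lambda p: (p.event_time, p.patient_id))
    n_expl = len(order) // 2
    from dataclasses import replace
    return (replace(cohort, patients=order[:n_expl]),
            replace(cohort, patients=order[n_expl:]))


def truth_table(truths: list[TruthRecord]) -> pd.DataFrame:
    """Ground-truth records as a DataFrame keyed by patient id."""
    return pd.DataFrame([asdict(t) for t in truths])
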