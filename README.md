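# inflarec

Kinetics and risk stratification of acute inflammatory recovery from
longitudinal white blood cell (WBC) and platelet (PLT) counts.

## The problem

Trauma, ischemia and infection all trigger an acute inflammatory response
that temporarily displaces a patient's blood-cell counts from their
homeostatic setpoints. Hospitalized patients who recover well share a
remarkably consistent resolution pattern in the WBC-PLT phase plane, and
deviation from that pattern flags patients at elevated risk of death or
prolonged stay. `inflarec` implements that analysis end to end for
biostatisticians and clinical-data scientists: a synthetic EHR-like cohort
generator (real cohorts of this kind are IRB-restricted), the kinetic
recovery model, non-dimensional trajectory collapse, reference-trajectory
construction, positional/directional risk scoring, and exploratory
trajectory clustering.

## The model

After the post-event WBC peak at time $t_{\mathrm{WBC_{max}}}$, a favorable
recovery follows

$$\mathrm{WBC}(t) = a + b\,e^{-c\,(t - t_{\mathrm{WBC_{max}}})}$$

— exponential decay at rate $c$ (day⁻¹) from the peak toward the setpoint
$a$, with half-life $\ln 2 / c$ — and, starting a lag $\tau \approx 2$ days
after the peak,

$$\mathrm{PLT}(t) = d + f\,(t - t_{\mathrm{WBC_{max}}})\,, \qquad t \ge t_{\mathrm{WBC_{max}}} + \tau$$

— linear platelet regrowth with slope $f$ (10³/(µL·day)), usually
overshooting the baseline setpoint. With the dimensionless variables

$$w = \frac{\mathrm{WBC} - a}{b}, \qquad
p = \frac{\mathrm{PLT} - \mathrm{PLT}(t_{\mathrm{WBC_{max}}}+\tau)}{f/c}, \qquad
t^* = (t - t_{\mathrm{WBC_{max}}})\,c$$

every recovery collapses onto the universal curves $w(t^*) = e^{-t^*}$ and
$p(t^*) = t^* - \tau c$.

Risk scoring compares each baseline-normalized patient-day against the mean
trajectory of good-outcome patients: **position** is the distance from the
reference point counting only elevated WBC and depressed PLT, **direction**
is the angle between the patient's 24-h change vector and the reference's.
Both are converted to percentiles of exploratory-cohort distributions;
out-of-sample strata (both < 50th vs both > 80th percentile) are compared by
relative risk and chi-squared tests.

## Worked example

```python
from inflarec import (SimConfig, generate_cohort, split_cohort,
                      apply_exclusions, run_risk_analysis, fit_patient)

cfg = SimConfig(n_patients=500, adverse_fraction=0.10, seed=5)
cohort, truths = generate_cohort(cfg)
cohort, _ = apply_exclusions(cohort)       # age/LOS/CBC-count filters

patient = cohort.patients[1]
fit = fit_patient(patient, "surgical")
print(f"patient {patient.patient_id}: k_WBC = {fit.wbc.c:.2f}/day "
      f"(half-life {fit.half_life_days:.2f} d), "
      f"k_PLT = {fit.plt.f:.1f} x10^3/uL/day after a {fit.plt.tau:.2f} d lag")

expl, val = split_cohort(cohort)           # earlier half sets thresholds
res = run_risk_analysis(expl, val)
print(res["strata_tables"][5])
rr = res["relative_risks"][5]
print(f"day-5 RR: {rr.rr:.1f} (95% CI {rr.ci_low:.1f}-{rr.ci_high:.1f})")
```

prints

```
patient P0001: k_WBC = 0.80/day (half-life 0.87 d), k_PLT = 16.9 x10^3/uL/day after a 2.21 d lag
           adverse   ok    n
stratum
both_lt50        1   60   61
mixed            3  177  180
both_gt80        9    0    9
day-5 RR: 61.0 (95% CI 8.7-426.1)
```

The fitted decay rate of 0.80/day means this patient clears excess WBCs with
a ~0.9-day half-life; platelet regrowth at ~17 x10³/µL per day began about
2.2 days after the WBC peak. In the out-of-sample half of the cohort, patients whose
day-5 position *and* direction both exceed the exploratory 80th percentile
carry a 61-fold higher adverse-outcome rate than patients below the 50th on
both — the synthetic analogue of the phase-plane risk chart.

The same pipeline is available as a CLI
(`inflarec simulate|fit|reference|risk|cluster|report <config.yaml>`), each
step writing CSV artifacts plus a manifest for reproducibility.

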