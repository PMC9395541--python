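# Methods

## Recovery model

For each patient the post-peak WBC count is modeled as exponential decay
toward the homeostatic setpoint, `WBC(t) = a + b·exp(−c·(t − t_peak))`, and
the platelet count as delayed linear growth,
`PLT(t) = d + f·(t − t_peak)` for `t ≥ t_peak + τ`, with the count held at
its post-dip plateau before the lag. The model assumes (i) excess WBCs are
removed at a constant per-cell rate with negligible new influx, so the
half-life is `ln2/c` and the mean residence time of an excess cell is `1/c`;
(ii) platelet production proceeds at a constant net rate beginning roughly
two days after peak inflammation, often overshooting the baseline setpoint;
(iii) both processes run at least until baseline is restored. Displayed
forms of the decay equation sometimes omit the setpoint offset; the offset
form `a + b·e^{−ct}` is the one implemented, since WBC counts plateau at the
setpoint, not at zero.

Non-dimensionalization maps every recovery onto a single shape:
`w = (WBC − a)/b`, `p = (PLT − PLT(t_peak+τ))/(f/c)`,
`t* = (t − t_peak)·c`, giving `w(t*) = e^{−t*}` and `p(t*) = t* − τc`.

## Alignment, inclusion and outcome rules

* Time is measured in real-valued days from the inflammatory event (surgery
  end or admission); pre-event times are negative. A continuous axis
  subsumes both "post-op day N" and hour-based conventions.
* The alignment origin is the peak WBC within 3 days of the event for
  surgical and ischemic cohorts, over the whole stay for infectious cohorts
  when fitting kinetics, and within the first 72 h for infectious cohorts
  when scoring risk (onset timing is unreliable in infection). Ties break to
  the earliest time.
* Cohort exclusions: age < 18 y, stay < 2 days, fewer than 2 WBC
  measurements. Kinetic fitting additionally requires a ≥ 2 × 10³/µL WBC
  rise over the first observed value and ≥ 5 days of post-peak WBC and PLT
  data.
* Adverse outcome = 30-day death or long stay; the long-stay threshold is
  10 days for cohorts with mean LOS < 7 days and 14 days otherwise, computed
  from the cohort itself (from the exploratory half when scoring a
  validation cohort).
* Duplicate (patient, analyte, timestamp) rows keep the first value; baseline
  means average all pre-event draws (not just the latest), falling back to
  the first post-event value when no pre-event draw exists.

## Fitting

Both fits use unweighted least squares over the first 5 days after the peak.
The WBC fit is multi-started over decay rates {0.1, 0.3, 0.5, 0.75, 1.0,
1.5, 3.0} day⁻¹ with bounds `c ∈ [0.01, 5]`, `a, b ≥ 0`, best objective
winning; tolerances are tightened to 1e-12 so noiseless data reproduces
parameters at machine precision. Constant series are flagged unidentifiable
(`b = 0`, `c` undefined) and excluded from cohort summaries with a logged
count.

The PLT lag is selected on a grid (0–4 d, step 0.25 d — finer than the 12-h
sampling) by maximizing adjusted R² of the ordinary least-squares line on
points at or beyond each candidate lag, ties to the smallest lag; candidates
reduced to the 3-point minimum are scored by plain R² since the adjustment
has no residual degrees of freedom there. The grid winner is then refined to
the intersection of the fitted line with the pre-lag plateau mean, clamped
to the interval between the last plateau sample and the first growth sample.
The refinement matters: under sparse irregular sampling, every lag between
those two samples selects the same point set and ties exactly, so the grid
alone only identifies the lag up to the local sampling gap. The PLT
intercept `d` is estimated freely rather than pinned to an observed value.

Adjusted R² is `1 − (1 − R²)(n − 1)/(n − p − 1)`, undefined (NaN) for
constant observations and an error for `n ≤ p + 1`.

## Risk scoring

The reference trajectory is the pointwise mean of baseline-normalized,
12-h-resampled WBC-PLT paths over good-outcome patients (survivors under the
long-stay threshold) of the exploratory half, using available-case averaging
(patients drop out at discharge rather than being carried forward).
Gridpoints supported by fewer than `min_patients` (default 10) contributors
are trimmed so late times are not dominated by long-stay patients.
Interpolation is linear with no extrapolation beyond the observed span;
daily values are the 24-h points of the 12-h grid. A raw-value mode instead
uses the last two non-repeat measurements, for sensitivity analysis against
interpolation artifacts.

Position counts only the unfavorable half-planes — WBC above and PLT below
the reference — so a patient with low WBC and high PLT scores zero.
Direction is the angle (degrees, `[0, 180]`) between 24-h change vectors;
zero-length change vectors are excluded rather than scored 0°, which would
spuriously signal good recovery. Percentiles use the empirical CDF with
midpoint tie handling; directional bands use midpoint-interpolated empirical
percentiles. All thresholds derive from the exploratory half only.

Relative risks use the Katz log-normal CI when counts are available (the CI
method behind published intervals is not standardized, so CI endpoints are
not treated as exact); single rates get exact (Clopper–Pearson) binomial
CIs; 2×2 comparisons use Pearson's chi-squared without continuity
correction.

## Clustering

Patients are represented by all markers' normalized trajectories on the 12-h
grid up to a horizon (default 10 d), zero after discharge, nearest-value
within the stay outside the observed span. Cluster count is the largest k
for which every k-means cluster (fixed seed, `n_init = 10`) keeps more than
`min_cluster_size` patients; patients with fewer than 3 measurement sets are
held out and assigned to the nearest centroid afterwards. Marker filtering
runs on a provisional clustering (cluster → filter → caller re-clusters):
markers whose cluster means differ by < 10% (max pairwise relative
difference — the precise statistic is a package choice) are dropped, and
marker groups with pairwise Pearson r > 0.9 over in-hospital entries are
collapsed onto a preferred representative (hematocrit for the red-cell
group).

Cluster significance uses a column-shuffle permutation null: each feature
column is independently permuted across patients, destroying joint
trajectory structure while preserving marginals, and
`p = (1 + #{null objective ≤ observed}) / (1 + n_null)`. This is a
simplification of published synthetic-data cluster tests and is labeled as
such in outputs. Null refits must use the same `n_init` as the observed
clustering; weaker null optimization inflates null objectives and biases p
low. Note the null only has power against structure spread across several
columns — a cluster split carried by a single feature survives column
shuffling.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes, not
mechanism: baseline setpoints drawn around cardiac-surgery cohort summaries
(WBC 7.9 ± 3.1, PLT 217.9 ± 71.7 ×10³/µL, age 63.9 ± 13 y, 71% male), a
linear WBC ramp to a peak 0.5–2.5 d post-event (rise 8 ± 3 ×10³/µL,
truncated ≥ 2.5 so the modeling-inclusion rule is meaningful), a 30% PLT
dip, recovery at `k_wbc ~ U(0.5, 1.0)` day⁻¹ and
`k_plt ~ U(13, 22)` ×10³/(µL·day) after a lag `τ ~ N(2.0, 0.3)` d truncated
at 0, and a 30% PLT overshoot cap. PLT setpoints are truncated at
150 ×10³/µL and the slope/dip/overshoot defaults chosen jointly so the
overshoot cap engages after the 5-day fit window for essentially all
parameter draws; otherwise the cap would alias into the slope estimate.
Measurement noise is mean-one multiplicative lognormal at 3% CV (CBC
analyzers have near-constant CV); sampling intervals are uniform on 12–24 h
with 1–3 pre-event baseline draws; discharge censors all later values, with
discharge at the later of model recovery (peak + ~5–6 d) and a lognormal
LOS draw (median 7.5 d, σ = 0.35).

A configurable adverse fraction (default 10%) receives one of three
divergence modes after a random onset 1–4 d post-peak: a second exponential
WBC rise, a linear PLT decline, or five-fold slowed WBC clearance. Outcome
labels follow divergence deterministically in kind: death occurs with
probability increasing in divergence magnitude (logistic link), and
non-death adverse patients draw an LOS above the long-stay threshold, while
good-outcome patients draw a truncated LOS below it. This keeps the label
consistent with the injected dynamics at the cost of slightly idealized LOS
tails. A muted subpopulation (default 0.5%) never mounts a 2-unit WBC rise.
Auxiliary markers (HCT, RDW, anion gap, BUN, creatinine, glucose) are AR(1)
relative deviations around patient baselines — enough to exercise the
clustering filters, with hemoglobin and red-cell count tracking hematocrit
at r > 0.99 to exercise the correlation collapse; they carry no disease
signal, so low-variation filtering legitimately removes them.

Because noise level and sampling cadence of real cohorts are not
characterized anywhere usable, these defaults are plausible rather than
fitted; passing tests demonstrate correctness of the pipeline's mechanics
and its statistical behavior under the assumed structure, not performance
on real EHR data (where baseline instability, treatment effects,
transfusions and correlated multi-marker dynamics all intrude).

## Problem sizes and known limitations

The test suite uses 200-patient cohorts for parameter recovery, 1000-patient
cohorts over 20 seeds for the out-of-sample enrichment property, and
100 repetitions for permutation-null calibration — sizes at which the
checked properties are stable while the suite stays fast.

Under the default study conditions (3% CV, 12–24 h irregular sampling,
5-day window, unweighted least squares), decay-rate recovery has an
irreducible statistical floor: the acceptance script's
`k_wbc_median_rel_err_pct_3pct_noise` lands around 12–14%, and the lag's
median error around 0.4–0.5 d, with Monte Carlo showing truth-initialized
and dense-oracle estimators do no better. Noiseless recovery is exact to
1e-6 except for the ~1% of patients whose lag leaves fewer than three
samples on the growth segment inside the window, where the slope is
unidentifiable at that precision. The mean-trajectory/percentile machinery
assumes at least a handful of good-outcome patients per gridpoint; with very
small cohorts, lower `min_patients` explicitly.
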