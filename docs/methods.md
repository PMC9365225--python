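# Methods

`hemsits` evaluates an organisational change in a regional helicopter
emergency medical service (HEMS) — the introduction of a dedicated HEMS
coordinator at the dispatch centre — using the two quasi-experimental
instruments appropriate when randomisation is impossible: a segmented
interrupted time series (ITS) on the monthly mean response time, and a
before/after comparison of each base's geographic service area. Because the
underlying registry (mission timelines, patient severity, GPS positions) is
person-identifiable and not public, the package ships a synthetic registry
generator whose defaults encode the study conditions, so every stage of the
analysis is exercised and tested end to end without any data download.

## The interrupted time-series model

Mission response times (alarm of the HEMS crew, or of the coordinator in the
post period, to arrival on scene) are aggregated into calendar-month means.
The monthly mean f(t) is modelled as

    f(t) = β0 + β1·t + β2·u(t − t_pi) + β3·(t − t_pi)·u(t − t_pi)
           + β4·I_winter(t) + ε(t)

with t a 0-based month index (t = 0 is the first study month, January 2017
under the defaults), u the unit step, and t_pi the index of the intervention
month. β2 is the immediate level change at the intervention, β3 the change
in slope, and β4 a winter elevation with I_winter = 1 for October–March.
ε(t) is a stationary error process; the default candidate set is white
noise, MA(1), AR(1) and a seasonal MA at lag 12, and the fitted model is the
candidate with the smallest AICc = AIC + 2k(k+1)/(n−k−1) (ties broken by
fewer parameters, then list order). The candidate set is a documented
choice, not a reconstruction of any particular prior analysis.

Estimation is exact Gaussian maximum likelihood in the state-space
representation (statsmodels). Excluded months — the intervention month
itself, plus any month flagged as an outlier — stay on the time grid as
missing observations, so the error process's timing is not distorted by
gaps. Outlier months are flagged by a leave-one-out z score: a month is
excluded when its mean lies more than `z_threshold` (default 3) standard
deviations from the mean of the *other* included months. Leave-one-out is
used because a genuinely extreme month inflates the pooled SD enough to
mask itself at the conventional threshold.

Inference on β2 and β3 uses t statistics with n − k degrees of freedom
(n observed months, k all estimated parameters including the error
coefficients and innovation variance). Because the ML innovation variance
divides by n rather than n − k, the ARMA-error standard errors are rescaled
by √(n/(n−k)); Monte Carlo at the study's dimensions (35 observed months,
MA(1) θ = 0.3) puts the 95% CI coverage near 0.94 and the type-I error of
both tests near 0.07–0.08, versus ~0.10 without the correction. R² is the
ordinary coefficient of determination of the deterministic fitted mean
against the observed monthly means (it deliberately excludes the error
model's one-step-ahead smoothing, and is labelled as such in outputs).

The counterfactual trajectory — expected response time had the intervention
not occurred — is β0 + β1·t + β4·I_winter(t); the fitted-minus-
counterfactual gap at post month m is β2 + β3·(m − t_pi) by construction.

The fit is exposed as a scikit-learn-style estimator
(`InterruptedTimeSeriesRegressor`: `fit`/`predict`/`get_params`, fitted
attributes with trailing underscores) so it composes with sklearn
tooling; `fit_its` and `select_error_model` are thin functional wrappers.

## Service-area analysis

Each mission's distance to its base is a geodesic on the WGS84 ellipsoid.
No ellipsoidal-geodesy library is part of the dependency set, so the
package implements Vincenty's inverse and direct formulae directly
(sub-millimetre at regional scales; validated in the tests against the
meridian-arc closed form, 110.574 km per degree at the equator). The 5% of
missions farthest from the base are discarded (per-base 95th percentile,
linear interpolation between order statistics; ties at the cutoff are
kept), and the convex hull of the remainder defines the service area.

Hulls are built in an azimuthal equidistant plane centred on the base; that
projection preserves exactly the distances-to-centre the filter is defined
on, and at the ~300 km scale involved the discrepancy from a true geodesic
hull is far below every other uncertainty in the analysis. Hull vertices
are a subset of the input points, so no inverse projection is needed.
Areas are measured by projecting the vertices through a Lambert azimuthal
equal-area projection on the authalic sphere (with geodetic→authalic
latitude conversion, so areas are ellipsoidal km²) centred on the hull
centroid, then applying the shoelace formula; a 100 km geodesic disc at
63°N and at the equator agree to 0.1%. Median and IQR mission distances are
computed on *all* map-eligible missions; only the hull uses the filtered
subset. Pre/post comparisons report absolute and percent area change
(percentages computed from unrounded areas), the Mann–Whitney p for the
distance shift, and a Hodges–Lehmann 95% CI for the median difference.

## Cohort statistics

Pearson chi-square without continuity correction for categorical contrasts
(severity NACA 4–7, scramble rates, 45-minute threshold proportions, base
mission shares); Mann–Whitney U (exact enumeration when both samples are
≤ 20 and untied, tie-corrected normal approximation otherwise) for skewed
continuous variables; Student's t for means (Welch by default, pooled
available). The Hodges–Lehmann estimator is the median of all n·m pairwise
between-group differences; its CI endpoints are order statistics of those
differences at ranks from the normal-approximation inversion of the
Mann–Whitney test. The 45-minute national response-time goal is read as
inclusive (≤ 45 min). In-flight scrambles — alarms accepted while already
airborne — are classified by a strictly-below-2-minutes alarm-to-takeoff
interval. No multiple-testing adjustment is applied by default (a Holm
switch exists in `AnalysisConfig`).

## The synthetic registry generator

The generator emulates the statistical structure the analysis assumes, not
the physics of flight. Month t's mean response time follows the segmented
trend above plus an MA(1) month shock (e_t = z_t + θ·z_{t−1}, z_t i.i.d.
normal); each mission adds i.i.d. normal noise around its month's mean,
truncated below at the larger of the base's start-up time and the mission's
own alarm-to-takeoff interval (the latter keeps alarm ≤ takeoff ≤ on-scene
ordered; in the noiseless configuration the bound never binds, so the
monthly means reproduce the trend exactly). Mission counts per base-month
are Poisson. Locations are area-uniform on a geodesic disc around the base
(uniform bearing, distance ∝ √uniform), giving positive density out to the
rim so the 95th-percentile filter always has work to do.

Default conditions (all overridable in `SimulationConfig`):

| parameter | default | rationale |
|---|---|---|
| months_pre / months_post | 24 / 12 | two pre years, one post year |
| bases | Trondheim (3 min), Ålesund (2 min), Ørland (10 min) | start-up times as published for the three airframes |
| missions_per_month | 28 per base | ≈ 3,000 missions over 36 months regionally |
| β0 | 31.05 min | regional mean response near 31 min |
| β1 | 0.05 min/month | near-flat pre trend |
| β2 / β3 | −0.13 / −0.13 | small null-like intervention effects |
| β4 | 1.1 min | winter (Oct–Mar) elevation |
| ma_theta / month_shock_sd | 0.3 / 1.0 min | moderate month-to-month correlation |
| mission_noise_sd | 10 min | within-month spread of single missions |
| scramble_prob | 0.12 | regional in-flight-scramble share |
| NACA vectors | P(≥4) = 0.615 pre / 0.682 post | severity mix by period; full 8-bin shapes chosen to give period means near 3.98/4.13 |
| max_mission_radius_km | 110 | median distances and hull areas in the tens-of-thousands km² range |

The generator also plants records the inclusion filter must drop
(cancelled, car/SAR/secondary, non-acute, no contact) and missions with
missing GPS (map-ineligible but still in the response-time denominator),
with ground-truth columns (`true_scramble`, `month_index`) so classifiers
are tested against what was actually planted. One `numpy` Generator seeded
from `config.seed` drives everything; the same seed reproduces the tables
byte-for-byte.

What the generator does **not** emulate — and hence what passing tests do
not establish about real registries: response times are symmetric
truncated-normal within a month (real ones are right-skewed); spatial
intensity is uniform over a disc (real missions follow population and
terrain, and coastal bases have half-empty discs); no weather, duty-time,
concurrency or COVID-era effects; no base-specific trend differences. The
per-mission truncation also lifts generated means slightly above the
configured trend (most visibly for the 10-minute-start-up base), which is
visible in descriptive means but immaterial to the ITS contrasts.

## Inclusion filtering

The analysis set is completed, primary, acute missions with patient
contact. Every dropped record is tallied under its first matching reason in
a fixed priority order (cancelled → rapid-response car → SAR → secondary →
not acute → no contact → missing/invalid timeline), so flow-chart counts
are deterministic; the tally conserves records by construction and is
checked. Missing GPS never removes a mission from the response-time
analysis, only from the map analysis — the two denominators differ, as they
do in practice. Multi-patient missions collapse to one row whose on-scene
time is the earliest patient contact, with all patients retained for the
descriptive tables. Records on the intervention day itself belong to the
post period.

## Numerical and design choices

- Timestamps are timezone-aware UTC instants; comparisons are instant-based,
  so local-time representation cannot shift a mission across the boundary.
- The intervention month is excluded from the fit but defines the step
  coding: the first included post month carries step 1 and ramp 1.
- ARMA fits retry with Powell (from the lbfgs solution) on convergence
  warnings and accept a solution whose gradient norm is below 0.1;
  genuinely non-converged fits raise with the optimiser diagnostics, and
  `select_error_model` reports every candidate's failure if all fail.
- Convex-hull degeneracy (fewer than three points, collinear inputs, or a
  projected sliver under 1e−6 km²) yields a flagged zero-area result rather
  than an error; polygon areas under 1e−3 km² are reported as 0.
- AICc is undefined for n ≤ k + 1; such candidates are rejected with a
  diagnostic (the fit itself already requires ≥ 10 observed months).
- Monte Carlo problem sizes: parameter recovery uses 200 replicate series
  and the null calibration 500 (tests) / 200–500 (acceptance script) —
  enough for ~±0.02 Monte Carlo error on coverage without slowing a
  default run beyond a couple of minutes.

## Known limitations

- The ITS candidate error set is fixed and small; richer SARIMA orders are
  not explored.
- MA-coefficient estimates at n ≈ 35 occasionally pile up at the
  invertibility boundary (|θ̂| → 1, ~5% of replicates at θ = 0.3); CIs from
  such fits are unreliable individually, which is part of why overall
  coverage sits near 0.94 rather than 0.95.
- Hull areas depend mildly on the projection pipeline; figures are stable
  to well under 1% but are not authoritative cartographic areas.
- Per-base subgroup ITS is intentionally out of scope; the regional series
  is the unit of analysis.
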