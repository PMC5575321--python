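# Methods

`shearwater` re-implements, as a reusable and tested pipeline, the analysis
of a GPS-tracking experiment on free-ranging Scopoli's shearwaters in which
incubating birds were made anosmic (zinc-sulphate irrigation), carried a
head-mounted magnet, or served as controls, and were tracked over natural
foraging trips to ask whether olfactory or magnetic disruption degrades
at-sea behaviour, foraging success, or homing orientation.  This note
documents the models and procedures as implemented, the parameters that
matter, what the synthetic-data generator does and does not emulate, and the
numerical choices made where the design was open.

## Track handling

**Geodesy.** All distances and bearings are spherical
(R = 6 371 008.8 m, haversine / great-circle forward-and-inverse formulas).
At trip scales (≤ a few hundred km) the discrepancy with an ellipsoidal
model is below 0.5 % (verified in the tests against an independent
ellipsoidal solver), far beneath GPS noise.  Planar work — simplification
tolerances, coast distances — uses a spherical azimuthal-equidistant
projection about a local centre, which preserves distances from the centre
exactly; tangential distortion grows as (d/R)²/6 (~0.04 % at 300 km).

**Trip splitting.** Deployments contain several trips separated by colony
attendance.  A trip is a maximal run of fixes outside the colony-attendance
radius (default 1 km, configurable), bracketed by the last at-colony fix
before departure and the first after return.  Excursions shorter than 1 h
or never exceeding 2 km from the colony are treated as loafing just
offshore and dropped.  None of these values are measurements — they are
pre-registered splitting conventions.

**Interpolation.** Longitude and latitude are each fit as a cubic spline of
time and resampled to an exact 300-s grid (the devices' nominal schedule).
Splines are fitted on geographic coordinates; at these latitudes and step
lengths the difference from interpolating projected coordinates is
negligible.  Fixes synthesised inside data gaps longer than 60 min are
flagged and excluded from behavioural-state fitting, because a spline
bridged across an outage fabricates plausible-looking movement.

**Kinematics.** Speed at fix *i* is the great-circle distance from fix
*i−1* divided by the elapsed time; the turning angle is the wrapped
difference of successive leg bearings, clockwise positive, in (−180°, 180°].
Endpoint fixes lack one or both quantities and never enter feature sets.

**Day/night.** Night is nautical night: solar elevation below −12°,
computed with the NOAA solar-calculator ephemeris (accurate here to well
under 0.1°, i.e. the twilight boundary is located to well within one
5-minute fix).  One reference location (median fix position) and one
reference date (median fix date) are used per trip, so a multi-day trip has
a single, fixed night window — matching how diel classes are defined for
activity budgets.

## Behavioural segmentation and the homing onset

Trips are decomposed into behaviourally consistent units with classic
Douglas–Peucker simplification of the locally projected track (default
tolerance 1 000 m ≈ three commuting fix-lengths); the runs between retained
vertices are the segments.  A segment makes *significant homeward movement*
when it (i) reduces the distance to the colony, (ii) points home on average
(circular-mean leg deviation within 60° of the instantaneous home bearing),
(iii) displaces at least 1 km, and (iv) converts at least 40 % of its path
length into homeward gain.  Criterion (iv) is what separates directed
flight (which achieves ≈ cos(deviation), i.e. ≥ 0.85 in practice) from
slow drift that happens to trend toward the colony.

The decision to home is found by scanning segments backwards from the
arrival: the maximal contiguous suffix of homeward segments marks the homing
section.  Because simplification breakpoints blur the exact turning point —
pre-turn search movement sometimes lies within tolerance of the homing
chord — the onset is then sharpened with a leg-wise backward walk from the
arrival using the **homeward speed** (homeward gain per unit time): directed
homing sustains roughly the commuting speed times cos(deviation), whereas
drift and area-restricted search cannot exceed their own much lower ground
speed toward home.  A leg continues the walk if its homeward speed reaches
3 m/s (midway between foraging and commuting flight); a fast but off-course
leg is forgiven unless the previous leg was also off course; the first
slow leg ends the walk.  On simulated trips with scripted turning points
this lands within two fixes of truth in ≥ 95 % of cases.  Trips with no
qualifying suffix (no directed return, e.g. truncated recordings) are
excluded from homing analyses with a logged reason.  Segmentation and onset
detection take no treatment argument: pre-processing is blind to treatment
by construction.

## Behavioural states

A Gaussian mixture over per-fix (speed, |turning angle|) features, pooled
across all birds and treatments, is fitted by EM (full covariances,
covariance floor 10⁻⁶, best of n restarts at a fixed seed) for 1–10
components.  The absolute turning angle is used because a mixture on signed
angles would split symmetric turning into mirror components.  The number of
states is chosen at the elbow of the log-likelihood: the interior K
maximising the flattening 2·ll(K) − ll(K−1) − ll(K+1), with a config
override available (the study regime yields three states).  Components are
given semantic labels by ascending mean speed — rest (~0.3 m/s, drifting on
the water), forage (~1.8 m/s, tortuous flight and surface feeding), commute
(~6.7 m/s, directed flight).  Each fix is assigned its maximum-posterior
component; posterior ties break deterministically to the slower state.
Activity budgets are second-order: per-trip proportions within each diel
class, averaged to bird level, then mean ± s.e. across birds per treatment.

## Orientation metrics

* **Outbound vanishing bearing** — the bearing from the colony to the point
  where the track first crosses 10 km from the colony, the crossing located
  by linear interpolation within the crossing 5-min leg.
* **Coast distance at 10 km** — distance from that same crossing point to
  the coastline geometry.
* **Pelagic/coastal split** — homing fixes beyond vs within 40 km of the
  coastline (the proxy for out-of-sight vs in-sight of land); the pelagic
  phase runs from the onset to the first fix within 40 km, the coastal
  phase from there to the colony, partitioning the homing section exactly.
  The 40 km is measured to the supplied archipelago coastline, not to the
  colony point.
* **Homeward deviation** — for each consecutive pair of commute-labelled
  fixes, the wrapped difference between the leg bearing and the bearing to
  the colony; home is 0° by construction, clockwise positive.  Only
  commute-state legs count as flight (directed flight is the navigational
  signal; foraging legs are excluded).
* **Straightness** — beeline distance divided by along-track path length of
  a section, in (0, 1].  This orientation of the ratio is deliberate: it is
  the bounded form consistent with reported straightness values of directed
  homing flight (0.85–0.95).
* **Homing timing** — for trips arriving at night, the UTC time-of-day of
  the homing onset and the colony distance at onset feed a mixed model of
  departure-time anticipation.

## Inference

**Iterated Watson–Williams test.** Outbound bearings are compared across
treatments with the Watson–Williams circular ANOVA (F with the standard
1 + 3/(8κ̂) concentration correction, κ̂ by Fisher's approximation, p from
F(k−1, N−k)).  Birds contribute several trips, so the test is iterated:
each of 5 000 iterations samples exactly one bearing per bird uniformly at
random and runs the test on that subset; the p distribution is reported as
mean ± s.e.  One seed governs all iterations; results are bit-reproducible.
A calibration subtlety, verified by simulation: under the null the
*per-resample* p is marginally uniform (each subset is a valid
one-angle-per-bird design, rejection rate 5.0 % at α = 0.05 over 1 000
simulated datasets), while the dataset-level *mean* p is pulled toward 0.5
by averaging over correlated resamples — so thresholding the mean p at 0.05
is conservative.  The mean ± s.e. is reported as the test's summary, as is
conventional for this procedure.

**Linear mixed models.** Treatment contrasts for trip-level responses
(duration, distance, straightness, coast distance at 10 km) use a bird
random intercept; per-fix responses (homeward deviations) add a trip
intercept nested in bird.  Estimates use cell-means coding (one mean per
treatment level) fitted by REML; p-values come from likelihood-ratio tests
of ML refits against the intercept-only null (χ², df = 2).  Angular
deviations are treated linearly in (−180°, 180°]; this is valid because
homing deviations are concentrated far from the wrap point — a documented
limitation for highly dispersed data.  When the LR test is significant,
Tukey-adjusted pairwise contrasts follow, using scipy's studentized-range
distribution with between-bird containment degrees of freedom
(clusters − levels) — a conservative stand-in for Satterthwaite df, which
statsmodels does not expose.  Boundary fits (a variance component truly 0,
as happens for coastal deviations) are detected by a health check on the
standard errors and refitted down an lme4-style fallback chain
(trip-in-bird → bird → fixed effects only); the structure used is recorded
in the result.

**Binomial GLMMs.** Per-fix behavioural-state indicators (one model per
state × diel class) are modelled with a logit link, treatment as fixed
factor, and independent random intercepts for bird, trip and calendar date
(absorbing weather/moon variation).  No frequentist ML binomial GLMM exists
in the installed Python stack, so the estimator is implemented here as the
standard Laplace approximation (the same objective as lme4's `glmer` at
nAGQ = 1): sparse penalised IRLS for the joint fixed-effect/random-mode
maximisation, a Laplace correction for the marginal likelihood, Nelder–Mead
over log-σ.  On shared datasets it matches `glmer` fixed effects to < 0.05
on the logit scale (verified in the tests, where `glmer` serves as an
independent oracle).  LR tests compare full and null Laplace-ML fits;
overdispersion is checked as the sum of squared Pearson residuals over
residual df (≈ 1 for genuinely Bernoulli data).  With few birds per
treatment the LR test is anticonservative (measured ~10 % at nominal 5 %
with 6 birds/level — a property of the method, reproduced exactly by
`glmer`, not of this implementation).

**Foraging success.** The incubation mass-loss rate is the mean over
repeat-weighed reference birds of 100·(m₁−m₂)/m₁ per day.  Departure mass
discounts the deployment mass by that rate over the days incubated before
first departure; corrected gain is retrieval mass minus departure mass (and
reduces to the raw gain when departure is immediate).  Corrected gain is
regressed on foraging effort (number of foraging-state fixes; one fix =
5 min), treatment, and their interaction, with sequential F tests — each
term tested against the residual of the model including it, entering in
that order.

## The synthetic colony

The generator emits exactly the formats the reader consumes (Movebank-style
track CSV, metadata CSV, repeat-weighing CSV, GeoJSON coastline) with full
ground truth (per-fix states, onset indices, outbound bearings, biases,
masses).  Its defaults encode the study conditions: 10/9/9 birds per
treatment; 1 + Poisson(1.1) trips per bird (≈ 59 trips expected); 5-min
fixes; 3–10-day trips to foraging areas 120–220 km offshore; state speeds
0.3/1.8/6.7 m/s (truncated normal) with von Mises heading persistence per
state; day/night state-transition matrices that script more resting at
night; outbound bearings von Mises about per-treatment means
(317°/321°/285°) with bird- and trip-level concentrations; homing headings
von Mises (κ = 10) about the instantaneous home bearing plus a treatment
bias applied only beyond 40 km of the coast — +22° for anosmic birds, 0°
otherwise, plus a bird-level N(0, 5°) offset; incubation mass loss
1 %/day before departure and gain of 0.06 g per foraging fix (≈ 0.7 g per
foraging hour), which with realised foraging budgets reproduces
corrected gains of roughly 60–120 g.  Geometry is wholly synthetic: a 5-km
colony island plus a small island 60 km east stand in for an archipelago,
with the colony on the island shore.

What the generator does *not* emulate — and hence what passing tests do not
establish about real data: GPS position error and missing fixes; wind drift
and sea-surface currents; route fidelity and memory effects; coastline
following; prey-field structure in foraging areas; device failure. The
generator's turn distributions are also deliberately not the mixture
model's Gaussian family (headings are von Mises), so state recovery is a
mild robustness check rather than a self-fulfilling fit.  One mechanical
side effect worth knowing: the pelagic heading bias slightly lowers anosmic
straightness (≈ 0.94 vs 0.95), so on large synthetic colonies the
straightness LR test can reject even though the corresponding field result
was null — the generator scripts a bias, the field data may not contain one.

## Numerical and reproducibility choices

* All randomness flows from explicit `numpy` Generators; simulation,
  mixture restarts and the iterated test are seed-deterministic
  (byte-identical outputs under a fixed seed).
* EM restarts: n_init = 10 for analyses, smaller in scaled test fixtures;
  covariance floor 10⁻⁶ with a 10⁻³ retry on collapse.
* Elbow ties (perfectly linear log-likelihood growth) select the smallest K
  with a warning.
* Posterior ties in state assignment go to the slower state.
* Degenerate bearings (identical points) are defined as 0 with a warning.
* Mixed-model fallbacks and GLMM variance bounds (log σ ∈ [−5, 3]) guard
  boundary cases; complete separation in a GLMM level warns.
* Scaled problem sizes in the test suite (3 birds/treatment, 1–2-day trips,
  50–100-replicate simulations, 200-resample iterated tests) are chosen so
  the full suite runs in a couple of minutes while keeping every recovery
  check at the power levels quoted above; the acceptance script runs the
  full study-scale colony (~50–60 trips, ~100k fixes).

## Known limitations

* Spherical geodesy only (no ellipsoidal mode is wired in, though the error
  at trip scale is negligible).
* Satterthwaite df are approximated by containment; exact Satterthwaite
  would need the variance-parameter Hessian statsmodels does not expose.
* The angular LMM treats wrapped degrees linearly; with poorly oriented
  groups (deviations spread over the circle) its estimates degrade — the
  Watson–Williams machinery is the right tool there.
* The GLMM uses Laplace (nAGQ = 1); for very small clusters adaptive
  quadrature would be more accurate.
* Night classification uses one reference location/date per trip by design;
  trips spanning large longitude ranges shift the effective twilight by a
  few minutes.
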