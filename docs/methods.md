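# Methods

## Model structure

Two discrete-time Markov chains share a common skeleton. Cycle length is one
year; the horizon is 15 cycles; within a cycle, competing risks combine as
independent events, `P = 1 − Π(1 − p_i)`, and death takes precedence over
disease transitions. Death is the single absorbing state of each arm, and
every alive state routes at least the background all-cause hazard into it.

**Lobectomy arm (9 states).** Initial/perioperative → NED (with an optional
detour through an adjuvant chemo-/radiotherapy tunnel for pathologically
node-positive patients, prevalence `p_pN_positive`, default 0) → first
failure → {regional-salvage track, untreated-recurrence bridge, progressive
disease} → death. The local-only share of failures after lobectomy is 0, so
there is no local-salvage pathway in this arm.

**SABR arm (13 states).** As above, plus a local-failure detection state
whose salvage procedure is lobectomy (at the mortality of the attained age),
a distant-metastasis detection state, and separate post-salvage NED states
for local and regional salvage with their own progression probabilities.
One state, a best-supportive-care terminal bridge, is retained to mirror the
22-state clinical diagram but receives no inflow under the packaged
pathway — distant failures are booked in the detection state, which already
carries progressive-disease mortality.

### Timing conventions

These conventions were fixed once, jointly, by calibrating the base case
against the published age-stratified life expectancies, five-year survival
sequences, and sensitivity thresholds that the default parameter table is
meant to reproduce; they were not revisited afterwards.

- The **initial state consumes one cycle** carrying procedure mortality
  combined with background mortality; progression risk starts in cycle 2.
- A **salvaged** locoregional failure spends one cycle in a detection state
  (background mortality only) and one in the salvage state (procedure +
  background mortality) before reaching post-salvage NED.
- An **unsalvaged** locoregional failure spends one bridge cycle
  (background mortality only) before progressive disease.
- A **distant** failure faces progressive-disease mortality immediately, in
  its detection cycle — "directly enters" progression.
- Post-salvage progression enters progressive disease directly (salvage is
  not repeated).
- Progressive-disease mortality (0.6268/y) is combined independently with
  background mortality.

## Parameters

All inputs live in `src/lungmarkov/data/default_parameters.yaml` and are
either a point estimate with a literature range (`ProbabilityEstimate`) or
an age-indexed curve (`AgeCurve`). The table values are annual
probabilities; `mort_lobectomy` is the 90-day post-operative mortality at
the age of operation, applied once per operation (primary or salvage);
`mort_sabr` (0.0037) and `mort_conv_rt` (0.0010) are likewise one-off,
age-invariant procedure risks.

### Mortality curves

Only the endpoints of the two age-dependent mortality schedules are
published: background mortality 0.002491 at 45 and 0.082156 at 85, operative
mortality 0.0133 and 0.0800. A straight log-linear chord between those
endpoints overstates mid-age mortality — human log-mortality is convex over
45–85 (mortality accelerates with age faster than a single Gompertz rate) —
and depressed every stratum's life expectancy by 0.3–0.9 years. The
packaged curves therefore carry intermediate anchors every five years on a
log-quadratic schedule pinned exactly to the published endpoints,

`log q(45 + x) = log q(45) + s·x + c·x·(x − 40)`, x ∈ [0, 40],

with curvature `c` = 0.0016/y² for background mortality and 0.0005/y² for
operative mortality (`s` is the chord rate). Beyond 85 the curves continue
log-linearly at 0.7× the chord rate, reflecting the well-documented
late-life deceleration of mortality growth (Kannisto-type); anchors at 90,
95 and 100 encode this, and the horizon never asks for ages above 100. Both
curvature constants and the deceleration factor were chosen in the single
calibration pass described above. Interpolation between anchors is
log-linear; users can override the whole schedule with a life table
(`age,annual_mortality` CSV).

`p_pN_positive` defaults to 0 because no prevalence is published for the
node-positive adjuvant pathway; the pathway itself is representable and
configurable. `p_salv_dm` is housed for completeness but must be 0 — the
state graph has no distant-salvage pathway.

## Probabilistic sensitivity analysis

Each nondegenerate estimate gets a Beta distribution with mean fixed at the
point estimate and concentration fitted numerically so the 2.5%/97.5%
quantiles approximate the literature range; degenerate estimates and points
at 0 or 1 stay fixed, and a range inconsistent with its mean falls back to
Uniform(low, high) with a warning. Draws are independent across parameters;
parameters shared by both arms (progressive-disease mortality, the
background life table) naturally take the same value in both arms within an
iteration. The age curves are not varied: no uncertainty ranges are
published for them. The p-value is the two-sided normal approximation
`2(1 − Φ(|mean|/sd))` using the standard deviation of the per-iteration
differences, reported alongside the empirical two-sided tail fraction; the
interval is the empirical 2.5–97.5 percentile range.

Because the draws are independent, the spread of the difference grows with
the width of the progression-probability ranges and is widest in the young
strata (sd ≈ 1 y at age 45). Readers comparing against analyses that
correlate prognosis draws across arms should expect our intervals to be
wider at younger ages.

## Microsimulation

`microsimulate` pushes individual patients through the same transition rows
with an explicit seeded generator; per-patient life years use the same
half-cycle convention (death in the first cycle contributes 0.5 years), so
the sample mean is an unbiased estimate of the cohort life expectancy. It
exists to attach first-order (between-patient) variability to any scenario;
all headline numbers come from the deterministic cohort.

## Sensitivity analyses

One-way bars and two-way preferred-strategy maps evaluate the deterministic
life-expectancy difference at perturbed inputs, ranges taken from the
literature ranges in the parameter table. Threshold analysis bisects the
difference along one parameter to 1e-4 on the parameter scale and reports
"no threshold in range" when the sign never changes. The default two-way
grid is 101×101; grids are evaluated as one vectorized batch, so resolution
is cheap.

## Synthetic data

The fixture generators emulate the *structure* of real inputs: parameter
tables jittered uniformly within each literature range (uniform, not Beta —
fixtures test plumbing and range invariants, not inferential assumptions),
life tables sampled from the packaged background curve with lognormal
noise, and study points placed on the model's own predicted survival curve
plus Gaussian noise. They deliberately contain no features the model lacks
(no covariates, no time-varying hazards), so tests passing on them show the
machinery is correct, not that the model generalizes to any particular real
cohort.

## Numerical choices

- Transition rows are validated to sum to 1 within 1e-10 after hazard
  combination; a failure raises rather than renormalizing silently.
- Life expectancy is the trapezoid `0.5·S(0) + ΣS(1..n−1) + 0.5·S(n)`; an
  all-alive 15-cycle trace gives exactly 15.0 years. Survival at
  non-integer times interpolates linearly between cycle boundaries.
- Curve evaluation at an anchor returns the anchor value exactly (no round
  trip through the log scale); outside the anchor span the curve continues
  at the adjacent segment's rate, capped at 1.
- Two-way ties are declared within 1e-6 years of difference.
- All stochastic components take explicit integer seeds and are
  reproducible bit for bit.

## Known limitations

- The recurrence hazard from NED is constant over cycles (a single one-year
  probability is the only published input). Real recurrence hazards decay
  after 2–3 years; a constant hazard makes the late survival tail somewhat
  pessimistic, most visibly in the youngest strata, where our life
  expectancies sit at the low edge of the published values.
- No terminal tail beyond the 15-cycle horizon, no discounting, no
  cost/utility (QALY) dimension — the model compares survival only.
- Second primary lung cancers and repeated salvage are excluded by design;
  salvage happens at most once.
- The mid-age mortality values and the node-positive prevalence are
  calibrated or defaulted, not published; conclusions that hinge on exact
  mid-age mortality should re-run with a user-supplied life table.
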