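# Methods

## Model

The package implements a discrete-time illness-death (three-state)
model. A cohort is split into susceptible (*S*), ill (*I*) and dead
(tracked as cumulative deaths *D*). Each calendar year, a susceptible
individual becomes ill with probability *i_t* or dies with probability
*m_S,t*; an ill individual dies with probability *m_I,t*. There is no
remission (appropriate for highly lethal cancers) and no age structure:
the observed inputs are already age-standardized rates, and the model
operates on the standardized population directly. Propagation is
deterministic — compartments are real-valued expected counts — and time
steps are annual difference equations; no continuous-time integration
scheme is applied. For a closed cohort (zero entry stream) the identity
*S + I + D = const* holds exactly and is enforced in tests to 1e-9
relative. An optional per-year entry stream adds new susceptibles after
the transitions; all conservation statements refer to the closed case.

A deliberate naming choice: the two mortality parameters are named
structurally by the compartment they drain — *m_S* from the susceptible
compartment, *m_I* from the ill compartment — rather than by any
symbolic convention, because mislabelled mortality parameters are the
classic failure mode in this model family. The recursion above is the
single source of truth for what each parameter does.

### Closed form used as oracle

Under constant probabilities the recursion solves to

    S_t = S_0 a^t,  a = 1 − i − m_S
    I_t = I_0 b^t + i S_0 (a^t − b^t)/(a − b),  b = 1 − m_I

(with the a = b limit `t i S_0 a^(t−1) + I_0 a^t`). The simulator is
checked against this independent analytic route to 1e-12 relative error
for horizons up to 100 years; the closed form also gives exact expected
trajectories for the synthetic generator's constant-rate mode.

## Calibration

GBD rates are per **total** population. Converting them into
per-compartment annual probabilities therefore divides by the
compartment's population share: with proportions *p* (prevalence), *λ*
(incidence), *μ_c*, *μ_a* (cause/all-cause mortality),

    i = λ/(1−p),  m_I = μ_c/p  (0 when μ_c = p = 0),  m_S = (μ_a − μ_c)/(1−p).

Without the share correction *m_I* would be absurdly small for a rare
disease (a per-population cancer-death rate of 18/100,000 against a
prevalent pool of 100/100,000 is an 18% annual case fatality, not
0.018%). Rates are treated directly as annual risks; the actuarial
`1 − exp(−r)` conversion is available (`annual_risk="exponential"`) but
changes nothing material at magnitudes of 1e-4–1e-1 per year, and the
identity convention keeps calibration exactly inverse to the step
equations — noise-free synthetic panels round-trip to their generating
schedules at ≤1e-10 absolute error, which the acceptance suite checks.
Estimated probabilities are clamped into [0,1] only if a pathological
input demands it, with a logged warning.

### Extrapolation beyond the observed years

The data do not say how rates evolve after the last observed year, so
this is an explicit modelling choice with two options:

* `hold_last` — freeze the final observed year's probabilities;
* `loglinear` (default, window 10) — fit a straight line to
  log(probability) over the trailing window per parameter and extend it,
  clamped to [0,1]. A parameter with a non-positive value in the window
  has no log-trend and falls back to hold_last (logged). If extrapolated
  *i + m_S* exceeds 1 the pair is rescaled to the boundary (logged).

The default reflects that observed incidence/mortality trends carry
information about the near future; hold_last is retained for sensitivity
analysis. On exactly geometric schedules the log-linear rule is exact
(≤1e-9), another acceptance property.

## Projection and uncertainty

Projection re-anchors the cohort at the last observed year: *I* = observed
prevalence × N/1e5 on a standard population N = 100,000, *S* = N − I,
*D* = 0. Only the prevalence proportion matters for the reported rate, so
this normalization is harmless and keeps rates and counts numerically
identical. Reported outputs follow the field's table conventions: ASPR
per year (anchor through horizon), a 5-year snapshot grid starting the
year after the anchor, and two period percentage changes (first→last
observed from the data; anchor→horizon from the projection).

95% intervals are parametric-resampling ("Monte-Carlo") intervals: every
observed rate is redrawn from a lognormal whose 2.5/97.5 percentiles
match its reported bounds, the full calibrate → extrapolate → simulate
pipeline is rerun per draw (vectorised across draws), and the empirical
2.5/97.5 percentiles of projected ASPR across draws form the interval.
The point estimate is the no-noise run and is unchanged by the number of
draws. Draws are independent across cells — no year-to-year or
measure-to-measure correlation — which is the simplest defensible
propagation and a stated limitation: correlated input uncertainty would
typically widen intervals. Within the Monte-Carlo ensemble, structurally
inadmissible draws (cause > all-cause mortality, prevalence ≥ 100%) are
clipped rather than raised, since a tail draw must not abort the
ensemble; the strict checks still apply to observed data. With a single
draw the "interval" degenerates to that draw's trajectory, so the point
estimate need not lie inside it; for any realistic number of draws the
point sits within the interval and tests assert this at n ≥ 50. Default
draws: 1,000 (library), 200 (pipeline config default).

On synthetic ground truth with noise-consistent bounds the intervals
attain 93–95% empirical coverage at nominal 95% over 500 replicates of
the whole procedure (the acceptance suite requires [92%, 98%]).

## Synthetic data generator

The generator emulates the structure of a GHDx rate panel: complete
annual series per (location, sex) of the four measures with point values
and 95% bounds, written/read in the GHDx CSV dialect so synthetic data is
a drop-in for real extracts. It does **not** emulate age structure,
demographic change, GBD's estimation machinery, or correlated
uncertainty; passing tests therefore validate the *pipeline's*
mathematics, not GBD's data-generating process.

Ground truth: per key, base probabilities drawn uniformly from configured
ranges, temporally constant, linear, or log-linear per the config's mode.
Defaults mimic a rare, highly lethal cancer: incidence 3e-5–9e-5/year,
background mortality 6e-3–1.2e-2/year, annual case fatality 0.2–0.45,
initial prevalence 3–7 per 100,000, annual trend coefficient ±2%, closed
cohort of 100,000. Emitted rates use start-of-year denominators — e.g.
incidence_t = i_t·S_t/(S_t+I_t) — which is what makes calibration an
exact inverse.

Noise is multiplicative lognormal with mean 1 and coefficient of
variation `noise_cv` (σ² = ln(1+cv²)), independent per cell; bounds are
value ×/÷ exp(1.96σ), i.e. the noise law's 2.5/97.5 percentiles around
the emitted value. Mean-1 noise keeps cell means unbiased (tested via
1,000 replicates against a 3-standard-error band); the matching
resampling law in the interval construction makes the generator and the
uncertainty propagation mutually consistent. The data sources never
document how their published bounds arise, so this convention is the
package's own and is stated as such.

## Trend analytics

Scalar definitions: percentage change `100·(v_end − v_start)/v_start`;
AAPC is the geometric annual growth rate `100·((v_t1/v_t0)^(1/Δt) − 1)`;
sex excess `100·(pct_female/pct_male − 1)`; period fold-change
`pct_late/pct_early`, defined only for a positive early change —
sign-discordant pairs return a `SIGN_FLIP` sentinel because the ratio's
magnitude is meaningless there. Rankings break ties by lexicographically
smallest region label (logged); "exceeding" a threshold is a strict
inequality. Full precision is kept internally; rounding happens only at
display.

One documented discrepancy: applying the geometric AAPC to the bundled
global snapshots (5.448 in 2020, 6.093 in 2040) gives 0.561% per year,
whereas the published headline rounds the average annual increase to
0.5%. No standard formula reproduces 0.5% exactly from the printed
cells; the package keeps the geometric definition and reports what it
computes.

## Pipeline and determinism

`run_pipeline` is driven by one config mapping (or YAML file):

```yaml
seed: 123                  # master seed for every random stage
output_dir: out/
horizon_year: 2040
method: loglinear          # or hold_last
window: 10
n_draws: 200
input:
  kind: synthetic          # or ghdx
  path: extract.csv        # ghdx only
  synthetic:               # generator settings (see GeneratorConfig)
    n_locations: 2
    sexes: [male, female]
    noise_cv: 0.05
```

Validation happens before any computation; every stage logs row counts
and warnings. All randomness descends from `seed` (truth generation,
observation noise, and per-key interval seeds derived via a spawned seed
sequence so key order cannot leak randomness). The run manifest records
config and package version but deliberately no timestamp, so identical
config + seed yields byte-identical output bundles; readers parse floats
in round-trip mode so write/read cycles are exact.

## Problem sizes in the test and acceptance suites

Oracle sweeps use 40 random constant-rate settings over 100-year
horizons; conservation uses 20 random schedules of 5–60 years; the
noisy-recovery study uses 200 replicates of a 30-year single-key panel at
5% CV; the coverage study uses 500 replicates with 300 draws each,
vectorised so the whole acceptance run completes in well under a minute
on one CPU. These sizes give Monte-Carlo standard errors comfortably
inside the asserted bands (e.g. ~1 percentage point for coverage).

## Known limitations

* No age-period-cohort structure; the model works on already-standardized
  rates and cannot separate ageing effects from rate changes.
* No remission transition; unsuitable for diseases with recovery.
* Input-uncertainty draws are uncorrelated across cells; real GBD
  uncertainty is strongly correlated over years, so intervals here should
  be read as propagation of *independent* cell uncertainty.
* The entry stream is a configurable scalar/series, not a demographic
  model; population renewal realism is out of scope.
* Published-bounds semantics are assumed lognormal-symmetric on the log
  scale; other bound-generating mechanisms would need a different
  resampling law.
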