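# Methods

This note records the model as implemented, the defaults and why they were
chosen, the places where the design was genuinely open and what was decided,
and what the tests do and do not establish.

## Natural-history model

One woman's disease course is the triple (onset age, inverse growth rate,
symptomatic volume); everything downstream is a deterministic function of it.

**Onset.** The two-stage clonal-expansion survival
`G(t) = [(B−A)e^{Bt}/(Be^{(B−A)t}−A)]^δ` is implemented together with its
hazard and density; the identity `f = h·G = −dG/dt` is enforced by tests to
1e−6 (relative, central differences), which also pins the reading of the
density's constant as `(B−A)^δ`. The mapping from the four Poisson event
rates (division α, first mutation ν, death β, second mutation μ) to
(A, B, δ) assigns A to the smaller quadratic root and B to the larger, which
is the only assignment compatible with the constraints A < 0 < B and the
default value A = −0.0722.

Onset ages are drawn on the integer grid 38–92 with per-age mass f(t) and an
explicit no-onset category carrying the residual mass (about 0.795 at the
defaults). Sampled ages are jittered uniformly within the year so detection
ages are continuous rather than spiky. The population adjustment (default
0.48, the ratio of West-African to Northern-European age-standardised
incidence) supports two readings, selectable via `OnsetModel.adjustment`:

* `"age_scaling"` (default): the sampled age is multiplied by 0.48. Onset
  ages then lie in [18.2, 44.6] with median ≈ 34.6 years, and downstream
  in-window detection ages centre in the mid-40s.
* `"thinning"`: per-age onset probabilities are multiplied by 0.48 and ages
  are unchanged, yielding a median onset near 72 — far older than any
  reference summary — so it is not the default.

Neither reading can produce an onset-age upper quartile above 44.6 years
under scaling (0.48 × 93 is a hard ceiling), which is why the acceptance
gate comparing the simulated onset quartiles with the reference values
(median 38, IQR 29–46) cannot be fully green: the reference upper quartile
is arithmetically outside the support of the stated mechanism. The
age-scaling default is retained as the closer of the two defensible
readings.

**Growth and size.** Volume grows exponentially from
v₀ = π·0.5³/6 ≈ 0.0654 mm³ with individual inverse growth rate
r ~ Gamma(shape a, rate b), a = b = 0.8162 by default (mean 1, so the mean
volume doubling time is 365·ln 2 ≈ 253.0 days). Spheres throughout;
volume↔diameter conversions round-trip to 1e−12.

**Symptomatic detection.** The hazard of noticing symptoms is η·V(x) with
η = e^{−9.644} ≈ 6.481×10⁻⁵ per mm³·year. Conditional on r the excess
symptomatic volume is Exponential(η·r), sampled by inverting a fresh
uniform variate; a Kolmogorov–Smirnov test on 10⁵ draws guards the law.
When a maximum diameter is configured the exponential is truncated through
its inverse CDF (`u' = u·F(v_max)`), which is equal in law to resampling
until the cap is met but deterministic in the number of draws consumed.
**No maximum is applied by default**: under the untruncated Lomax marginal
the >50 mm share of symptomatic sizes is 22.6%, matching the reference
unscreened-arm share (22.19%) where a 120 mm truncation would give 20.2%;
the 120 mm and ≤50 mm variants are treated as display filters, available via
`DetectionModel(max_diameter=...)`.

Follow-up is age-based: symptomatic ages beyond `max_follow_up_age`
(default 100 years) count as never diagnosed. Calendar cohort years
(1985–2020 by default) are labels only.

## Screening overlay

Screens occur instantaneously at `start, start+interval, …` up to the
largest age ≤ `end`. Attendance is either perfect, absent, or a permanent
two-type mixture (80% of women attend each screen independently with
probability 0.90, 20% with 0.15). At each attended screen with the tumor
latent (onset ≤ x, symptomatic age > x), detection is a Bernoulli draw with
logistic probability `expit(β₀ + β₁ d(x))` in the current diameter;
draws are independent across screens (no per-tumor frailty beyond size),
and the first success wins. Ties between a screen age and the symptomatic
age go to symptomatic detection.

Interval cancers are symptomatic detections preceded by ≥ 1 attended
negative screen and occurring before the next scheduled screen — or before
the program's end age when the last attended screen has no successor. An
attended screen before tumor onset counts as negative (a symptomatic case in
an attender whose tumor arose entirely after her last attended screen is
still an interval case if it surfaces before the next scheduled screen).
Symptomatic cases with no prior attended screen are "other symptomatic".

Randomness is organised as named substreams of the master seed (onset,
growth, symptomatic, attendance type, attendance, sensitivity), so every
policy overlaid on the same master seed reuses the identical natural history
— strategy comparisons are paired (common random numbers) — and raising β₁
or attendance on a fixed seed can only add screen detections (coupling,
enforced by test).

## Strategy evaluation

Both arms are windowed to detections at ages within the policy's
[start, end]: this is the only windowing under which per-strategy
no-screening counts differ across strategies and under which the
overdiagnosis identity `Q = (N_scr − N_abs)/N_scr` reproduces the reference
percentages from the reference counts. Screen-detected and interval
percentages are shares of the screened arm's in-window count. Size bins are
[0,10), [10,20), [20,50], (50,∞) mm — closed at 50 so the four labels
partition all sizes.

## Estimation

The likelihood is the Lomax-type marginal
`f(v) = η a bᵃ/(b+η(v−v₀))^{a+1}` over volumes obtained from diameters via
the sphere formula (applied once, internally). The fit maximises the
log-likelihood in (log η, log a) with b = a by substitution (default; an
unconstrained three-parameter variant exists), using L-BFGS-B with the
analytic gradient, initialised at η = 1/mean(v−v₀), a = 1, with tolerances
gtol = 1e−10 on the log scale. Densities are evaluated in log space to
survive extreme shapes (a = b ~ 10⁴ is used in tests to check the
degenerate-growth limit). Standard errors invert the observed information,
computed by numerical differentiation of the negative log-likelihood at the
optimum on the natural scale; non-convergence and degenerate (constant)
data are flagged on the result object, never raised mid-pipeline.

The interval multiplier defaults to **1.645**, because the reference
interval this package reproduces is labelled "95%" but has half-widths equal
to 1.645×SE; `z_multiplier=1.96` gives the conventional two-sided 95%
interval. This discrepancy is surfaced in the API documentation rather than
silently corrected.

## Synthetic data

The generator draws (r, V) exactly from the model the likelihood assumes and
is the package's stand-in for the undeposited 187-case clinical series.
Optional 0.5 mm rounding mimics histology reporting (nearest increment,
floored at 1.0 mm so rounded sizes stay inside the likelihood's support —
the probability mass below 0.75 mm is ~1e−5, so the floor is practically
inert); rounding is off by default because the likelihood treats sizes as
exact. The generator emulates none of the features that make real clinic
data hard: no referral/selection bias, no measurement error beyond optional
rounding, no stage, grade, laterality or age covariates, no missingness.
Passing the generate-and-fit loop therefore shows correctness of the
estimator under the model, not robustness to real-world violations of it.

## Problem sizes

Strategy grids run on the study-size population of 5,000 births × 35 cohorts
(175,000 women; ~2 s per 12-scenario grid). Duration summaries (doubling
times by detection mode, presence times of interval cancers) use a larger
cohort of 28,572 × 35 ≈ 10⁶ women, the size at which the reference medians
were reported. Parameter-recovery checks use n = 20,000 (consistency) and
200 replicates of n = 187 (sampling spread).

## Known limitations and non-reproducible reference quantities

The acceptance layer compares simulation output against reference values at
their stated tolerances, and several comparisons fail *reproducibly and for
structural reasons*; they are left failing rather than papered over:

* **Screen-detected shares.** Under per-screen independent Bernoulli
  sensitivity, a tumor that is latent through many attended screens is
  detected with probability approaching one: with perfect attendance and
  biennial screens at ages 40–74 this package finds ~82% of in-window
  diagnoses screen-detected, where the reference reports 43%. Reproducing a
  43% share would require roughly one effective screening exposure per tumor,
  which contradicts the stated schedule/attendance semantics. The same
  saturation raises screen shares and depresses interval shares across the
  whole strategy grid.
* **Interval-cancer durations.** The reference's interval-cancer summaries
  are mutually inconsistent under this model: a median doubling time of
  168 days (r ≈ 0.66) together with a median interval size of 35 mm implies
  a median presence time of ≈ 8.4 years (r·ln(V/v₀)), not the reported
  3.9 years. This package's interval cases — the fast minority that slips
  between screens — show short doubling times and presence times instead.
* **Onset quartiles.** See the onset section: the reference upper quartile
  (46 years) exceeds the hard ceiling (44.6) of the 0.48 age-scaling it
  states.
* **Shape-parameter standard error.** The observed-information SE of b at
  n = 187 is ≈ 0.100, and 200 generate-and-fit replicates give an empirical
  spread of 0.107 — the two agree, but both are five times the reference's
  printed 0.0201, which corresponds to an information content of roughly
  5,000 observations.

Beyond reproduction issues, the model itself omits competing mortality,
false-positive recalls, mammographic-density effects on sensitivity,
covariate heterogeneity and any mortality or cost outcome; it compares
strategies only on diagnosis counts, detection modes, sizes and timing.
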