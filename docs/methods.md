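# Methods

This note documents the statistical model implemented in `perimort`, the
choices made where the method leaves room, and the known limitations. It
makes no empirical claims beyond quantities computed by the test suite and
`scripts/acceptance.py`.

## Data structure

The unit of analysis is a pregnancy of at least 7 months' gestation reported
in a household survey. After eligibility filtering (minimum gestation,
conception-offset window, interview-month handling), each pregnancy is
placed on one of ten analysis intervals:

| j | interval | event |
|---|----------|-------|
| 1 | STB      | stillbirth (fetal death ≥ 7 months) |
| 2 | D0-1     | death on day 0 or 1 of life (pooled) |
| 3–10 | D2 … D9 | death on a single day of life |

Days 0 and 1 are pooled because surveys record them inconsistently.
Ongoing pregnancies are censored in interval 1; everything alive at the
start of day 10 is censored there. Because censoring happens only at
interval boundaries, the at-risk flow is exact:
`n[j+1] = n[j] − d[j] − c[j]`. An optional actuarial half-interval
correction (`compute_life_table(..., actuarial_censoring=True)`) exposes
the conventional alternative; the default uses the exact flow.

Interval risks are `q_j = d_j / n_j`, and

- SBR = 1000·q₁,
- ENMR = 1000·(1 − ∏_{j=2..7}(1 − q_j)) (days 0–6 only: early neonatal),
- PMR = 1000·(1 − (1 − q₁)(1 − ENMR/1000)).

Days 7–9 are tabulated and modeled (they carry the heaping signal) but do
not enter the reported rates.

## Quality indicators and reference bands

Four indicators are computed from the death counts:

- heaping index = 5·d₇ / (d₅+d₆+d₇+d₈+d₉),
- STB/D0-1, STB/first-week, D0-1/D2-6 death-count ratios.

Each is classified against contiguous, lower-inclusive reference bands
(probable / plausible / improbable; D0-1/D2-6 is one-sided with an
"under-reported" band below 2.4). An indicator with a zero denominator is
`None` and classified "unclassifiable"; undefined indicators never trigger
an adjustment.

Two constants drive the adjustments and are exposed as
`CONSTRAINT_CONSTANT = 1.89` (STB/D0-1 in complete data) and
`WEIGHT_CONSTANT = 2.4` (D0-1/D2-6 in complete data).

## Models

All four models maximize the product-binomial likelihood
`∏_j Binomial(d_j; n_j, q_j)` with `q_j = 1 − exp(−h_j)`.

**Model 1 (saturated piecewise-exponential).** One log-hazard per interval,
fitted as a Binomial GLM with complementary-log-log link (statsmodels).
Saturated, so it reproduces the observed life table exactly; intervals with
zero deaths get a `−inf` log-hazard sentinel (q = 0) and are flagged. This
equivalence is verified to 1e-6 on 100 random tables.

**Smooth late hazard (models 2–4).** Days 2–9 share a modified
Gompertz–Makeham hazard `h(x) = γ₀ + exp(α + β·x)` evaluated at interval
midpoints x = 2.5, …, 9.5. The STB and D0-1 hazards remain free, so the
likelihood separates: the free hazards have closed forms, and (γ₀, α, β)
are fitted by L-BFGS-B with bounds γ₀ ∈ [0, 1], α ∈ [−30, 2], β ∈ [−5, 5]
and three deterministic starts derived from the crude late-death level.
The smooth hazard cannot reproduce a day-7 spike, so fitted expected deaths
are de-heaped by construction; the fitted heaping index is reported.

**Stillbirth constraint (models 2 and 4).** Triggered when observed
STB/D0-1 < 1.89. When active, the stillbirth log-hazard is set to
`γ₁ = γ₂ + log(1.89)` — exact on the hazard scale — with γ₂ estimated from
the D0-1 data, and the stillbirth interval is *excluded from the
likelihood*. This is an imputation reading of the constraint: the observed
stillbirth count is treated as uninformative (that is precisely the
diagnosis that triggered the constraint) and replaced by the value implied
by the better-reported D0-1 hazard. The alternative — a jointly
constrained MLE over both intervals — would shrink the adjustment toward
the corrupted observed counts and largely defeat its purpose; it is not
implemented.

**D0-1 weighting (models 3 and 4).** Triggered when observed
D0-1/D2-6 < 2.4. D0-1 deaths are multiplied by w = 2.4 / (observed ratio),
which restores the ratio exactly. Flow is re-balanced by reducing later
entrants and absorbing the difference into day-10 censoring (default), or
by inflating the cohort total (`weighting_balance="inflate-cohort"`).
Weighting touches only the D0-1 interval, so model 3 never moves the
stillbirth rate. Model 4 weights first, then re-evaluates the constraint
trigger on the weighted table: up-weighting D0-1 lowers STB/D0-1, so the
constraint can fire under model 4 even when the raw ratio looked healthy —
the mechanism by which the two adjustments compound.

Model log-likelihoods are reported both on the table each model was fitted
to (`loglik_`) and on the raw input table (`loglik_input_`); the latter
makes unconstrained ≥ constrained comparisons well-defined.

## Synthetic generator

`TrueCohortParams` holds a stillbirth risk and nine interval hazards
(pooled D0-1, then days 2–9); true rates are computed analytically from
the parameters, so the estimand is exact, not itself sampled.
`calibrated_cohort_params` solves (scipy `brentq`) for the D0-1 hazard and
the scale of a geometrically declining day 2–9 hazard so that *expected*
death-count ratios hit 1.89 and 2.4 exactly — the regime in which the
adjustment models are correctly specified.

`ReportingErrorParams` corrupts records with mutually exclusive per-record
draws: stillbirth omission, stillbirth→D0 transference, D0→stillbirth
transference, D0-1 omission, and day-{5,6,8,9}→7 heaping. A truth ledger
records every affected record. The "typical" preset (35% stillbirth
omission, 5%/3% transference, 40% D0-1 omission, 30% heaping) was designed
from expected-value arithmetic before any recovery run, to represent the
error profile that motivates the method.

**Realism limits.** The generator is deliberately stylized: hazards are
homogeneous across pregnancies (no frailty, no covariates, no clustering or
survey design effects); gestation and conception offsets are coarse;
reporting errors are independent across records and of fixed probability
(real omission correlates with time since the event and respondent
characteristics); heaping only moves deaths onto day 7 from days 5–9, never
from outside the window and never onto day 14/21. Recovery results measure
internal consistency of the adjustment under its own error taxonomy, not
performance on any real survey.

## Numerical choices

- Optimizer: L-BFGS-B, tolerance 1e-8, ≤ 500 iterations, three
  deterministic starts; failure of all starts raises with a trace rather
  than returning a silent best-effort fit.
- Zero-death intervals use exact `q = 0` sentinels; log-likelihood terms
  use `log1p(−q)` for survivors and skip `d·log q` when d = 0.
- Quantiles in multi-survey summaries use numpy's `median_unbiased` method,
  fixed for reproducibility; relative differences are summarized as the
  median of per-survey values, not the difference of medians.
- All randomness flows through `numpy.random.default_rng`; derived seeds
  are drawn below 2³¹. The recovery experiment isolates replicate failures
  (excluded with a warning and counted) rather than aborting.

## Limitations

- The constants 1.89 and 2.4 are treated as known; their sampling
  uncertainty is not propagated, and no standard errors or intervals are
  produced for the adjusted rates (jackknife/bootstrap would be the natural
  extension).
- The constraint and weighting triggers are sharp thresholds; surveys
  sitting near a boundary get all-or-nothing adjustment, and with clean
  data calibrated exactly at a boundary the trigger fires in about half of
  replicates, adding one-sided noise (the test suite demonstrates this).
- Adjustment assumes the D0-1 deficit relative to D2-6, and the stillbirth
  deficit relative to D0-1, are entirely reporting error; true epidemiology
  that deviates from the reference ratios will be "corrected" toward them.
- Sampling weights are accepted in tabulation but the likelihood treats
  weighted counts as if they were real counts (no design-effect
  adjustment).
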