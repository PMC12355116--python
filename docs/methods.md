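# Methods

This note documents the models, conventions and numerical choices behind
`gabadose`, and what the synthetic-data tests do and do not establish about
real claims data.

## Exposure reconstruction

Claims data record dispensing dates and quantities, not regimens or days'
supply, so exposure is reconstructed from the dispensing stream alone. A
treatment episode is a maximal run of dispensings of one drug in which
consecutive dispensings are separated by at most `gap_threshold_days`. The
default 35 days reflects a four-week maximum dispensing period plus a
one-week grace period; 42- and 56-day thresholds are run as sensitivity
definitions. Gaps are measured between dispensing *dates*, not estimated
supply-exhaustion dates, and same-day rows are summed into one dispensing
(claims can split one dispensing across package rows).

**Episode duration.** An episode defined as "first to last dispensing" has
zero duration when it contains a single dispensing, making the average
daily dose undefined. Every episode is therefore extended by
`terminal_supply_days = 28` (one maximum supply period) past its last
dispensing. Applying the same extension to every episode, rather than only
to singletons, keeps doses comparable across episode sizes. This convention
is this package's documented choice; duration = (last − first) + 28, and
the episode midpoint is start + ⌊duration/2⌋ (floor, for deterministic
integer dates).

**Dose.** Average daily dose = total mg dispensed in the episode / duration.
Doses are standardised in Defined Daily Doses (pregabalin 300 mg,
gabapentin 1800 mg). High-dose use means an average daily dose *strictly*
above the maximum recommended dose (600 mg pregabalin, 3600 mg gabapentin —
exactly 2 DDD for both); an average of exactly the maximum is not flagged.

## Cohort selection

New users have ≥3 dispensings of the index drug within 365 days of the
first one (the cohort entry date, anchored at the first in-window
dispensing), no index-drug dispensing in the 365 days before entry, age ≥18
(computed as entry year minus birth year, claims-style; exactly 18 is
eligible), known age and sex, and enrolment covering every day of
[entry−365, entry] (a configurable gap allowance defaults to 0). The
washout applies to the index drug only by default, because prior exposure
to the *other* gabapentinoid is a model covariate and would be impossible
under a both-drug washout; a config switch (`washout_drug_scope`) provides
the stricter variant. The ≥3-dispensing qualification counts index-drug
dispensings only, consistent with two separately selected cohorts. Rules
are applied in a fixed order (window → prevalent → occasional → under-age →
missing demographics → enrolment) and each exclusion is attributed to the
first rule that fires, so attrition counts are order-dependent but conserve
the screened total exactly.

## Outcome and survival analysis

The event is the midpoint of the first high-dose episode; time runs from
cohort entry, capped at 730 days, censored at the earliest of death from
any cause, loss to follow-up (enrolment end) and the cap. Death is treated
as censoring, not a competing risk — cumulative incidence is F(t) = 1 −
S(t) with S the Kaplan–Meier estimate — so F(t) is interpreted as the
incidence that would be observed absent death, consistent with the
estimand the pipeline is built to reproduce. An Aalen–Johansen
competing-risk estimator is deliberately out of scope. Zero event times are
clamped to 0.5 days. Person-years use 365.25 days/year (configurable).

Incidence-rate CIs default to the natural-scale Wald interval
rate ± 1.96·rate/√D; the Garwood exact-Poisson interval is available and is
the automatic fallback at D = 0. At large D (tens of thousands of events)
the natural, log-scale and exact intervals agree to printing precision, so
the choice is cosmetic there; it matters for small-event subgroups.
Log-rank p-values below 10⁻⁴ are printed as "p < 0.0001".

## Cox model of associated factors

Continuous covariates (age, deprivation index, number of prescribers)
enter as restricted cubic splines with 5 df: the Harrell truncated-power
basis with 6 knots at the standard quantiles (.05, .23, .41, .59, .77,
.95), linear beyond the boundary knots. The 5-df/6-knot reading of "five
degrees of freedom" is pinned in tests; a lower df is a config change. When
a covariate has too few distinct values for the requested df (number of
prescribers typically does in simulated cohorts), the term degrades to the
largest feasible df, down to a plain linear term, with a warning —
degrading beats aborting an otherwise valid run; calling `rcs_basis`
directly with an infeasible df still raises.

Ties are handled by Efron's method (fitted via lifelines' Newton solver); a
Breslow option uses an in-package Newton–Raphson maximiser (gradient
tolerance 10⁻⁸, step-halving, divergence of any coefficient beyond ±20
reported as separation). The two coincide exactly on tie-free data, which
is tested. The robust (sandwich) covariance A⁻¹BA⁻¹ is computed from
per-subject score residuals at the fitted coefficients; on tie-free data it
reproduces lifelines' robust standard errors to machine precision. Under
non-proportional hazards, coefficients are read as time-averaged log hazard
ratios, which is why the robust variance is the default. Missing covariate
values are handled by complete-case deletion only.

Proportionality is assessed with the Grambsch–Therneau score test computed
from Schoenfeld residuals: with transformed, centred event times c_k, d
events, model-based covariance V and u = Σ_k c_k s_k, the per-covariate
statistic is d(Vu)_j²/(V_jj Σc²) on 1 df and the global statistic
d·u′Vu/Σc² on p df. The default time transform is the Kaplan–Meier
transform g(t) = 1 − S_KM(t); identity and rank transforms are available.
Type-I error of the global test is verified by simulation (5% ± 3% over 200
proportional-hazards replicates). Time-varying coefficients β(t) are
lowess smooths (span 0.75 over event times, configurable) of the scaled
residuals d·V·s_k + β̂, with a pointwise normal band from the local
residual spread — a descriptive band, not a simultaneous one.

## Descriptive conventions

Baseline-table percentages use the full cohort as denominator for age and
sex (never missing by design) and exclude missing values from the
denominator for fields that can be missing (initial prescriber,
deprivation, the comorbidity block). This convention is pinned by
arithmetic tests against published cohort counts.

## Trends

Monthly new-user counts per drug are divided by a user-supplied monthly
population table (per 100,000); months without entries count zero. The
series is decomposed additively with STL (period 12, seasonal smoother 13,
robust fitting on — the decomposition parameters are package defaults, not
reported values). Components sum to the input exactly; both the raw and
trend series are written.

## Synthetic-data generator

The generator emulates the structure the pipeline consumes, with a known
ground truth:

- **Event process.** Each patient draws a latent event time from an
  exponential proportional-hazards model, rate = baseline_hazard[drug] ×
  exp(Σβz). Default β are the published pregabalin-cohort hazard ratios
  (man 1.67, opioid agonist treatments 3.30, paraplegia 1.94, prior other
  gabapentinoid 1.92, active cancers 1.32, strong opioid analgesics 1.27).
  Baseline hazards (0.0176 / 0.0057 events per person-year) were chosen by
  marginalising those HRs over the default covariate mix so the measured
  rates land near 26 and 10 per 1000 person-years. Continuous effects (age,
  deprivation) are supported but default to zero, so fitted spline curves
  are legitimately flat under the defaults.
- **Expression.** A latent event before censoring is expressed as one
  high-dose episode whose midpoint is placed on the latent day (exactly, in
  the common case; within half a refill interval when the event falls
  inside the first episode), drawn from a shifted-lognormal dose regime
  strictly above 2.05 DDD (median ≈ 2.4 / 2.3 DDD). Non-event episodes draw
  therapeutic doses capped strictly below 2 DDD. This makes parameter
  recovery through the full chain well-posed, which is the generator's
  purpose.
- **Structure.** Refill gaps uniform on 18–35 days (mean 26.5), dispensings
  per episode 1 + Poisson(1.1), episodes per patient 1 + Poisson(3.2),
  inter-episode gaps 45–130 days: these knobs were set once to put cohort
  medians (age 64, 4 episodes, ~50-day durations, 2 prescribers) near the
  published baseline table; per-dispensing quantity distributions have no
  published empirical counterpart and are calibration knobs. Entry dates
  follow per-drug piecewise-linear monthly trends (pregabalin declining
  after 2019, gabapentin rising) with mild seasonality, so the trends stage
  has signal.
- **Ineligible records.** Configurable fractions of prevalent users (with a
  monthly dispensing chain reaching back before the inclusion window),
  occasional users (≤2 dispensings), minors, missing demographics and
  enrolment-gap patients are injected (defaults 6/6/1/1/2%, far below the
  real-world attrition share, to keep simulated cohorts compute-efficient).
  An "eligible" patient whose drawn death or loss truncates the stream
  below three dispensings is relabelled occasional, since that is what the
  realised record is.
- **Quantities in milligrams.** Dispensed amounts are emitted directly as
  total mg (box counts × strength collapsed), since the dose computation
  needs only total mg. Missing values are genuine empty fields, never
  sentinels.

**What the generator does not emulate:** dose titration within episodes,
stockpiling across drugs, seasonal dispensing behaviour, informative
censoring, region-level deprivation structure, or real prescriber networks.
Passing recovery tests therefore show the *pipeline* is correct under the
assumed proportional-hazards data-generating process, not that the model is
correctly specified for real claims data.

## Problem sizes and test design

The calibration and sensitivity checks run on a 50,000-patient simulation;
full-chain hazard-ratio recovery runs 20 seeds at n = 50,000 and checks
robust-CI coverage (≥17/20); the proportionality-test calibration uses 200
replicates at n = 2,000; the acceptance script runs the end-to-end pipeline
at n = 60,000 plus one 400,000-patient single-cohort run for hazard-ratio
recovery, where the 0.7%-prevalence opioid-agonist-treatment factor
accumulates enough events for a stable estimate. Oracles are independent of
the code paths they check: exhaustive cut-point enumeration for episode
segmentation, a from-scratch product-limit estimator for Kaplan–Meier,
direct partial-likelihood enumeration and grid search for the Cox fit, and
closed-form arithmetic for rates and percentages.
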