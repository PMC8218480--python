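# Methods

## The model

`multistate_aging` projects how many older adults (65+) live with
functional disability and/or cognitive impairment over a multi-decade
horizon, using a deterministic dynamic multi-state cohort-component model.

**State space.** Cognition is graded from the MMSE total (0–30) into
intact (≥ 24), mild (18–23), moderate (10–17) and severe (≤ 9) impairment;
function from the count of limited ADL items (six basic self-care
activities) into active (0), 1–2 limitations and 3+ limitations. Their
cross product gives 12 living composite states; death is a 13th absorbing
composite value, so every transition-kernel row is a single probability
vector. For reporting, living states collapse into four impairment
classes (none / ADL only / CI only / CI and ADL), and a state carries
nursing-home-type care needs when it has 3+ ADL limitations or
moderate-to-severe cognitive impairment.

**Structural zeros.** Recovery out of moderate or severe cognitive
impairment, and out of 3+ ADL limitations, is forbidden by design. These
transitions are excluded from the multinomial choice sets (not zeroed
after fitting) and are exactly 0 in every emitted rate table, including
after the improvement adjustment.

## Transition estimation

The estimation input is a two-wave panel with a two-year gap: per
respondent, sex, age, a sampling weight, cognitive and functional
category at each wave, and vital status at wave 2. A midpoint state is
imputed for the unobserved year: identical wave states are carried
through; differing states (death included) resolve to the wave-1 or
wave-2 value with a fair coin. Each respondent then contributes up to two
one-year transition pairs (the second is dropped when the imputed
midpoint is death). Both pairs enter the likelihood; the dependence
between a respondent's two pairs is ignored in point estimation and is
instead carried into the intervals by resampling whole respondents in the
bootstrap.

Each process is fitted per origin with a weighted multinomial logit,
"stay" being the reference category:

* cognitive: `ln(p_ij/p_ii) = b0 + b1·age + b2·age² + b3·sex`
* functional: `ln(p_ij/p_ii) = b0 + b1·age + b2·sex + b3·ci`

with sex coded female = 1 and `ci` (any cognitive impairment) = 1. For
the functional process the CI covariate is measured at the start of each
interval: wave-1 cognition for the first pair, imputed midpoint cognition
for the second. Age is centred at 80 internally (ages 65–100 with a
quadratic are ill-conditioned otherwise); CSV exports report the natural
scale. Ages above 100 are evaluated at 100 (open age interval). The
solver is a small Newton–Raphson with analytic Hessian, step halving and
warm starts (needed to keep hundreds of thousands of bootstrap refits
fast); it is cross-checked in the tests against a closed-form binary MLE
and against scikit-learn's unpenalised multinomial regression. Permitted
destinations never observed in the data are pinned at intercept −20
(probability ≈ 0) with a logged warning rather than failing.

### Known estimator biases

Two biases are intrinsic to this design and documented rather than
patched, because they are properties of the published method itself:

1. **Midpoint-imputation shrinkage.** Converting a two-year observation
   into two one-year pairs slightly under-counts transitions relative to
   exposure when the destination is not absorbing. The asymptotic effect
   on a one-year probability is a multiplicative odds shrinkage of order
   `(p_ii + p_jj) / ((3 + p_ii²)/2)`; it is negligible when annual rates
   are small and grows with turnover (−0.05 to −0.25 on the log scale for
   stay probabilities between 0.92 and 0.80).
2. **Death-source confounding.** The panel records a single vital
   outcome, generated by the competing action of both processes, yet each
   process's model carries death as one of its own destinations. Each
   fitted death intercept therefore approximates *total* mortality
   (≈ +ln 2 when the two processes kill at similar rates), and the
   projection's product-of-survivals combination
   `1 − (1 − p_death_cog)(1 − p_death_fun)` correspondingly double-counts.
   No de-duplication is attempted because the two death outcomes are
   deliberately fitted in separate models, as in the original analysis.

Consequence: parameter-recovery experiments that push survey data through
the full pipeline cannot reproduce the generating kernels to tight
tolerances even at large n; the recovery acceptance check reflects this
honestly. Interval-calibration (coverage) studies are run in the
dedicated low-turnover `calibration` preset with single-process mortality
variants, where the estimator is consistent for its own truth kernel and
coverage measures the bootstrap rather than these biases.

## Bootstrap

Design weights are rescaled to sum to one and used as draw probabilities;
each replicate draws n respondents with replacement (a respondent may
appear once, several times or never) and re-enters estimation with unit
weight — the design weight was consumed by the sampling probability, and
weighting again would double-count it. Replicate r uses seed
`base_seed + r`; failed replicates are redrawn with a shifted seed
(logged), and more than 5% failures is a hard error. Intervals are simple
percentiles of the replicate distribution (BCa is out of scope); when
demographic inputs are supplied the full projection is re-run per
replicate so projected counts get intervals too.

## Projection

State: a sub-65 feeder population (single-year ages 0–64 × sex) and the
65+ population (ages 65–100+, 100+ an open accumulator, × sex × 12
states). Update order within each calendar year, fixed and pinned by a
nested-loop oracle test:

1. births = Σ female stock(a) × fertility(a), ages 15–49, split
   male : female by the sex ratio at birth (default 1.05, configurable;
   unstated in the source material);
2. sub-65 survival with `q(a)·(1 − 0.015)^(year − 2010)`, net migration
   (default zero; only ages 0–64 carry migration), one-year age shift;
   survivors of 64 leave as entrants, births enter age 0;
3. 65+ transitions with rates adjusted by the improvement schedule:
   worsening and death probabilities × `(1 − 0.01)^(year − 2014)`, freed
   mass returned to the stay probability, recovery untouched. Years
   before the 2014 base are clamped (no adjustment), since the projection
   starts in 2010;
4. 65+ age shift (99 → 100+, 100+ accumulates);
5. entrants join the intact-active state at 65.

The cognitive kernel is applied before the functional kernel, and the
functional kernel's CI stratum is read from the *updated* cognition —
this is the mechanism by which cognitive decline drives the onset of
functional disability. The alternative order is available behind
`AssumptionSchedule(kernel_order="functional_first")` for sensitivity
analysis. Dynamics are expected-value stock-flow (fractional persons); a
flow ledger records births, deaths and entrants, and the conservation
identity `total(t+1) = total(t) + births − deaths + migration` is checked
to 1e-9.

The 1.5%/yr mortality decline applies to the sub-65 life table only; 65+
death transitions improve through the 1%/yr rule — applying both to the
same flows would double-count improvements. The 65+ initial population
enters intact-active by default (consistent with the entry-at-65
assumption; the source material states no initial health-state mixture),
so early projection years under-state impairment until the state
distribution burns in; an explicit `initial_state_mixture` can be passed.

## Synthetic data

The generator stands in for restricted survey and census inputs and
targets structural, not empirical, realism.

* **Surveys** (`generate_survey`): wave-1 ages from Beta(1.2, 2.0) over
  65–100 (front-loaded, with a long old-age tail), 1010 : 814
  female : male mix, log-normal weights (σ = 0.5; a unit-weight option
  exists for clean recovery experiments), wave-1 states from stated
  mixtures (cognition 0.55/0.20/0.15/0.10, function 0.55/0.28/0.17), then
  two sequential *annual* transitions from the truth kernels using the
  projection's combination order. The midpoint is hidden, as in real
  two-wave data, so the imputation rule is exercised under realistic
  information loss; a debug flag exposes it for oracle tests.
* **Demographics** (`generate_demographics`): a large ageing population
  (1.36 billion, 51.2% male) with a flat-then-tapering age pyramid,
  below-replacement fertility (TFR 1.65 → 1.60 over 2010–2017, frozen
  thereafter, Gaussian age profile centred at 26), and a sub-65 life
  table with an infant spike plus Gompertz adult mortality (male
  excess 1.15). Deterministic per scenario; a seed only feeds optional
  jitter.
* **Presets**: `null` (identity dynamics — projections stay intact-active
  forever), `realistic` (worsening/death rising with age, recovery
  falling, women transitioning into cognitive impairment more and dying
  less, men worsening functionally more), `stress` (high turnover),
  `calibration` (low turnover for coverage studies, see above). Preset
  coefficients ship as YAML on the age-centred scale.

What a green test does *not* establish: agreement with any real
population's marginals, the true size of either estimator bias in real
data, or the realism of the assumption schedules — those are modelling
choices taken as given.

## Numerical choices

* Rate-table rows sum to 1 within 1e-12; projection conservation within
  1e-9; structural zeros are exact.
* Newton solver: convergence at max |gradient| < 1e-9·Σw, Levenberg ridge
  1e-10, 40 step-halvings; non-convergence raises with the origin named.
* Annualised change columns are arithmetic (total change / horizon), not
  geometric — the identity the published tables satisfy.
* Rounding in rendered tables is round-half-to-even at 3 d.p. for counts
  (millions), 2 d.p. for annual and 1 d.p. for total percentage changes.
* Lost-to-follow-up respondents (alive-but-unobserved at wave 2) are
  dropped with a logged count; their transitions are unobservable.

## Limitations

* No provincial or urban/rural disaggregation, no cost projections, no
  calibration against official population statistics.
* Migration defaults to zero and is only supported below age 65.
* Covariates are limited to age, age², sex and CI; no interactions, so
  sex-by-age crossings of transition rates cannot be represented.
* The two estimator biases above mean fitted kernels are systematically
  attenuated/death-inflated relative to a generating world; projections
  inherit this through the rate tables.
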