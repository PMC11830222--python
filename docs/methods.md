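# Methods

## The problem

Australia's National Disability Insurance Scheme (NDIS) funds individual
support budgets. Whether the scheme operates equitably can be asked at
three stages: who is deemed **eligible** when they apply; how large a
**plan** (personal budget) eligible participants are allocated; and how
much of the budget is actually **spent** on services. `ndisparity`
implements a causal pipeline for quantifying social inequalities at each
stage, between an exposure group and its comparator:

* women and girls vs other applicants (self-reported gender);
* residents of the three lowest deciles of the Index of Relative
  Socio-economic Disadvantage (IRSD) vs other areas;
* people aged 55 or older at the eligibility decision vs younger
  applicants — eligibility analysis only, because support needs genuinely
  rise with age, so an age contrast on plan size or spending would not be
  a pure inequality.

Estimates are stratified by seven broad disability groups (sensory,
autism, intellectual-other, physical, psychosocial, brain injury/stroke,
other), to which each primary disability code maps deterministically.

The real unit records are confidential, so the package ships a
synthetic-data generator with a fully known causal structure; every
estimator is validated against that known truth and against exact
published marginal counts.

## Cohorts

**Eligibility cohort.** One row per access request. Filters, in order:
age ≥ 7 at the decision date (younger children face different criteria);
the most recent access request per applicant (latest decision date, ties
broken by record order — the tie-break is a package choice); decided
requests only (access met / access not met; cancelled, withdrawn,
in-progress and revoked/ceased requests are dropped in three logged
steps); complete socio-demographic information. Every filter writes one
line of an `ExclusionLog` whose conservation (input = final + removed) is
asserted, and filtering is idempotent. On the calibrated synthetic table
the flow reproduces the published counts exactly: 705 594 applications →
485 676 included (393 152 eligible, 92 524 ineligible).

**Plan/spending cohort.** One row per active participant's most recent
completed plan providing strictly more than 180 days' support, age ≥ 7 at
plan start. Dollar amounts are annualised as `amount × 365.25 /
plan_days`; the year length is a package convention.

## Estimands and estimators

### Total causal effect (TCE) by g-computation

For outcome $Y$, binary exposure $A$ and confounders $C$, the TCE is

$$\Delta = E\,[\,Y(a{=}1)\,] - E\,[\,Y(a{=}0)\,],$$

standardized over the stratum's **full empirical confounder
distribution** (both exposure groups combined). The choice of standard
population is a design decision: it makes the estimate a population-level
inequality, matching the "per 1000 access requests" framing; the
comparator group's crude and standardized rates are both reported.

The estimator fits a parametric outcome model (main-effects logistic for
eligibility, adjusted for prior source of disability support; Gaussian on
annualised dollars for plan size and spending, adjusted for age band,
remoteness, severity band, years in scheme, four accommodation-program
flags and prior support), then replicates the stratum rows with $A$ set
to each level and averages `n_mc` simulated outcomes per row. Binary
draws use a shared uniform grid and Gaussian draws a shared normal grid
across the two arms: the coupling is exchangeable, cancels simulation
noise from the contrast, and makes swapping exposure and comparator negate
the estimate exactly. A deterministic plug-in (`standardize_analytic`)
replaces draws by predicted means and is the estimator's `n_mc → ∞`
limit; on a saturated model over discrete data it reproduces cell-frequency
standardization exactly, which is the brute-force oracle used in testing.

Eligibility effects are reported per 1000 access requests (probability
difference × 1000); plan and spending effects in dollars per year.

### Interventional mediation (IDE/IIE)

Spending differences may flow through plan allocation. With plan size $M$
as a continuous mediator, the package estimates the interventional
decomposition via a three-arm simulated trial on the standard population:

1. comparator arm: $A=0$, $M$ drawn from the fitted mediator model at
   $A=0$ given $C$;
2. exposure arm: $A=1$, $M$ drawn at $A=1$;
3. exposure arm with intervention: $A=1$, but $M$ drawn from the
   **comparator-level conditional distribution given $C$** (a random
   interventional analogue of shifting the plan-size distribution, not a
   rank-preserving shift).

Then TCE = mean(2) − mean(1), IIE = mean(2) − mean(3), and the direct
effect is defined as the remainder, IDE = TCE − IIE. All arms share the
mediator's and outcome's noise draws, so TCE = IDE + IIE holds to machine
precision by construction (and equals mean(3) − mean(1) up to float
rounding). Conditioning the arm-3 mediator draw on $C$ rather than using
the marginal comparator distribution was a genuinely open choice; the
conditional version was adopted because it keeps confounder-driven plan
variation intact and only removes the exposure's influence on allocation.

The mediator model is Gaussian on log plan dollars (plans are positive
and right-skewed), so simulated plans are log-normal; an identity-scale
Gaussian mediator family is available and is used for the closed-form
checks below. The spending model includes an exposure-by-mediator
interaction by default (switchable); counterfactual spending is **not**
truncated at plan size during simulation — the fitted model owns that
relationship — though a post-hoc clamp exists behind a flag (default off,
recorded in the output).

Only the two-way decomposition is produced; natural direct/indirect
effects need cross-world assumptions the interventional framing avoids.

### Confidence intervals

All intervals are 95% nonparametric percentile bootstraps: records are
resampled with replacement (within stratum), and the **entire**
fit-and-simulate estimator is re-run per replicate, so nuisance-model
estimation uncertainty is inside the interval. Defaults: 200 replicates
(desk scale; raise to 1000 for production via `BootstrapConfig`).
Replicate seeds derive from the root seed through
`numpy.random.SeedSequence`; failed replicates are dropped and counted,
and more than 10% failures aborts with a tally. BCa, bootstrap-t and
delta-method intervals are out of scope.

## The synthetic data-generating process

The generator defines the study conditions; its defaults are fixed once:

* exposure prevalence 0.433 (the published share of women and girls among
  applicants); demographic and disability-code distributions follow the
  published applicant composition; decision-type mix follows the published
  flow shares, with the access-met/not-met split produced by the
  eligibility DGP itself;
* eligibility: logit $= 1.0 - 0.35A + $ prior-support and
  disability-group terms chosen so marginal eligibility is ≈0.8 with
  group rates spanning ≈0.65–0.93, the published pattern's shape;
* plan size: log-normal, $\log M = 10.7 - 0.06A + C\gamma + 0.85\,z$ —
  mean plans on the order of \$100k, rising with severity and
  accommodation-program participation;
* spending: $Y = M \times U$ with $U \sim \text{Beta}$ with mean
  $\text{logit}^{-1}(0.6 + 0.12A)$ and precision 15 — utilisation ≈0.65,
  slightly higher for the exposure group (a positive direct effect), and
  `spend ≤ plan` row-wise by construction;
* unmeasured confounding is **off** by default (the latent factor in the
  causal diagram influences nothing); `unmeasured_strength > 0` adds a
  shared latent term to exposure assignment and spending for sensitivity
  experiments.

Confounders are drawn independently (no correlation table is published;
one can be supplied). A deterministic calibration mode allocates exact
integer cell counts by largest remainder — calibration is exact by
construction, never multinomial.

`true_effects` evaluates the DGP's own TCE/IDE/IIE by direct large-sample
simulation (default 200 000 rows): mediator draws come straight from the
generating equations with noise shared across arms, and the outcome's
conditional mean given $(A, C, M)$ is inserted analytically — an exact
variance reduction, not a model fit. `implied_eligibility_rate`
integrates the logistic DGP exactly over the finite confounder support.
An identity-link Gaussian configuration (`experiments.linear_gaussian_config`)
makes the decomposition available in closed form (IDE = direct
coefficient, IIE = mediator-effect × exposure-to-mediator coefficient),
serving as an independent oracle.

**What the generator does not emulate:** dependence among confounders,
within-applicant correlation over repeated requests, calendar trends,
heavy-tailed spending beyond the log-normal/Beta structure, and any
re-identification-realistic microdata. Passing tests therefore
demonstrate estimator correctness under the assumed parametric structure,
not robustness to real-data misspecification.

## Numerical choices and edge cases

* Monte Carlo default `n_mc = 200` draws per row; stratum seeds derive
  from the root seed and the stratum's sorted index, so strata are
  independent and reproducible.
* Minimum stratum size 50 (configurable); smaller strata, strata with a
  single observed exposure level, and non-converging fits are reported as
  not estimable rather than extrapolated. Apparent separation (diverging
  logistic coefficients or non-finite standard errors) is an error naming
  the stratum; a constant outcome or zero-variance mediator likewise.
* Categorical covariates enter as full dummy sets with configurable
  reference levels; models are deterministic given data.
* Output cells from strata with fewer than 15 records are suppressed
  after estimation (the scheme's own disclosure rule), never before.
* All dollar results are on the annualised scale; per-1000 results are
  clipped only by validation (they must lie in [−1000, 1000]).

## Validation problem sizes

Chosen once as the package's own desk-scale conditions: coefficient
recovery at n = 50 000 (within 3 SEs of truth for every family);
parameter recovery of TCE/IDE/IIE over 200 replicates at n = 20 000 with
bias below 5% of truth; bootstrap coverage over 200 simulated datasets at
n = 1 200 with 100 replicates per interval, assessed against the exact
central 99% band of Binomial(200, 0.95); oracle-equivalence on a four-cell
discrete toy at `n_mc = 10 000`. The acceptance script
(`scripts/acceptance.py`) recomputes all of these from scratch.

## Known limitations

Parametric nuisance models only (no machine-learning or doubly-robust
estimators, no IPW/TMLE); binary exposures only; single mediator; the
exact functional forms of the original analyses are not public, so the
defaults here (main-effects logistic; log-scale mediator; dollar-scale
spending with exposure-mediator interaction) are declared package
conventions; no imputation of missing demographics; Indigenous and CALD
status are carried through as flags but not analysed.
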