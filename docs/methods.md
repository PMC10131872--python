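# Methods

## Model and assumptions

The package estimates regional differences in monthly medical costs
around an incident CKD diagnosis from a long-format claims panel.  Costs
are semicontinuous, so the model has two parts sharing one design:

* **Usage part** — `P(Y_ij > 0 | a_i) = logit⁻¹(x₁'α + a_i)`.  The
  binary part models the probability of *any* expenditure in the month
  (usage orientation; a sign flip converts to the zero-probability
  orientation).
* **Overall-mean part** — `E(Y_ij | a_i, d_i) = exp(x₂'β + d_i)`.  The
  marginalized parameterization: `β` acts on the mean over users and
  non-users combined, so `exp(β_k)` is a population-level cost ratio.
  The positive-part mean is recovered as `μ = ν/π` and the positive
  costs follow a gamma distribution with shape `κ` and mean `μ`.
* **Random effects** — correlated intercepts `(a_i, d_i) ~ N₂(0, Σ)`
  with `Σ` parameterized by `(σ_a, σ_d, ρ)`.  Intercepts only: random
  slopes are out of scope (the original analysis reports it could not
  fit them either).

The design is a segmented interrupted time series on the month index
`t = 0..48` with diagnosis at `t = 24` (the diagnosis month counts as
post-diagnosis; `after_time = max(0, t − 24)`).  Structural columns:
intercept, diagnosis (level shift), region (1 = vulnerable, PARC
< −0.33), time, diagnosis×region, diagnosis×after_time, region×time,
region×after_time, followed by adjustment covariates (age in years, sex
with female = 1, Charlson category entered as its 0/1/2 score — the
published table shows a single coefficient per covariate, implying a
score, not dummies).  Income tertile and coverage type are available
through `covariate_spec` but excluded from the default model, matching
the published coefficient table.

### Identifiability of the region-by-trend terms

A design carrying both `region × after_time` and
`diagnosis × region × after_time` — the literal reading of the published
parameter labels — is rank-deficient, because `after_time > 0` already
implies the diagnosis indicator is 1: the two columns are elementwise
identical.  The published account of the 8th coefficient as "the
difference in difference in pre- and post-diagnosis costs between
regions" pins down the identifiable reading used here: the 7th term is
`region × time` (a differential secular trend for vulnerable regions)
and the 8th is `region × after_time`.  Under this layout the pre/post
difference-in-differences between regions is `β₈` (−0.0152) and the
post-diagnosis region slope gap is `β₇ + β₈` (0.0026/month), which
reproduces the published year-by-year projection exactly.

### The year-projection unit caveat

The published region-difference-by-year row (0.26, 0.52, 0.78, … %) is
reproduced by `100 × (β₇ + β₈) × years` although the slope coefficients
are per *month*; multiplying by elapsed months would give 3.12% at one
year.  The package implements the published convention (and documents it
prominently) plus an exact-ratio variant `100 × (exp((β₇+β₈)·years) − 1)`.
At years 4 and 5 the published values (1.05, 1.31) differ in the last
digit from the rounded recomputation (1.04, 1.30), consistent with the
source rounding from unprinted precision; only years 1–3 are treated as
exactly reproducible.

## Likelihood and numerics

The subject log-likelihood integrates the two-part density over
`(a_i, d_i)` with Gauss–Hermite product quadrature (default 9 nodes per
dimension).  The adaptive scheme centers nodes at the per-subject
Laplace mode with the local curvature as scale, written in importance
form: node positions and weights are frozen constants and the bivariate
normal prior is an explicit analytic factor, so the frozen-node objective
has exact gradients in *all* parameters, including `(σ_a, σ_d, ρ)`.
Fitting alternates L-BFGS-B maximization of the frozen-node objective
(unconstrained scale: `log κ`, `log σ`, `atanh ρ`; design columns scaled
to unit maximum for conditioning) with node re-adaptation, preceded by a
cheap 1-node (Laplace) warm-up round; two to four outer rounds suffice.
Starting values come from a logistic GLM of the usage indicator and a
log-link Poisson quasi-likelihood fit of the zero-inclusive cost — the
latter because the marginal mean is exactly what `β` parameterizes; a
positives-only gamma fit would target the conditional mean instead.

Numerical safeguards: `π` is clipped below at 10⁻⁶ when forming
`μ = ν/π` (clip events are counted and surfaced in fit diagnostics);
with `σ_a = σ_d = 0` the likelihood short-circuits to the closed-form
independent two-part sum; non-finite integrands raise an error naming
the offending subject.  The observed information is computed by central
differences of the analytic gradient with per-parameter adaptive steps
and inverted for the covariance (delta-method transform back to the
natural scale); if it is not positive definite an
outer-product-of-gradients covariance is substituted with a warning.
Convergence is declared when the relative gradient
`max_k |g_k·max(|θ_k|,1)| / |ℓ|` falls below 10⁻⁵ *and* the
log-likelihood changes by less than 10⁻⁴ (relative) across the final
node re-adaptation; an absolute gradient-norm criterion is not used
because it is not attainable at panel log-likelihood magnitudes (~10⁵)
with unscaled covariate columns.  Intervals are Wald (not profile),
matching the symmetric published limits.

Note that with `ρ = 0` the two-dimensional integral still does not
factorize in general: the marginalized gamma mean `μ = ν/π` couples the
two random effects whenever a month has positive cost.  It factorizes
only for subjects whose window is all-zero (tested as such).

## Synthetic cohort generator

`default_params()` encodes the study conditions: 7,966 subjects, 12.2%
vulnerable, 49 monthly records each, covariates drawn from the published
frequency tables (seven age bands sampled uniformly within band, 40.1%
female, income tertiles 13.7/44.4/41.9%, 52.3% medical aid, Charlson
categories 20.7/28.9/50.5%), and structural `α`/`β` equal to the
published estimates.  Costs are drawn exactly per the model: Bernoulli
usage, then a gamma draw with mean `ν/π`.

Calibrated quantities (the study does not report them):

| parameter | default | rationale |
|---|---|---|
| `σ_a` | 0.3 | smallest non-degenerate value placing the zero-cost share at ≈29.4% analytically (the mixture average of `1−π` rises with `σ_a`) |
| `σ_d` | 0.7 | overdispersion of positive costs; keeps monthly USD means in the published $200–420 range via the log-normal mixing factor `exp(σ_d²/2)` |
| `ρ` | 0.5 | positive usage–cost dependence, plausible for claims data |
| `κ` | 0.8 | right-skewed positive costs (CV > 1), typical of monthly claims |

Two further calibration choices are deliberate deviations from printed
values, both forced by internal inconsistencies of the source tables:
the binary-part age coefficient uses 0.0166, the midpoint of its printed
interval (0.0161, 0.0171), because the printed point estimate 0.0116
lies outside that interval and makes the stated 29% zero share
unreachable for any `σ_a`; and drawn costs are converted from the
log-KRW scale of the published mean-part intercept (exp(11.19) ≈ 72,400)
to USD using the source's own implicit rate, 8,361,000 KRW / $6,367.04 =
1,313.17 KRW/USD, which lands the simulated means on the published USD
scale.  The reference-estimates table shipped in
`mtpcost.reference` keeps every printed value verbatim.

What the generator does **not** emulate: calendar-time claim streams
(panels are emitted already aligned to diagnosis), death (a geometric
death process exists but is off by default — the source reports no
rates), serial correlation of costs within subject beyond the shared
random intercepts, and the observed near-zero pre-diagnosis region gap
(the printed `β₇ = 0.0178` on `region × time` makes simulated
vulnerable-region costs diverge over the whole window, running the
vulnerable subgroup mean to ≈$550).  Passing tests therefore show that
the estimator recovers the generative truth under the model's own
assumptions, not that the model is correctly specified for real claims.

## Problem sizes used in the checks

The recovery study fits 200 cohorts of 500 subjects (24,500 subject-months
each) with 3-node-per-dimension adaptive quadrature and two full outer
rounds — settings at which the quadrature error in the interaction
coefficient is far below its sampling error.  The marginalization check
pools 40,000 subjects for the empirical region ratio (≥20,000
subject-months per region cell at the probed month) and fits a separate
1,200-subject cohort for the model contrast.  The generator calibration
check runs at the full study size.  Oracle comparisons use 10⁵-draw
Monte-Carlo integration per subject.

## Known limitations

* The displayed model equations of the source are lost to figure
  placeholders; the likelihood is the standard MTP formulation
  specialized to the published parameter list, and the identifiable
  region-by-trend layout described above is a reconstruction — a
  different lost layout cannot be ruled out, but no identifiable
  alternative reproduces both the published DID description and the
  year projection.
* Printed-coefficient results (slope grid, projections, trajectories)
  carry no covariance, so derived intervals are omitted there.
* The OPG covariance fallback is a weaker estimator than the observed
  information; its use is always logged.
* Abstract-level cohort counts in the source (5,903 included patients;
  3,191 women) conflict with its own cohort table (7,966 = 971 + 6,995;
  2,790 women); the package follows the cohort table throughout.
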