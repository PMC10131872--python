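# mtpcost

Marginalized two-part (MTP) longitudinal modelling of semicontinuous
medical-cost panels, built around the question of whether patients with
chronic kidney disease (CKD) in medically vulnerable regions of South
Korea accrue higher costs after diagnosis than patients elsewhere.  It is
aimed at health-services researchers working with monthly claims panels
in which many subject-months have zero expenditure and the positive costs
are heavily skewed.

The cohort the package is designed around (South Korea's NHIS-NSC claims
sample) is access-restricted, so the package ships a synthetic cohort
generator that emulates its structure — 7,966 incident CKD cases, 12.2%
in vulnerable regions (PARC index < −0.33), 49 monthly cost records
centered on the diagnosis month, ≈29% zero-cost subject-months — with
known ground truth, making every stage of the pipeline testable end to
end.

## The model

Monthly cost `Y_ij` for subject `i` at month `j` is semicontinuous: a
point mass at zero plus skewed positive values.  With correlated random
intercepts `(a_i, d_i) ~ N₂(0, Σ)`:

```
P(Y_ij > 0 | a_i)        = π_ij = logit⁻¹(x₁ᵢⱼ'α + a_i)       (usage part)
E(Y_ij  | a_i, d_i)      = ν_ij = exp(x₂ᵢⱼ'β + d_i)           (overall mean)
Y_ij | Y_ij > 0, a, d    ~ Gamma(shape κ, mean μ_ij = ν_ij/π_ij)
```

Unlike a conventional two-part model, the MTP parameterization puts `β`
on the log of the **overall** mean (zeros included), so `exp(β_k)` is a
population-level cost ratio per unit of covariate `k`; the conditional
positive mean `μ = ν/π` is derived, not modelled.  Both parts share a
segmented interrupted-time-series design centered on the diagnosis month
(index 24 of 0..48): intercept, post-diagnosis level shift, region,
monthly trend, their interactions with the post-diagnosis clock
`after_time = max(0, t − 24)`, and adjustment covariates (age, sex,
Charlson category).  The coefficient on `region:after_time` is the
difference-in-differences of pre/post cost slopes between vulnerable and
nonvulnerable regions — the study's headline quantity — and the sum of
the two region-by-trend coefficients is the monthly rate at which the
regional cost gap accrues after diagnosis.

The subject likelihood integrates the two-part density over `(a_i, d_i)`
by adaptive Gauss–Hermite quadrature; fitting maximizes it with exact
analytic gradients and reports Wald intervals from the observed
information.

## Worked example

```python
import mtpcost as m

fit = m.reference_fit()                # published coefficient table
print(m.predict_region_difference(fit, 1))   # 0.26
print(m.predict_region_difference(fit, 3))   # 0.78

grid = m.named_slope_contrasts(fit)
# (difference, after-before) -> -0.0152   pre/post DID between regions
# (difference, after)        ->  0.0026   monthly post-diagnosis gap accrual
```

`0.26 / 0.52 / 0.78` are the percent differences in overall mean
expenditure between vulnerable and nonvulnerable regions at 1/2/3 years
after diagnosis (the reported convention multiplies the monthly gap
coefficient by elapsed years; see `docs/methods.md` for the unit caveat).
The negative DID (−0.0152) says the vulnerable-region cost slope falls
less after diagnosis than the nonvulnerable slope — vulnerable-region
costs pull ahead.

Simulation and fitting:

```python
cfg = m.default_params()          # ground truth calibrated to the cohort
cfg.n_subjects = 300; cfg.seed = 7
panel = m.generate_cohort(cfg)
res = m.fit(m.build_design(panel), quad=m.QuadratureSpec(3))
print(res.summary())              # coefficient table with Wald CIs
```

The `examples/` directory holds one narrative script per capability
(simulation, fitting, published contrasts, trajectories, claims-to-panel
cohort building); each prints the numbers it computes with a line on what
they mean.  A thin CLI mirrors the pipeline:

```
mtpcost simulate --n-subjects 500 --seed 1 --out out/panel
mtpcost fit --panel out/panel.csv --out out/model
mtpcost report --fit out/model.fit.json --out out/report
```

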