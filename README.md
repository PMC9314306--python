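# promirt

Item-based pharmacometric analysis of composite patient-reported outcomes:
a graded response model for daily symptom-diary items, a nonlinear
mixed-effects latent trajectory, and clinical-trial simulation with
parameter uncertainty — built around the 11-item E-RS:COPD respiratory
diary (RS-Total score, range 0–40) as analyzed in a 24-week two-arm COPD
trial.

## Who this is for

Pharmacometricians and trial statisticians who want to analyze ordinal
item-level diary data instead of daily total scores. Modeling the items
directly uses all the information the instrument collects, which narrows
the confidence interval of the change-from-baseline (CFB) endpoint
relative to a mixed-model-repeated-measures (MMRM) analysis of the total
score — equivalently, the MMRM design would need several-fold more
patients for the same precision.

## The model

**Item layer (graded response model).** A latent disease state θ drives
every item *j* through cumulative logistic curves

    P(y_ij ≥ k) = expit( a_j (θ_i − b_jk) ),    P(y_ij = k) = P(y ≥ k) − P(y ≥ k+1),

with discrimination `a_j > 0` and ordered difficulties `b_j1 < … < b_jK`.
Item parameters are estimated by marginal maximum likelihood under an
independent-occasion design: each complete subject-day is one
pseudo-subject, run-in days anchored at θ ~ N(0, 1) and post-baseline
days at an estimated N(μ, ω²).

**Longitudinal layer (Weibull + offset).** Per-occasion empirical-Bayes
estimates of θ (diffuse prior, curvature SEs) become the dependent
variable of an arm-specific latent trajectory

    θ(t) = θ₀                                                       t = 0
    θ(t) = θ₀ + R_max (1 − exp(−((ln2 / T_prog) · t)^γ)) + offset    t > 0

with t in years: `R_max` the gradual maximum response, `offset` the
rapid-onset drug effect, `T_prog` the time to half the Weibull response
and γ its steepness. θ₀, T_prog (log-normal), R_max and offset carry
inter-individual variability with an arm-specific sparse correlation
structure; smoking and region shift θ₀; the residual variance is shared
and can absorb each θ estimate's known measurement SE.

**Endpoint layer.** Replicated virtual trials drawn with parameter
uncertainty (normal fixed effects, inverse-Wishart random-effect blocks)
give the distribution of arm-level mean CFB per 4-week interval; its
median and 2.5/97.5 percentiles are the reported mean (95% CI). Two
analyses of the same endpoint are compared through the relative sample
size `N = (CI_MMRM / CI_IRT)²`.

## Worked example

```python
import promirt

rel = promirt.reference_relative_n()           # packaged published table
s = rel.summary()
print(s["cells"][("FF/UMEC/VI", "21-24")])     # 4.0
print(s["cells"][("BUD/FOR", "21-24")])        # 4.72
print(s["minimum"], s["min_cell"])             # 3.64 ('FF/UMEC/VI', '1-4')
print(s["median_by_arm"])                      # {'BUD/FOR': 4.9, 'FF/UMEC/VI': 4.0}

# two-step pipeline on a synthetic diary trial
design = promirt.TrialDesign(n_per_arm=(150, 150), schedule="weekly")
trial = promirt.generate_trial(design, seed=1)
irt = promirt.GradedResponseIRT(compute_se=False).fit(trial)
theta = irt.transform(trial)                   # per-day latent estimates
nlme = promirt.LatentTrajectoryNLME(compute_se=False).fit(theta)
for arm, fx in sorted(nlme.fixed_effects_.items()):
    print(f"{arm}: R_max={fx.r_max:.2f}, offset={fx.offset:.2f}, "
          f"T_prog={fx.t_prog * 365.25:.0f} days")
# BUD/FOR: R_max=-0.09, offset=-0.01, T_prog=29 days
# FF/UMEC/VI: R_max=-0.17, offset=-0.14, T_prog=26 days
```

The first block reproduces the published precision comparison: at the end
of treatment the total-score MMRM analysis would need a 4.0-fold
(triple-therapy arm) or 4.72-fold (dual-therapy arm) larger study to
match the item-based model's CI, and at least 3.64-fold at any interval.
The second block fits both stages to a simulated 150-per-arm trial; the
fitted `R_max`/`offset` are on the model's anchored latent scale (more
negative = larger symptom improvement) and the triple-therapy arm shows
the larger drug effect, as in the generating parameters.

A `promirt` command-line interface wraps each stage
(`simulate-data`, `fit-icf`, `estimate-theta`, `fit-longitudinal`,
`endpoints`, `run-all`); `promirt run-all --outdir out/` runs the whole
pipeline on synthetic data and writes a hash manifest.

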