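# Methods

## Scope and data model

The package analyzes long-format ordinal diary data: one record per
subject × study day × item, for an instrument of 11 items (seven with
five ordered categories 0–4, four with four categories 0–3; total score
0–40). Days −14…−1 are the run-in, treatment runs day 1–168, and the
change-from-baseline (CFB) endpoint compares each subject's 4-week
interval mean of the total score (consecutive 28-day blocks starting at
day 1) against the mean over the run-in window. Diary completion is
all-or-nothing within a day; days with a partial item set are rejected at
validation. Subjects with no complete run-in day cannot contribute a CFB
and are excluded with a log message.

## Stage 1: item characteristic functions

Items follow the graded response model. Estimation treats every complete
subject-day as an independent pseudo-subject; the latent variable is
N(0, 1) for run-in occasions — the identifiability anchor; no further
constraints are placed on `a`, `b` — and N(μ, ω²) for post-baseline
occasions (pooled by default; one distribution per 4-week interval is
available via `post_grouping="interval"`).

The one-dimensional latent integral per occasion uses Gauss–Hermite
quadrature, by default adaptively centred on each occasion's posterior
mode with the Laplace scale (`scheme="agh"`, 15 nodes; one node is a
Laplace approximation; `scheme="gh"` centres on the class prior).
Gradients are analytic given the node positions; freezing the adaptive
nodes within an evaluation perturbs the gradient only at quadrature-error
level. Monotone difficulties are enforced by parameterizing the first
threshold freely and the increments on the log scale. Start values are
unit discriminations with difficulties at empirical logit quantiles of
each item's cumulative score frequencies. Convergence follows L-BFGS-B
(`ftol` 1e-9, `gtol` 1e-5 by default); standard errors come from a
central-difference Hessian of the analytic gradient, delta-method-mapped
to the natural scale. Items with unobserved categories are flagged as
degenerate before fitting (their parameters drift to a boundary), and
fitted discriminations outside (0.05, 30) raise a boundary warning.

Node-count sensitivity: between 15 and 31 adaptive nodes the fitted
log-likelihood moves by well under 1e-4 on the desk-scale sets used in
the tests; 7 nodes is visibly coarser (~1e-2).

## Intermediate stage: per-occasion latent estimates

With item parameters fixed, each diary day's latent state is the mode of
the log posterior under a deliberately diffuse N(0, 100) prior — large
enough that the estimate is effectively the conditional ML value and the
translated total score tracks the raw data (correlation > 0.95 on
synthetic data) — with a curvature (Laplace) standard error. The mode is
found by a damped Newton iteration, which converges globally because the
graded-response category log-likelihood is strictly concave in θ.
Estimates with |θ̂| > 6 are flagged as extreme response patterns (floor
or ceiling days carry very little information and large SEs). The
per-occasion SE is carried into stage 2 as a known measurement-error
variance added to the residual (`use_ebe_se=True`, the default).

## Stage 2: latent-trajectory mixed-effects model

The latent time course is a Weibull onset plus a rapid-onset additive
drug effect (both zero at baseline), time in years (`t = day/365.25`,
run-in days at t = 0), with arm-specific fixed effects and
inter-individual variability on θ₀, T_prog (exponential/log-normal),
R_max and offset; the arm-specific correlation structure defaults to the
published sparsity (R_max~offset and θ₀~offset in one arm, θ₀~offset and
R_max~θ₀ in the other). Smoking and region (region 2 reference) shift θ₀
and are shared across arms, as is the residual variance. All arms are fit
jointly in one likelihood.

**Estimation.** The model is *linear* in the θ₀, R_max and offset effects
conditional on the progression-time effect. Those three therefore
marginalize exactly by linear-mixed-model algebra (Woodbury identity on
the diagonal residual), leaving a one-dimensional integral over the
progression-time effect, evaluated on a dense trapezoid grid expressed in
units of its prior SD (±5.5 SD, 71 points by default — spectrally
accurate once the grid step is below the conditional posterior width).
This route was chosen after a single-mode Laplace/FOCE implementation
proved materially biased here: with weekly observations and steep Weibull
shapes the per-subject joint posterior is multimodal in the
progression-time effect, and the Laplace objective preferred a heavily
flattened steepness (checked against exact integration, which this scheme
matches to Monte-Carlo accuracy). The price is that the progression-time
effect must stay uncorrelated with the other effects — which the
published structure satisfies — and configurations violating that are
rejected.

Outer gradients are fully analytic. Box bounds keep the search
interpretable (γ capped at 60: beyond that the onset is a step at any
realistic sampling interval and the likelihood is flat in γ; T_prog in
[0.002, 5] years). Standard errors use a finite-difference Hessian of the
analytic gradient; parameters that finish on an active bound are
conditioned on and excluded from the SE report. RSEs for variance-like
quantities are reported on the approximate SD scale (half the
variance-scale relative SE). Start values are method-of-moments from the
latent series (baseline mean, late plateau, a 60/40 R_max/offset split of
the drop, γ = 5).

Empirical-Bayes subject effects (for diagnostics) maximize the joint
posterior by damped Gauss–Newton with multi-start over the
progression-time effect, for the same multimodality reason.

## Trial simulation with parameter uncertainty

Each replicate draws fixed effects from a multivariate normal on the
estimation scale (logs for T_prog and γ, so draws stay in the valid
domain), random-effect covariance blocks (the connected components of the
correlation graph) from inverse-Wishart distributions with degrees of
freedom matched to the variance SEs via `df = 2 (ω²/se)² + 1 + dim`
(mean-preserving scale `Ψ = Ω̂ (df − dim − 1)`; zero SE pins the block),
and the residual variance from the dim-1 case. A large virtual trial per
arm (covariates resampled at the design frequencies: 44% smokers, region
mix 21/24/21/18/6/10%) is simulated on a weekly grid with run-in days at
−14/−7/−1; latent states get the daily residual and are converted to item
responses (default) or to expected totals via the tabulated θ→total map
(`response="expected"`). The median and 2.5/97.5 percentiles (linear
interpolation) of the arm-level mean CFB across replicates are the
reported mean (95% CI). With many virtual subjects the spread is
dominated by parameter uncertainty, which is the design intent; desk
defaults are 200 replicates × 2,000 subjects/arm (the study-scale
2,000 × 15,000 is reachable by configuration).

## Endpoint comparison

Relative sample size is the squared ratio of CI widths, with widths taken
from bounds at their printed two-decimal precision and summaries rounded
at the reporting convention (cells to two decimals, per-arm medians to
one). The packaged comparator table ships with the package; one of its
24 SE entries is internally inconsistent with its own printed bounds at
round-off level, which the tests pin explicitly. The minimal clinically
important difference for the total score is 2 points; the MCID assessment
reports the earliest interval whose mean CFB reaches −2 per arm.

## Diagnostics

The visual predictive check simulates the observed design (same subjects,
covariates and diary days) at point estimates — no parameter
uncertainty, per the standard VPC definition — and compares observed
2.5/50/97.5 total-score percentiles per arm × calendar-week bin with the
95% band of each percentile across simulations. The item-characteristic
check bins occasions by latent estimate (equal counts, thin bins merged)
and compares observed threshold exceedance fractions against a
parametric-bootstrap expectation that pushes simulated data through the
same estimate-then-bin pipeline; binning on a noisy latent estimate
flattens curves at the extremes, so the analytic curve alone is reported
but not used for the deviation summary. Residual summaries provide
population residuals normalized by the linearized marginal SD and
individual residuals normalized by the residual SD; both have mean ≈ 0
and SD ≈ 1 under a correct model.

## Synthetic data generator

The generator emulates the trial's structure: two arms (907/894 subjects
by default) with the packaged published longitudinal estimates as
generating truth; 14 run-in days plus 24 treatment weeks of daily records
(a weekly schedule is available for desk-scale work); 91% completers;
missing diary days drawn per subject from a negative binomial (shape 0.8,
mean solved so the median matches 5, capped at 101) placed uniformly on
the daily calendar; dropout day for non-completers log-normal with median
84 (σ = 0.6), truncated to the treatment window.

Item parameters are synthetic (the real item estimates are not in the
public domain): discriminations spread over [0.8, 2.5] and evenly spaced
difficulties sweeping the symptomatic range, then shifted so the first
arm's expected baseline total under its generating latent distribution is
exactly 12.2. The second arm's higher baseline variance then reproduces
the published between-arm baseline pattern (≈12.9) through the curvature
of the θ→total map. The resulting baseline SD (~8) is larger than the
published 5.85 — matching both moments would require implausibly weak
discriminations — so the synthetic instrument is somewhat steeper than
the real one. Consequences: per-occasion latent estimates are relatively
informative, while diary floor effects (strong responders pushed below
the lowest difficulty) are somewhat stronger than in the real data.

**What passing tests show.** The generator matches the analysis model's
assumptions (it shares the trajectory and item machinery), so recovery
and calibration results demonstrate internal correctness of the two-step
pipeline, not robustness to real-data features it does not emulate:
within-subject day-to-day autocorrelation beyond the latent trajectory,
time-varying covariates, non-ignorable missingness, or item-level
response styles.

**Scale alignment in recovery studies.** The latent scale is identified
only up to an affine transform fixed by the run-in N(0, 1) anchor. Data
generated at the published estimates have a baseline latent SD above 1
(IIV + covariate spread + daily residual), so refitting re-anchors the
scale; recovered location/scale parameters are compared to generating
values after mapping through the affine alignment of fitted vs generating
item difficulties (`affine_scale_alignment`). A residual attenuation of
the response amplitude (~10–20% on R_max) remains even after alignment:
it traces to the instrument floor — the strongest responders' diary days
carry little information and saturated latent estimates — and is a
property of the measurement design, not of the estimator (direct fits to
latent observations recover the generating values to sampling accuracy).

## Problem sizes used in the tests

Recovery runs use 20 replicates of 300 subjects/arm with weekly diaries,
step-1 item estimation on the run-in days plus every fourth treatment
week (≈4,000 occasions; the items have ~50 parameters, so this is ample),
and latent estimation on all occasions. Uncertainty-simulation checks use
20 replicates × 4,000 virtual subjects/arm; predictive-check calibration
uses 150 subjects/arm and 300 simulations. These sizes were chosen so the
whole suite runs on a laptop-class single core while leaving each check
statistically meaningful.

## Known limitations

- The marginal likelihood is exact only given the progression-time
  quadrature grid; pathological configurations (residual variance orders
  of magnitude below the data spacing) could under-resolve the
  conditional posterior — raise `n_quad` if in doubt.
- Random-effect correlations involving the progression-time effect are
  not supported.
- The two-step procedure (items, then trajectory on plug-in latent
  estimates with Gaussian measurement error) inherits the floor/ceiling
  attenuation discussed above; a joint one-stage fit would avoid it at
  far higher cost.
- No type-I-error/multiplicity machinery, no bootstrap/resampling SEs,
  and no model-averaging across structural candidates.
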