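# Methods

## The disease model

`alstrialsim` simulates two-arm ALS trials from a shared-random-effects
joint model of functional decline and survival. Subject *i* carries
random effects **b**ᵢ = (b₀ᵢ, b₁ᵢ, b₂ᵢ) ~ MVN(0, **D**) and a latent
ALSFRS-R trajectory

  mᵢ(t) = β₀ + b₀ᵢ + (β₁·(1 − r·aᵢ) + b₁ᵢ)·t + b₂ᵢ·t²,

where aᵢ indicates treatment and r is the fractional reduction of the
fixed rate of decline (0, 0.15 or 0.30 in the scenario grid). Observed
scores add N(0, σ²) measurement noise at each visit. The hazard of death
conditions on the current latent value:

  hᵢ(t) = (ρ/λ)(t/λ)^{ρ−1} · exp(γ·aᵢ + α·mᵢ(t)).

Treatment can therefore act directly on the hazard (γ = log HR; scenario
HRs 1, 0.66, 0.5 are this *conditional* hazard ratio) or indirectly by
slowing functional loss, which feeds into survival through the
association α (log hazard ratio per ALSFRS-R point, default log 0.88).
The fixed time effect is linear; curvature enters only through the
subject-level quadratic random effect. The latent value is *not* clamped
to the instrument range [0, 48] inside the hazard (a config option turns
clamping on); at the default parameters trajectories rarely exit the
range within 18 months.

Event times are drawn by inverse-transform sampling: H(T) = −log U with
the cumulative hazard computed by Gauss–Legendre quadrature (15 nodes per
month-long panel; there is no closed form once α ≠ 0) and inverted by
vectorized bisection to 10⁻⁶ months. Subjects whose cumulative hazard at
the horizon never reaches the target are administratively censored.

## Parameter calibration

The population the generator emulates is a pooled placebo cohort of ALS
trial participants: mean baseline ALSFRS-R 38 points (SD ≈ 5), mean
decline 1.06 points/month, and placebo survival 86.5% at 12 months and
64.2% at 18 months. The variance components of the original fitted model
are not published, so the generator's defaults are calibrated stand-ins,
fixed once:

| parameter | value | source |
|---|---|---|
| β₀ | 38 points | published baseline mean |
| β₁ | −1.06 points/month | published mean decline |
| α | log 0.88 | published association (HR per point) |
| SD(b₀) | 4.6 points | baseline total SD ≈ 5 with σ = 2 |
| SD(b₁) | 0.74 points/month | calibrated to the published LME operating characteristic (below) |
| SD(b₂) | 0.02 points/month² | curvature consistent with late-stage acceleration |
| σ | 2.0 points | visit-to-visit measurement noise |
| ρ, λ | 1.353, 4.062 months | solved so placebo survival hits 86.5%/64.2% |

Two quantities are solved rather than assumed. First, the Weibull
baseline (ρ, λ) is found by 2-D root-finding on (log ρ, log λ) so that
the Monte-Carlo marginal placebo survival E_b[exp(−H(t))] (common random
numbers, 2×10⁵ draws) matches both survival targets within ±0.005;
`calibrate_weibull` re-runs this procedure for any parameter set. The
calibrated shape exceeds 1 — death rates accelerate over follow-up, so a
constant (exponential) rate would be wrong.

Second, the random-slope SD is the one variance component that the
published operating characteristics pin down sharply: the empirical power
of the linear-mixed-model analysis at a 15% slope reduction (150 per arm,
18 months) is a direct measurement of the treatment–slope standard error,
hence of the between-patient slope variance. SD(b₁) = 0.74 reproduces
that published power (0.406) at the study's design point; smaller values
(e.g. 0.35, which would be suggested by naive baseline-progression-rate
summaries) give LME power near 0.9 and visibly too-weak attenuation of
conditional hazard effects in every survival-side analysis. This
calibration uses only the one LME cell; the Cox, CAFS, composite and
joint-model operating characteristics are *not* calibration targets —
wherever they land is an emergent prediction of the model.

## Trial assembly

Visits follow the nominal monthly grid 0, 1, …, H (H = 12 or 18) with
independent N(0, 0.16²) jitter on every non-baseline visit; jittered
times below zero are redrawn, not truncated, so the marginal jitter SD is
preserved. About 10% of subjects are lost to follow-up at a
Uniform(0, H) time drawn independently of their outcome (non-informative
dropout). Follow-up is min(death, dropout, H); death truncates the
ALSFRS-R series — visits after the event are removed, never imputed,
which is exactly the informative-missingness structure the analysis
strategies must confront. Datasets round-trip losslessly through two CSV
files (`*_longitudinal.csv`: subject_id, arm, time_months, alsfrs_r;
`*_survival.csv`: subject_id, arm, time_months, status) with a
provenance comment header.

## Estimation engines

**LME.** The longitudinal analysis model has fixed intercept and time
(plus treatment×time when testing; no arm main effect, by randomization)
and random intercept, slope and quadratic time. Fitting maximizes the
profiled ML deviance over the relative Cholesky factor of **D** (lme4's
parametrization) with analytic gradients; all per-subject algebra reduces
to batched 3×3 operations, so one fit takes ~0.1 s. ML (never REML) keeps
likelihood-ratio tests across fixed-effect specifications valid. A
near-singular covariance triggers a diagonal refit with a warning flag.
Inference on the interaction is a two-sided Wald z test — at 300 subjects
the large-sample regime, so no small-sample degree-of-freedom correction
is applied. statsmodels' MixedLM serves as an independent cross-check in
the test suite, not as the engine (it is ~20× slower per fit, which the
Monte-Carlo loops cannot afford).

**Cox.** lifelines' partial-likelihood fit with Efron tie handling;
two-sided Wald test of the treatment log-HR. Zero-event datasets raise.

**Joint model.** The analysis joint model mirrors the generator: LME
submodel plus Weibull proportional-hazards submodel linked by the
current-value association. The survival scale is reparametrized as
κ = −ρ·log λ, which makes κ, α and the trajectory level nearly linearly
coupled in the log hazard and conditions the optimization well. The
marginal likelihood integrates the three random effects by
pseudo-adaptive Gauss–Hermite quadrature: nodes are recentered per
subject on the empirical-Bayes posterior of the preliminary LME fit
(5 nodes/dimension by default; the maximized log-likelihood moves by
< 0.1 going to 9). The within-subject survival integral uses a 12-node
Gauss–Legendre rule on [0, Tᵢ] (doubling the nodes changes nothing at
reported precision). Gradients are fully analytic; optimization is
L-BFGS-B started from staged fits (LME for the trajectory block, an
events/person-time survival pre-fit for ρ, κ, α, γ). Standard errors come
from a central-difference Hessian of the analytic gradient. A Weibull
rather than semiparametric baseline is used deliberately: it is
correctly specified with respect to the generator and keeps the 2-df
omnibus LRT well defined.

## The six strategies

All decisions are two-sided at α = 0.05.

1. **cox** — treatment log-HR Wald test (survival only).
2. **lme** — treatment×time Wald test (function only).
3. **cox_lme_omnibus** — Hommel step-up combination of the two p-values
   (for two hypotheses identical to Hochberg: reject iff max p ≤ α or
   min p ≤ α/2).
4. **composite** — Cox on time to death or first *observed* 6-point drop
   from baseline, dated at the visit where first seen (no interpolation,
   as in trial practice).
5. **cafs** — joint-rank test: every ordered pair is compared on survival
   first (+1 to the subject who demonstrably outlives the other's death;
   0 when indeterminate), then on change-from-baseline ALSFRS-R at the
   latest scheduled visit index available to both; subject totals are
   compared between arms by a rank-sum test with normal approximation and
   tie correction (a label-permutation test is available as an option).
   The pairwise matrix is antisymmetric by construction.
6. **jm_omnibus** — 2-df LRT between the joint model without any
   treatment term and the one with both treatment×time and the direct
   hazard effect, fitted on shared quadrature; the larger model's warm
   start embeds the null optimum, which guarantees the nested ordering.
   The fit also reports the individual trajectory-adjusted effects (β, γ)
   — the interpretability advantage over rank-based composites.

Non-convergent fits count as non-rejections in the power engine
(conservative for type-I error) and are tallied; a scenario with > 2%
non-convergence carries a warning in the report.

## Power engine and sample size

`run_scenario` replicates trials with per-replicate seeds spawned from a
master seed (any single replicate is reproducible in isolation), analyzes
every requested strategy on the *same* dataset (paired comparison), and
reports rejection proportions with binomial MC standard errors. Empirical
power translates to the sample size achieving a target power via

  N = n_total · [(z_{1−α/2} + z_target) / (z_{1−α/2} + Φ⁻¹(power))]²,

rounded up to the next whole patient.

## Monte-Carlo scale

The reference study used 10,000 replicates per scenario. The default here
is 1,000 (MC SE ≤ 0.016), the package's chosen desk-scale compromise; the
test suite uses 500–1,000 replicates for the closed-form strategies and
~120 for joint-model scenario runs (each replicate fits two joint
likelihoods), with tolerance bands widened to the corresponding binomial
MC error. All reported checks state the replicate count they used.

## What the generator does and does not emulate

It reproduces: trajectory-dependent mortality (patients with low or
fast-falling scores die sooner), death-truncated longitudinal series,
noisy monthly visits with schedule jitter, non-informative dropout, and
the published placebo survival and decline rates. It does not emulate:
item-level ALSFRS-R structure or bounded/integer scores (observations are
continuous and unclamped), nonlinear mean decline, staggered accrual,
competing risks such as tracheostomy or NIV, or informative dropout.
Passing tests therefore demonstrate the statistical behaviour of the
analysis strategies under this idealized data-generating process, not
their performance on any real cohort.

## Known limitations

- The variance components are calibrated stand-ins; operating
  characteristics that depend on them (everything except the null row and
  the deterministic translations) inherit that uncertainty.
- The conditional-vs-marginal reading of the scenario hazard ratios
  matters: here γ is conditional on the trajectory, so the marginal
  (Cox-visible) effect is attenuated by the α-induced frailty.
- The CAFS scoring algebra follows the standard joint-rank construction;
  the original study does not print its exact tie-handling, so
  third-decimal agreement of CAFS power is not expected.
- Joint-model standard errors use a finite-difference observed
  information; near-boundary variance estimates (tiny quadratic-effect
  variance at small n) can make them unstable, which the convergence flag
  reports.
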