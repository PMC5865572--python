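# alstrialsim

Joint-model based simulation of ALS clinical trials: functional decline,
survival, and six ways of analyzing them together.

## The problem

ALS trials measure two things that a treatment may affect at once: the
ALSFRS-R functional score (0–48, declining ~1 point/month) and survival.
Analyzing either endpoint alone can falsely dismiss an effective drug —
a survival-only Cox model is blind to functional benefit, a
mixed-model slope analysis is blind to survival benefit, and the two
outcomes are entangled because patients with low or fast-falling scores
die sooner, truncating their own functional data. `alstrialsim` is a
simulation laboratory for this problem, aimed at trial statisticians: it
generates realistic two-arm trials from a shared-random-effects joint
model and measures the type-I error and empirical power of six analysis
strategies.

## The model

Subject *i* has latent trajectory and conditional hazard

    m_i(t) = β₀ + b₀ᵢ + (β₁(1 − r·aᵢ) + b₁ᵢ)t + b₂ᵢt²,   bᵢ ~ MVN(0, D)
    h_i(t) = (ρ/λ)(t/λ)^{ρ−1} exp(γ aᵢ + α m_i(t))

with treatment indicator aᵢ, slope-reduction r, direct log hazard ratio
γ, and association α (default log 0.88 per ALSFRS-R point). Defaults are
calibrated so that simulated placebo arms match a pooled ALS trial
population: baseline 38 ± 5 points, decline 1.06 points/month, survival
86.5% at 12 months and 64.2% at 18 months. See `docs/methods.md` for the
full account.

The six strategies: Cox PH (`cox`), linear mixed model (`lme`), their
Hommel-corrected combination (`cox_lme_omnibus`), Cox on time to death or
6-point loss (`composite`), the CAFS joint-rank test (`cafs`), and a 2-df
likelihood-ratio omnibus test between nested joint models (`jm_omnibus`),
fitted by pseudo-adaptive Gauss–Hermite quadrature with analytic
gradients.

## Worked example

Simulate one 150-per-arm, 18-month trial in which treatment reduces the
hazard by 34% (HR 0.66) and functional decline by 15%, then analyze it
with every strategy:

```python
import alstrialsim as ats

params = ats.default_parameters().with_scenario(hr=0.66, slope_reduction=0.15)
design = ats.TrialDesign(n_per_arm=150, max_followup=18.0, seed=7)
trial = ats.generate_trial(params, design)

for name in ats.STRATEGIES:
    res = ats.analyze_trial(trial, name)
    print(f"{name:16s} p={res.p_value:.4f} reject={res.reject}")
```

prints

```
cox              p=0.0712 reject=False
lme              p=0.0090 reject=True
cox_lme_omnibus  p=0.0180 reject=True
composite        p=0.2153 reject=False
cafs             p=0.0201 reject=True
jm_omnibus       p=0.0001 reject=True
```

This replicate (94 deaths among 300 subjects) shows the pattern the
package exists to study: the survival-only Cox test and the composite
endpoint miss a genuine combined effect, while the joint-model omnibus
detects it decisively — and unlike the rank-based CAFS it also reports
the individual adjusted effects (here γ̂ = −0.19, β̂_int = 0.21,
α̂ = −0.107). Empirical power over many replicates comes from the power
engine:

```python
res = ats.run_scenario(ats.default_parameters(), ats.Scenario(0.66, 0.15, 18.0),
                       strategies=("cox", "cafs"), n_reps=1000, master_seed=1)
res.power("cox"), res.mc_se("cox")
```

and translates to sample size via
`ats.sample_size_from_power(0.616, 300)` → `464` patients for 80% power.

A CLI wraps the same functions:

```sh
alstrialsim simulate --hr 0.66 --slope-reduction 0.15 --seed 7 --out trial
alstrialsim analyze --longitudinal trial_longitudinal.csv \
    --survival trial_survival.csv --strategy jm
alstrialsim power --grid 18mo --reps 1000 --seed 42 --out table.csv
alstrialsim calibrate --mc-n 100000 --seed 0 --out calibrated.cfg
```

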