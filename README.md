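# snowscr

Spatially explicit capture-recapture (SCR) for camera-trap **count** data,
with least-cost ("ecological") distance, AIC model averaging, and the
double-observer mark-recapture estimator for ungulate prey surveys.

The package targets the analysis workflow used to estimate density of
low-density, wide-ranging carnivores (the motivating case is snow leopards
in Trans-Himalayan multiple-use rangeland): individuals identified from
camera-trap photographs are tallied into independent encounters, an SCR
likelihood integrates their unknown activity centres over a habitat mask,
candidate covariate models are ranked by AIC, and wild-prey abundance — the
key density covariate — comes from a two-observer survey. Every input can
also be simulated, so the whole chain is testable end to end without field
data.

## The models

**Density.** Activity centres follow an inhomogeneous Poisson point
process over a discretized habitat mask with log-linear intensity

    log D(s) = θ₀ + Σ_d θ_d x_d(s)            [animals / km²]

**Detection.** Counts of individual *i* at camera *k* are Poisson with
mean `effort_k · λ₀_k · exp(−d(s,k)² / 2σ_k²)` (half-normal encounter
function), with log-linear detector-covariate models for the encounter
intercept λ₀ (e.g. one vs two cameras, topographic setting) and the range
σ. Marginalising the activity centres yields the Poisson-process
likelihood maximized by `snowscr.fit`.

**Ecological distance.** `d(s,k)` is either Euclidean or the least-cost
path through a conductance surface `c(s) = exp(α·z(s))` on a standardized
covariate (altitude), with α estimated jointly with everything else —
positive α means high ground is cheaper to traverse.

**Model selection.** Candidate models are ranked by AIC; density surfaces
(not coefficients) are model-averaged with Akaike weights.

**Prey abundance.** Two observers independently record ungulate groups.
With C groups seen by both and S₁/S₂ seen by one only, the Chapman
bias-corrected estimator `Ĝ = (n₁+1)(n₂+1)/(m+1) − 1` (n₁ = C+S₁,
n₂ = C+S₂, m = C) gives group abundance; `N̂ = Ĝ × Û` with Û the mean
group size.

## Worked example

Simulate a desk-scale study (25 camera stations, 80-day session, ~1,300
pixel mask) with study-like truth — wild-prey density slope 0.61,
two-camera encounter effect 0.56, conductance coefficient 0.36 — and fit
three candidate models:

```python
from snowscr import (ScrModelSpec, SimConfig, aic_table, derived_density,
                     fit, model_average_density, simulate_study)

cfg = SimConfig.scaled_down(seed=1)
study = simulate_study(cfg, with_double_observer=False)
hist = study.detections.history
specs = [
    ScrModelSpec(),
    ScrModelSpec(density=("WildPrey",), lambda0=("Cameras",)),
    ScrModelSpec(density=("WildPrey",), lambda0=("Cameras",), noneuc="Altitude"),
]
fits = [fit(s, hist, study.mask, study.detectors) for s in specs]
print(aic_table(fits).table.round(3).to_string(index=False))
best = min(fits, key=lambda f: f.aic)
surf = derived_density(best)
print(surf.n_hat, surf.ci)
```

Output (seed 1):

```
simulated 34 animals; detected 20 (174 encounters) at 25 camera stations
                                                model  npar   logLik     AIC   dAIC  weight
D~WildPrey; lambda0~Cameras; sigma~1; noneuc~Altitude     6 -200.234 412.469  0.000     1.0
                 D~WildPrey; lambda0~Cameras; sigma~1     5 -218.484 446.968 34.499     0.0
                              D~1; lambda0~1; sigma~1     3 -224.940 455.880 43.411     0.0
best-model N_hat = 31.8 (95% CI 20.4-49.4); true N = 34
conductance coefficient alpha = 0.53 (SE 0.10)
```

The true least-cost model wins decisively (ΔAIC ≈ 34 over its Euclidean
twin), the derived abundance `N̂ = ΣD̂(s)·a = 31.8` brackets the simulated
truth of 34, and the estimated conductance is within two standard errors of
the generating value.

For the prey survey, `snowscr.estimate(records)` returns the full
double-observer summary (C, S₁, S₂, Ĝ, Û, N̂, P₁, P₂) from a list of
`GroupRecord`s, and `block_density` the per-block densities.

A CLI mirrors the library: `snowscr simulate`, `mask`, `fit`, `aicavg`,
`dobs` and `run` (full pipeline from a config file); see `snowscr --help`.

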