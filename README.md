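# camabund

Simulation-based evaluation of hierarchical abundance estimators for
camera-trap surveys of unmarked, group-living animals.

Camera traps produce temporally replicated counts of animals that usually
cannot be identified individually. Ecologists estimate abundance from such
data with hierarchical *N-mixture* models, but these models assume things
real animals violate: individuals stay at one site (geographical closure),
are never double-counted, and are detected independently. `camabund`
quantifies what those violations cost. It simulates a population of
group-living animals moving through a gridded landscape, observes them
through camera viewsheds, fits three standard hierarchical models to the
resulting counts, and scores the estimates against the known truth.

## The simulation

A 10.8 km x 10.8 km area is divided into 144 cells of 0.9 km x 0.9 km;
cameras are placed at the centroids of 36 cells (one random cell per 2x2
block), each with a circular-sector viewshed of radius 15 m and opening
42°, facing North. `G = 40` groups of animals (sizes drawn from a pool and
summing to the population size `N`) move by a discrete-time bivariate
Ornstein–Uhlenbeck walk around home-range centres `s_g`:

    u[t+1] | u[t]  ~  Normal( s_g + ρ (u[t] − s_g),  σ² (1 − ρ²) I ),

stationary around `s_g` with per-coordinate variance σ², frozen during the
12 nightly rest hours, and refined to 10-minute resolution with a Brownian
bridge. The 99% contour of the stationary distribution defines the
home-range area (HRA): 0.65 / 2.61 / 10.38 / 41.58 km² for
σ = 150 / 300 / 600 / 1200 m. Centres are drawn from the cell centroids
(closed population) or uniformly over the area (open). A group crossing a
viewshed is counted with its full size, at most once per camera-hour;
hourly tallies are thinned by the per-camera probability
P(detected | in viewshed) — 1, or ≈ 2/3 with Matérn spatial variation —
and summed into daily counts `y_ij` (36 cameras x 25 days).

## The estimators

All three models put a Poisson state on the latent site abundance,
`N_i ~ Poisson(λ)`, and differ in the observation kernel:

| model | data | observation model |
|---|---|---|
| BernP (Royle–Nichols) | binary `w_ij` | `w_ij ~ Bernoulli(1 − (1−p)^{N_i})` |
| BP (binomial N-mixture) | counts | `y_ij ~ Binomial(N_i, p)` |
| PP (Poisson N-mixture) | counts | `y_ij ~ Poisson(N_i · μ)` |

The discrete `N_i` is marginalized over `0..K` (`K = 100` for binary data,
`max(y) + 100` for counts), giving a 2–3 parameter posterior over
`(λ, θ_det)` — or `(λ, β0, β1)` with `link(θ_det,i) = β0 + β1 x_i` when the
Matérn field value is used as a detection covariate — sampled with an
affine-invariant ensemble sampler. Fit quality is assessed with
posterior-predictive Bayesian P-values and PSIS-LOO ELPD; estimator quality
with relative bias `(θ̂−θ)/θ`, RMSE, 95% CI coverage, and the proportion of
replicates with |relative bias| ≤ 0.5, for abundance λ, site-use frequency
λ_use, and post-hoc trend ratios `λ_N / λ_{0.9N}`, `λ_N / λ_{0.8N}`.

## Worked example

```python
import numpy as np
from camabund import ModelSpec, fit_hm, loo_elpd
from camabund.pipeline import Scenario, simulate_survey

scn = Scenario(N=480, sigma=150, rho=0.7, closure="closed")
survey, truth, extra = simulate_survey(scn, replicate=0, master_seed=7)
print(f"lambda = {truth.lambda_true:.2f}, detections = {survey.counts.sum()}")

for family in ("BernP", "BP", "PP"):
    fit = fit_hm(ModelSpec(family=family, seed=1), survey)
    lam = fit.summary["lambda"]
    elpd, _, _ = loo_elpd(fit)
    print(f"{family:5s} lambda-hat {lam['mean']:5.2f} "
          f"[{lam['q2.5']:.2f}, {lam['q97.5']:.2f}]  LOO-ELPD {elpd:8.1f}")
```

prints (seed-dependent):

```
lambda = 3.33, detections = 646
BernP lambda-hat  0.32 [0.15, 0.55]  LOO-ELPD   -133.0
BP    lambda-hat  6.04 [5.12, 7.04]  LOO-ELPD  -1669.7
PP    lambda-hat  0.75 [0.48, 1.07]  LOO-ELPD  -1139.4
```

The true density is 3.33 animals per cell. The binomial model inflates it
(unmarked groups are double-counted), while the binary and Poisson models
shrink it (three quarters of the cameras never see a group, because group
centres are points and home ranges are small); the binary likelihood wins
the predictive comparison. See `docs/methods.md` for why these patterns
arise and where they differ from individual-level movement.

The same machinery is scriptable from the shell:

```bash
camabund simulate --n 480 --sigma 150 --closure closed --seed 7 --out survey.csv
camabund fit survey.csv --family PP --seed 1
camabund study --seed 0 --replicates 2 --out study_out
```

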