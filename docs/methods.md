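# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the known limitations of `camabund`.

## Movement model

Groups move by a discrete-time bivariate Ornstein–Uhlenbeck (OU) process
with hourly steps. Writing `u_t` for the group position and `s` for its
home-range centre,

    u_{t+1} | u_t ~ Normal( s + ρ (u_t − s),  σ² (1 − ρ²) I ),

which is the standard AR(1) form of the OU transition: ρ ∈ (0,1) is the
lag-1 autocorrelation of positions, σ (metres) the stationary per-coordinate
standard deviation, and the stationary law is Normal(s, σ² I) regardless of
ρ. The first position is drawn from the stationary law rather than pinned at
`s`, avoiding burn-in transients over a short 600-step survey. During rest
hours — a nocturnal schedule freezing positions whose 1-based hour index
`t+1` satisfies `(t+1) % 24 ∈ {0..5, 18..23}` — the position is copied
exactly.

The home-range area (HRA) emerges from σ as the area of the 99% contour of
the stationary Gaussian, `π · χ²₂(0.99) · σ²`: 0.65, 2.61, 10.38 and
41.58 km² at σ = 150, 300, 600, 1200 m. The 99% level is used because it
reproduces this published sequence of emergent areas to within 0.5%; a 95%
contour does not.

### Sub-hourly refinement

Hourly resolution is too coarse relative to a 15 m viewshed, so each active
transition is refined with a Brownian bridge: `B = 6` substeps (10-minute
resolution), interior point at fraction `f` having mean on the chord and
per-coordinate variance `scale² · f(1−f)`. The bridge scale defaults to
`σ√(1−ρ²)/2`, half the hourly innovation standard deviation; with these
defaults the realized per-capita daily detection probability and rate in the
closure scenario (σ=150, N=480, ρ=0.7) fall inside the published ranges
(p ≈ 0.033–0.053 against 0.0297–0.0554; μ ≈ 0.043–0.061 against
0.0411–0.0831), which is the calibration evidence for the default. Rest
transitions are repeated exactly rather than bridged — a resting group does
not wander — so bridge noise cannot manufacture detections during rest
blocks.

### Groups

`G = 40` groups always (capped at N when N < 40, with all sizes 1). Group
sizes are drawn from a configurable pool — by default a geometric-like decay
on {1..30}, a synthetic stand-in for empirical group sizes of a gregarious
ungulate — *conditioned on summing exactly to N* via a dynamic-programming
pass over the pool distribution. Conditioning is exact: a naive
"last group absorbs the remainder" scheme produces a single degenerate group
of several hundred animals whenever the pool mean differs from N/G. The sum
constraint forces the realized mean size to N/G (12 at N = 480), whatever
the pool shape; the pool controls dispersion around that mean.

## Detection geometry

Cameras sit at the centroids of 36 of 144 cells (one uniformly drawn cell
per 2×2 block — the randomized-regular reading of the design), each with a
circular-sector viewshed (r = 15 m, 42° opening, facing North; bearings are
degrees clockwise from North, coordinates in metres from the southwest
corner). Segment–sector intersection is computed exactly (endpoint
containment, radial-edge crossing, arc crossing), not by polygonal
approximation; unit tests check it against a dense point-sampling oracle.

A group whose fine-scale path crosses a viewshed during an hour contributes
its full size once to that camera-hour (`n_ijh`); re-appearances in later
hours count again, which is what lets unmarked animals be double-counted
across a day. Hourly counts are thinned binomially by the camera's
conditional detection probability and summed to daily counts
`y_ij = Σ_h y_ijh`; the binary reduction is `w_ij = 1{y_ij > 0}`.

The spatially varying detection regime draws a zero-mean Matérn Gaussian
field (smoothness 1.5, length scale 2700 m, sd 0.75 — declared defaults, as
no published values exist) at the camera locations and sets
`P_i = invlogit(logit(2/3) + x_i)`. The field value `x_i` is also the
covariate handed to covariate submodels. Because the inverse logit is
nonlinear, the expected probability is ≈ 0.65 rather than 2/3 exactly.
Trajectories are not reflected at the study boundary; only viewshed
intersections generate data.

## Ground truths

* **Abundance** λ = N / 144 exactly: activity centres per cell.
* **Site use** λ_use: each group's HRA disc (radius `σ√χ²₂(0.99)`) is
  intersected with every cell rectangle (exact clamped-distance test);
  overlapped cells receive the whole group size, and the mean over the 144
  cells is taken. Under closure, individuals are bounded to their centre
  cells by construction and λ_use = λ (the published convention); the disc
  computation applies to open populations. Members of a group share its
  home range.
* **Trends**: a decline to `f·N` is simulated as an *independent*
  population of `round(f·N)` individuals (fresh centres, walks,
  detections); the true ratio is 1/f. Independent populations mirror the
  post-hoc use of two separately surveyed years.
* **Realized detection parameters**: the per-capita daily detection
  probability p (and rate μ) are computed from the crossing record as the
  expected number of detected individuals (counts, for μ) per day divided
  by N, using per-group crossing-hour counts and camera-level thinning
  probabilities.

## Inference

The three mixtures (BernP/Royle–Nichols, binomial BP, Poisson PP) share the
Poisson state `N_i ~ Poisson(λ)`. The site likelihood is marginalized over
`N_i = 0..K` with log-sum-exp; `K = 100` for binary data and
`max(y_ij) + 100` for counts. Truncation error is checked to be below 1e-6
when K grows by 100. Sufficient statistics (binomial coefficients,
factorials) are precomputed once per dataset so each likelihood evaluation
is a small dense array operation.

Priors are weakly informative on the unconstrained scale:
`log λ ~ N(0, 1.5)`, detection intercept `β0 ~ N(0, 1.5)` (logit scale for
BernP/BP, log scale for PP — a logit link is ill-defined for a rate that
may exceed 1), slope `β1 ~ N(0, 1)`. Posteriors are sampled with the
`emcee` affine-invariant ensemble sampler (8 walkers, 1000 steps, 300
warmup, thin 2 by default), initialized near the Nelder–Mead MAP; any
sampler producing exchangeable draws from this 2–3 dimensional posterior
would do, and a MAP + Laplace mode exists for smoke tests. Split-R̂ across
walkers above 1.05 raises a convergence flag in the result; flagged fits
are recorded, never discarded, matching the study convention of keeping
non-converged replicates.

Goodness of fit uses the posterior-predictive P-value with a Pearson
discrepancy `Σ (y − E[y|θ])² / (E[y|θ] + 0.5)` (the 0.5 guards sparse
cells), replicating data from the full hierarchy per draw. Model comparison
uses PSIS-LOO ELPD with the site (camera) as the exchangeable leave-one-out
unit. Note that LOO-ELPDs compare BernP on binary data against BP/PP on
counts — smaller-support data yield higher predictive density, which is
inherent to comparing these models as practitioners do.

## Evaluation

Relative bias `(θ̂−θ)/θ` uses the posterior mean as point estimate
(posterior median available); accuracy is `|RB| ≤ 0.5`, inclusive at the
boundary (the stricter `<` is available as an option). Coverage is the
fraction of replicates whose equal-tailed 95% credible interval contains
the truth, benchmarked against 0.95. Trend point estimates are ratios of
posterior means from independent fits; trend intervals resample
independent draw pairs. Study tables report per-scenario accuracy
proportions with a study-level median row.

## Problem sizes

The default study grid is the full published design (10 parameter rows × 2
values of ρ, plus spatial-detection variants at σ = 300, declines of 0, 10
and 20%, 40 replicates). The shipped test suite and acceptance script run
reduced versions chosen as sensible desk-scale studies: the test suite's
study fixture covers all 10 parameter rows at ρ = 0.7 with 2 replicates and
all three declines; parameter-recovery checks use 40 replicates per family
(8 in the acceptance script) at 36 sites × 25 occasions, λ = 3,
θ_det = 0.3.

## What the generator does and does not emulate

The generator captures serially autocorrelated, home-ranging, group-level
movement; an activity schedule; exact viewshed geometry; group-wise
simultaneous detection; per-hour re-counting; and spatially correlated
detection probability. It does not emulate landscape or climate covariates,
inter-group interactions, temporal variation in detectability, camera
failures, or within-group spatial spread — a group is a single point, so
either the whole group is in view or none of it. That last simplification
matters: under closure with σ = 150, group centres are isolated points and
roughly three quarters of cameras can never record anything, so the
Poisson-state models see a zero-inflated dataset and shrink λ sharply. With
individual-level centres the same machinery reproduces the classical
pattern (binary and Poisson mixtures near truth, binomial mixture inflated
by double counts); passing tests on group-level data therefore demonstrate
estimator behaviour under *strong* detection clustering, not under the
milder clustering of real, spatially spread groups.

## Known limitations

* Zero-inflated and negative-binomial state models are out of scope.
* The ensemble sampler is adequate for these low-dimensional posteriors but
  reports walker-based split-R̂, a heuristic, as its convergence summary.
* Bayesian P-values use one discrepancy (Pearson); conclusions about
  misfit are tied to that choice.
* The Brownian-bridge and Matérn parameterizations are declared defaults
  calibrated only against published summary ranges, not fitted to data.
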