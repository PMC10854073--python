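# Methods

## Model

A step-selection function (SSF) models the transition density of an
animal's position as a weighted distribution,

    [s(tᵢ) | s(tᵢ₋₁), β] ∝ g(w(s(tᵢ)), β) · fᵢ(s(tᵢ) | s(tᵢ₋₁)),

where fᵢ is the movement (availability) kernel and g weights movement by
habitat covariates w.  Ecological diffusion — motility δ(s) inside both
spatial derivatives of the Fokker–Planck equation — yields, after
homogenization, a closed-form kernel: an isotropic bivariate Gaussian
centered on the previous fix with per-coordinate variance σ² = 2δ̄(tᵢ)Δtᵢ.
Changing variables to step length l and angle θ (Jacobian determinant l)
turns this into

    [l, θ] = (l/σ²) exp(−l²/2σ²) · 1/(2π),

i.e. Rayleigh(σ) lengths and uniform angles.  The two parameterizations
are the same distribution; `rayssf.kernels` implements both, property-tests
their equality pointwise, and cross-checks the samplers distributionally.
Because σ² scales with Δtᵢ, the kernel is continuous-time: every step of
an irregularly sampled track defines a valid stratum.

Since the angle distribution is uniform, a "turning angle relative to the
previous heading" and an "absolute bearing" induce the same endpoint
distribution.  The samplers draw absolute bearings, which additionally
makes the first step of a track usable (no prior heading is needed), so
strata start at step 1.

### Selection functions

Two forms of g are supported in the conditional likelihood
ℓ(β) = Σᵢ [η_used − log Σⱼ exp(ηⱼ)]:

- **exponential** (the conventional choice): g = exp(w′β), η = w′β.
  Inference is relative selection strength.  ℓ is concave in β.
- **ede_residence**: the diffusion model's own selection function
  g = 1/(δ(s)Δt) with δ(s) = (Δs²/4Δt)·logit⁻¹(w′β), giving
  η = log g = log(1 + exp(−w′β)) up to stratum constants.  Inference maps
  directly to residence time (large w′β ⇒ high motility ⇒ low residence).

Stratum-constant factors — intercepts, and the Δs²/(4Δt)·Δt constants of
the residence-time form — cancel inside the softmax and are therefore not
estimable; neither is included.  This invariance is property-tested.

### Plug-in movement parameters

δ̄(tᵢ) is pre-estimated by the temporal moving average
Σ ‖Δsⱼ‖²/(4nᵢΔtⱼ) over steps whose midpoint lies within a window of step
i's midpoint (inclusive; step i always contributes).  It is then treated
as a known constant during fitting, as is the gamma baseline's
shape/rate.  Uncertainty in these plug-ins is **not** propagated, so
reported selection-coefficient uncertainty can be biased low; every fit
report carries this caveat.  Joint movement-plus-selection estimation
(iSSA-style) is deliberately out of scope.

## Tunable parameters

| parameter | default | units | notes |
|---|---|---|---|
| motility window half-width | 24 | h | temporal window centered on the step midpoint; 0 = each step alone, ∞ = whole track.  A step-count window is available for irregular data exploration.  Wider ⇒ smoother δ̄ series.  The right span is study-dependent; with a constant-motility generator the widest window is the matched choice, and the validation experiments use ∞. |
| motility floor | 1e-8 | m²/h | keeps σ² > 0 when an animal is stationary |
| M (available per used) | 100 | — | the case-study convention; validation shows estimates move < 1 SE between M = 100 and 500 |
| ci_level | 0.90 | — | Wald intervals from the observed information; `profile_ci` provides profile-likelihood intervals because reference software is ambiguous between the two |
| gradient tolerance | 1e-8 | — | BFGS `gtol`, scaled by \|ℓ\| for large problems; max 500 iterations |
| Hessian FD step | 1e-5 | — | central differences of the analytic gradient, on standardized covariates |
| out-of-bounds redraw cap | 10·M | draws | then candidates drop; a stratum drops when its used point is out of bounds or fewer than M/2 candidates survive; all drops are counted and reported |
| candidate radius (simulator) | 5σ | m | Gaussian mass beyond 5σ < 1e-6 |

Covariate standardization defaults ON in the CLI fitting pipeline;
coefficients are reported on both scales (the z-scored layers and, via the
stored per-layer mean/sd, the raw scale).

## Synthetic study conditions

The simulator draws each next position from the discrete distribution over
landscape cell centers within 5σ of the current position, with probability
∝ g(w(cell), β) × Gaussian density at the cell center — exact sampling for
the discretized model, with deterministic cost.  Cells outside the
landscape get zero probability (soft reflection, logged per step).
Covariates are piecewise-constant on the grid, so snapping positions to
cell centers does not distort covariate values; the only discretization
effect is the lattice approximation of the Gaussian, which vanishes as
grain/σ → 0 and is checked by a test comparing the step-length
distribution to the Rayleigh law at two grains.

The validation experiments (`rayssf.experiments`) fix one set of
conditions, chosen once as a plausible mid-sized mammal telemetry study:

- motility δ = 50 m²/h, constant in time, so σ ranges 17–28 m across the
  interval mixture;
- Δt mixture {3 h: 0.55, 4 h: 0.40, 8 h: 0.05} — a schedule dominated by
  3- and 4-hour fixes with occasional 8-hour gaps;
- a 4 km × 4 km landscape at 5 m grain (grain/σ ≈ 0.2–0.3) with two
  standardized smoothed-Gaussian-noise covariates, correlation lengths
  ≈ 40 m and ≈ 80 m.  Selection is identified only by within-step
  covariate contrast, so layers must vary at the scale of a step; a
  landscape-spanning gradient, by contrast, is nearly constant within any
  stratum and its coefficient is weakly identified;
- true β = (1.0, −0.5) on the exponential form;
- 500-step tracks and M = 50 in the 200-replicate recovery study (sizes
  chosen so the replicated experiments complete in about a minute while
  leaving Monte-Carlo error well below the effects being measured);
  300-step tracks in the 50-replicate precision comparison; M = 100
  elsewhere, matching the case-study convention.

What the generator does *not* emulate: GPS measurement error, fix loss
correlated with habitat, directional persistence, boundary-constrained
home ranges, and temporally varying motility.  Passing the validation
suite therefore demonstrates internal consistency of estimator and
simulator under the stated model, not robustness to these real-data
features.

## Numerical choices

- Log-sum-exp guarding throughout the conditional likelihood; a β of ±200
  on standardized covariates stays finite.
- BFGS with analytic gradients for both forms, followed by Newton polish
  steps using the observed information when BFGS halts on precision loss
  short of the gradient tolerance; the final gradient norm is reported.
- Observed information by central differences of the analytic gradient
  (step 1e-5); covariance is its inverse, symmetrized.
- Rayleigh sampling by inverse CDF, l = σ√(−2 ln U), so draws are a
  deterministic function of the uniform stream and reproducible across
  implementations from a documented stream.
- Gamma MLE on log-parameters (Nelder–Mead) from the method-of-moments
  start; zero lengths are excluded with a count (a zero step is a
  non-move, and the gamma density is undefined at 0 for shape < 1).
- Non-identifiability (zero within-stratum contrast for every stratum) is
  detected before optimization and raised as a distinct error.
- Grid cells are half-open, [x₀, x₀+Δs) × [y₀, y₀+Δs), row-major with the
  origin at the lower-left corner: one documented convention for
  point-in-cell lookup, shared by the simulator, the extractor and the
  ASCII-grid I/O.
- Time is hours internally; ISO-8601 timestamps are converted on read,
  numeric timestamps are taken as hours.  Coordinates must be projected
  meters; values in lon/lat range are rejected unless overridden.

## Known limitations

- Plug-in δ̄ (no joint estimation): CI coverage can dip below nominal when
  motility is poorly estimated, e.g. short tracks with narrow windows.
- The residence-time form's likelihood is not guaranteed concave; fits
  from the zero start have been well-behaved, but a grid or multi-start
  check is prudent for small, noisy datasets.
- No geodesy: tracks must arrive in a projected metric CRS.
- No outlier screening of fixes; gross position errors inflate δ̄ within
  their window.
- The gamma-baseline pipeline inherits the discrete-time restriction it
  exists to illustrate: it analyses only the regular-interval subset.
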