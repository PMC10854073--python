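# rayssf — continuous-time step-selection functions

`rayssf` is a toolkit for fitting step-selection functions (SSFs) to animal
telemetry data collected at **irregular fix intervals**.  Conventional SSFs
sample "available" steps from empirical or gamma step-length distributions,
which ties them to a regular sampling schedule and forces analysts to throw
away every fix that does not sit on that schedule.  `rayssf` instead uses
the availability kernel implied by ecological diffusion: step lengths are
Rayleigh-distributed with scale

    σ² = 2 δ̄(tᵢ) Δtᵢ

and turning angles are uniform on (0, 2π), which is exactly equivalent to
an isotropic bivariate Gaussian kernel on Cartesian coordinates with
per-coordinate variance σ².  Because Δtᵢ enters the kernel explicitly, a
track whose intervals mix 3-, 4- and 8-hour gaps is used in full.

The homogenized motility coefficient δ̄(tᵢ) (m²/h; inversely related to
residence time) is pre-estimated from the track by a temporal moving
average,

    δ̄(tᵢ) ≈ Σ_{tⱼ∼tᵢ} ‖Δsⱼ‖² / (4 nᵢ Δtⱼ),

and plugged into the kernel.  Selection coefficients β are then estimated
by maximizing the conditional (within-stratum softmax) likelihood over
choice sets of one used step plus M sampled available steps,

    ℓ(β) = Σᵢ [ η_used,i − log Σⱼ exp(ηᵢⱼ) ],

with η = w′β for the exponential selection function g = exp(w′β), or
η = log(1 + exp(−w′β)) for the residence-time selection function implied
by the diffusion model (g = 1/(δΔt) with motility on an inverse-logit link
of the covariates).  Wald or profile confidence intervals come from the
observed information.

The package also implements the two reference pipelines used for
comparison: a plain-diffusion kernel (single motility fitted to l/√Δt) and
the discrete-time gamma step-length baseline, which must first discard all
steps off the regular interval.  A trajectory simulator generates tracks
from the weighted-distribution SSF model on gridded landscapes for
end-to-end validation.

Intended users are movement ecologists and biostatisticians working with
GPS/Argos telemetry and gridded environmental covariates.

## Worked example

Simulate a 300-step track with known selection (β = +1.0 on `forage`,
−0.5 on `terrain`) on a synthetic landscape, then recover the coefficients
with the full pipeline:

```python
import numpy as np
from rayssf import (simulate_landscape, SimulationConfig, simulate_track,
                    derive_steps, estimate_motility, build_choice_sets, fit_ssf)

scape = simulate_landscape(
    nrow=400, ncol=400, grain=5.0,
    layer_spec={"forage": {"kind": "smooth", "sigma_cells": 8.0},
                "terrain": {"kind": "smooth", "sigma_cells": 16.0}},
    seed=8, standardize_layers=True)

config = SimulationConfig(landscape=scape, beta=[1.0, -0.5],
                          n_steps=300, delta=50.0, seed=8)
track, _ = simulate_track(config)          # Δt mixes 3, 4 and 8 h

steps = derive_steps(track)
mot = estimate_motility(steps, window_hours=np.inf)
sets = build_choice_sets(steps, mot, scape, M=100, sampler="polar",
                         rng=np.random.default_rng(8))
fit = fit_ssf(sets, ci_level=0.90)
for name, b, lo, hi in zip(fit.covariate_names, fit.beta,
                           fit.ci_lower, fit.ci_upper):
    print(f"{name:8s} {b:+.3f}  90% CI [{lo:+.3f}, {hi:+.3f}]")
```

prints

```
forage   +0.801  90% CI [+0.540, +1.062]
terrain  -0.305  90% CI [-0.732, +0.122]
```

Both true coefficients lie inside their 90% intervals; a single 300-step
track carries limited information, so intervals this wide are expected
(the replicated recovery experiment in `rayssf.experiments` quantifies
calibration).  The motility estimate here is δ̄ = 46.7 m²/h against a
generating value of 50, and all 300 steps form strata — including the
8-hour ones a discrete-time analysis would discard.

The same pipeline is available from the shell:

```sh
rayssf simulate --config sim.yaml --seed 8 --out data/
rayssf fit --track data/track.csv --landscape data/landscape \
           --kernel rayleigh --m 100 --seed 8 --out fit_rayleigh/
rayssf fit --track data/track.csv --landscape data/landscape \
           --kernel gamma --dt-regular 3 --seed 8 --out fit_gamma/
rayssf compare fit_rayleigh/fit.json fit_gamma/fit.json --out compare.csv
```

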