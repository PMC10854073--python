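"""Availability kernels for step sampling.

The continuous-time kernel is an isotropic bivariate Gaussian centered on
the previous fix with per-coordinate variance σ² = 2δ̄Δt.  A change of
variables to polar step coordinates (length l, angle θ) with Jacobian
determinant l turns it into the product of a Rayleigh(σ) length density
and a Uniform(0, 2π) angle density:

    [l, θ] = (l / σ²) exp(−l² / (2σ²)) · 1/(2π)

Sampling steps in polar form is therefore exactly equivalent to sampling
endpoints from the Gaussian.  Because σ² carries Δt explicitly, the kernel
applies directly to telemetry with irregular fix intervals — no
subsampling to a regular schedule is needed.

Two reference variants are included: a plain-diffusion kernel (a single
motility for the whole track, fitted to l/√Δt) and the conventional
discrete-time gamma step-length baseline, which requires a regular Δt.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, special, stats

TWO_PI = 2.0 * np.pi
LOG_TWO_PI = np.log(TWO_PI)


# ---------------------------------------------------------------------------
# densities

def polar_logpdf(l, theta, sigma2):
    """Log joint density of (step length, angle) under the diffusion kernel.

    Rayleigh(σ) for the length times Uniform(0, 2π) for the angle;
    −inf at l = 0 (the Rayleigh density vanishes at the origin).
    """
    l = np.asarray(l, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if np.any(l < 0):
        raise ValueError("step length must be nonnegative")
    if np.any((theta < 0) | (theta >= TWO_PI)):
        raise ValueError("theta must lie in [0, 2*pi)")
    sigma2 = _check_sigma2(sigma2)
    with np.errstate(divide="ignore"):
        out = np.log(l) - np.log(sigma2) - l**2 / (2.0 * sigma2) - LOG_TWO_PI
    return float(out) if out.ndim == 0 else out


def cartesian_logpdf(endpoint, origin, sigma2):
    """Log density of the isotropic Gaussian availability kernel.

    Bivariate normal with mean ``origin`` and covariance σ²·I, normalizing
    constant included.
    """
    sigma2 = _check_sigma2(sigma2)
    endpoint = np.asarray(endpoint, dtype=float)
    origin = np.asarray(origin, dtype=float)
    d = endpoint - origin
    r2 = np.sum(d * d, axis=-1)
    out = -LOG_TWO_PI - np.log(sigma2) - r2 / (2.0 * sigma2)
    return float(out) if np.ndim(out) == 0 else out


def jacobian_det(l, theta):
    """Jacobian determinant of the polar-to-Cartesian step map.

    Evaluated literally as l·cos²θ + l·sin²θ so the trigonometric identity
    collapsing it to l can be property-tested rather than assumed.
    """
    l = np.asarray(l, dtype=float)
    if np.any(l < 0):
        raise ValueError("step length must be nonnegative")
    theta = np.asarray(theta, dtype=float)
    out = l * np.cos(theta) ** 2 + l * np.sin(theta) ** 2
    return float(out) if out.ndim == 0 else out


def _check_sigma2(sigma2) -> float:
    sigma2 = float(sigma2)
    if not np.isfinite(sigma2) or sigma2 <= 0:
        raise ValueError("sigma2 must be a positive finite scalar")
    return sigma2


# ---------------------------------------------------------------------------
# samplers (pure functions of inputs + rng state)

def sample_polar(origin, sigma2, M, rng) -> np.ndarray:
    """Sample M endpoints via Rayleigh lengths and uniform angles.

    The length uses the inverse CDF, l = σ√(−2 ln U) with U ~ Unif(0, 1],
    so the draw is a deterministic function of the uniform stream.
    """
    sigma2 = _check_sigma2(sigma2)
    if M < 1:
        raise ValueError("M must be >= 1")
    u = 1.0 - rng.random(M)  # in (0, 1]
    l = np.sqrt(sigma2) * np.sqrt(-2.0 * np.log(u))
    theta = rng.uniform(0.0, TWO_PI, M)
    origin = np.asarray(origin, dtype=float)
    return origin + np.column_stack([l * np.cos(theta), l * np.sin(theta)])


def sample_cartesian(origin, sigma2, M, rng) -> np.ndarray:
    """Sample M endpoints as two independent Gaussian coordinates."""
    sigma2 = _check_sigma2(sigma2)
    if M < 1:
        raise ValueError("M must be >= 1")
    origin = np.asarray(origin, dtype=float)
    return origin + np.sqrt(sigma2) * rng.standard_normal((M, 2))


def sample_gamma_polar(origin, shape, rate, M, rng) -> np.ndarray:
    """Sample M endpoints with gamma lengths and uniform angles.

    The discrete-time baseline: lengths from Gamma(shape, rate), angles
    uniform.  Only meaningful at a fixed, regular Δt.
    """
    if shape <= 0 or rate <= 0:
        raise ValueError("shape and rate must be positive")
    if M < 1:
        raise ValueError("M must be >= 1")
    l = rng.gamma(shape, 1.0 / rate, M)
    theta = rng.uniform(0.0, TWO_PI, M)
    origin = np.asarray(origin, dtype=float)
    return origin + np.column_stack([l * np.cos(theta), l * np.sin(theta)])


# ---------------------------------------------------------------------------
# plain-diffusion variant

def plain_diffusion_scale(l_values, dt_values) -> float:
    """Single Rayleigh scale for time-standardized lengths l/√Δt.

    Under plain (spatially constant) diffusion l_i/√Δt_i is Rayleigh with
    a common scale; its MLE is σ̂²₀ = Σ(l²/Δt)/(2n).  The per-step kernel
    scale is then σ²₀·Δt_i.
    """
    l = np.asarray(l_values, dtype=float)
    dt = np.asarray(dt_values, dtype=float)
    if l.size == 0:
        raise ValueError("need at least one step")
    if np.any(dt <= 0):
        raise ValueError("all dt must be positive")
    return float(np.sum(l**2 / dt) / (2.0 * l.size))


# ---------------------------------------------------------------------------
# gamma step-length baseline

@dataclass
class GammaStepModel:
    """Gamma step-length model fitted by maximum likelihood."""

    shape: float
    rate: float
    n: int
    loglik: float
    converged: bool
    n_zero_dropped: int = 0

    @property
    def mean(self) -> float:
        return self.shape / self.rate


def _gamma_loglik(shape: float, rate: float, l: np.ndarray) -> float:
    return float(
        np.sum(
            shape * np.log(rate)
            - special.gammaln(shape)
            + (shape - 1.0) * np.log(l)
            - rate * l
        )
    )


def gamma_moment_start(l: np.ndarray) -> tuple[float, float]:
    """Method-of-moments initialization: shape = m²/v, rate = m/v."""
    m = float(np.mean(l))
    v = float(np.var(l))
    if v <= 0:
        raise ValueError("degenerate input: zero variance")
    return m * m / v, m / v


def fit_gamma_lengths(l_values) -> GammaStepModel:
    """Fit Gamma(shape, rate) to step lengths by numerical MLE.

    Zeros are excluded (the gamma density is not defined at 0 for
    shape < 1 and a zero step is a non-move, not a length draw); the count
    of exclusions is carried on the result.  Optimization runs on
    log-parameters from the method-of-moments start.
    """
    l = np.asarray(l_values, dtype=float)
    if np.any(l < 0):
        raise ValueError("step lengths must be nonnegative")
    n_zero = int(np.sum(l == 0))
    l = l[l > 0]
    if l.size < 2:
        raise ValueError("need at least 2 positive step lengths")
    if np.all(l == l[0]):
        raise ValueError("all step lengths equal; gamma shape diverges")

    shape0, rate0 = gamma_moment_start(l)

    def nll(logp):
        return -_gamma_loglik(np.exp(logp[0]), np.exp(logp[1]), l)

    res = optimize.minimize(
        nll, x0=np.log([shape0, rate0]), method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-10, "maxiter": 2000},
    )
    shape, rate = np.exp(res.x)
    return GammaStepModel(
        shape=float(shape),
        rate=float(rate),
        n=int(l.size),
        loglik=-float(res.fun),
        converged=bool(res.success),
        n_zero_dropped=n_zero,
    )


def gamma_length_logpdf(l, model: GammaStepModel):
    """Log density of step lengths under a fitted gamma baseline."""
    return stats.gamma.logpdf(np.asarray(l, dtype=float), a=model.shape,
                              scale=1.0 / model.rate)
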