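"""Homogenized motility estimation.

The availability kernel's variance is set by the homogenized motility
coefficient δ̄(t_i) (m²/h), pre-estimated from the track itself by a
temporal moving average of squared displacements:

    δ̄(t_i) ≈ Σ_{t_j ~ t_i} ||Δs_j||² / (4 n_i Δt_j)

where the sum runs over the n_i steps whose midpoint time falls within a
window around step i's midpoint (step i always included).  Under isotropic
diffusion E||Δs||² = 4δΔt per step, so each term is an unbiased one-step
estimate of the local motility; averaging trades temporal resolution for
variance.  δ̄ is treated as a plug-in constant during selection fitting —
its uncertainty is not propagated, and fit reports say so.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tracks import StepSeries

DEFAULT_WINDOW_HOURS = 24.0
DEFAULT_FLOOR = 1e-8  # m²/h; keeps kernel variance positive when stationary


@dataclass
class MotilitySeries:
    """Per-step homogenized motility δ̄(t_i) with window bookkeeping."""

    delta_bar: np.ndarray     # m²/h, already floored
    n_window: np.ndarray      # steps contributing to each estimate
    window_hours: float | None
    window_steps: int | None
    floor: float
    t_mid: np.ndarray
    dt: np.ndarray

    def __len__(self) -> int:
        return len(self.delta_bar)

    def sigma2(self) -> np.ndarray:
        """Per-step kernel scale σ² = 2 δ̄(t_i) Δt_i (m²)."""
        return motility_to_sigma2(self.delta_bar, self.dt)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "step_id": np.arange(len(self)),
                "t_mid": self.t_mid,
                "dt_h": self.dt,
                "delta_bar": self.delta_bar,
                "n_window": self.n_window,
            }
        )


def estimate_motility(
    steps: StepSeries,
    window_hours: float | None = DEFAULT_WINDOW_HOURS,
    window_steps: int | None = None,
    floor: float = DEFAULT_FLOOR,
) -> MotilitySeries:
    """Moving-average motility estimate per step.

    Parameters
    ----------
    steps : StepSeries
        Derived steps (irregular Δt is fine; each step's own Δt_j sits in
        the denominator of its term).
    window_hours : float, optional
        Temporal half-width of the window, centered on each step's
        midpoint time, inclusive at both ends.  ``0`` means each step uses
        only itself; ``np.inf`` uses the whole track.  Default 24 h.
    window_steps : int, optional
        Alternative half-width in number of neighbouring steps; overrides
        ``window_hours`` when given.
    floor : float
        Strictly positive lower bound applied to δ̄ (default 1e-8 m²/h) so
        downstream kernels never have zero variance.
    """
    if len(steps) == 0:
        raise ValueError("StepSeries is empty")
    if floor <= 0:
        raise ValueError("floor must be strictly positive")
    term = steps.length**2 / (4.0 * steps.dt)  # per-step motility estimate
    mid = steps.midpoint_time
    n = len(steps)

    if window_steps is not None:
        if window_steps < 0:
            raise ValueError("window_steps must be >= 0")
        idx = np.arange(n)
        lo = np.maximum(idx - window_steps, 0)
        hi = np.minimum(idx + window_steps, n - 1) + 1
    else:
        if window_hours is None or window_hours < 0:
            raise ValueError("window_hours must be >= 0")
        # midpoints are nondecreasing for a valid track, so a sorted search works
        lo = np.searchsorted(mid, mid - window_hours, side="left")
        hi = np.searchsorted(mid, mid + window_hours, side="right")

    csum = np.concatenate([[0.0], np.cumsum(term)])
    n_window = hi - lo
    if np.any(n_window < 1):
        raise AssertionError("window must always contain the step itself")
    # each term already carries its own 1/(4Δt_j); the window just averages
    delta = (csum[hi] - csum[lo]) / n_window
    return MotilitySeries(
        delta_bar=np.maximum(delta, floor),
        n_window=n_window,
        window_hours=None if window_steps is not None else window_hours,
        window_steps=window_steps,
        floor=floor,
        t_mid=mid,
        dt=steps.dt.copy(),
    )


def motility_to_sigma2(delta_bar, dt):
    """Kernel scale σ² = 2 δ̄ Δt.

    This is simultaneously the Rayleigh scale parameter (squared) of the
    step-length distribution and the per-coordinate variance of the
    equivalent isotropic Gaussian availability kernel.
    """
    delta_bar = np.asarray(delta_bar, dtype=float)
    dt = np.asarray(dt, dtype=float)
    if np.any(delta_bar <= 0):
        raise ValueError("delta_bar must be positive")
    if np.any(dt <= 0):
        raise ValueError("dt must be positive")
    out = 2.0 * delta_bar * dt
    return float(out) if out.ndim == 0 else out


def write_motility(motility: MotilitySeries, path) -> None:
    motility.to_frame().to_csv(path, index=False, float_format="%.17g")
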