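import numpy as np
import pytest

from rayssf import (
    SimulationConfig,
    build_choice_sets,
    derive_steps,
    estimate_motility,
    simulate_landscape,
    simulate_track,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_landscape():
    """Standardized 2-layer smoothed-noise landscape, 1.2 km at 5 m grain."""
    return simulate_landscape(
        nrow=240,
        ncol=240,
        grain=5.0,
        layer_spec={
            "forage": {"kind": "smooth", "sigma_cells": 8.0},
            "terrain": {"kind": "smooth", "sigma_cells": 16.0},
        },
        seed=99,
        standardize_layers=True,
    )


@pytest.fixture(scope="session")
def sim_track(small_landscape):
    """120-step track simulated with known selection on the small landscape."""
    config = SimulationConfig(
        landscape=small_landscape,
        beta=np.array([1.0, -0.5]),
        n_steps=120,
        delta=20.0,
        seed=7,
    )
    track, truth = simulate_track(config)
    return track


@pytest.fixture(scope="session")
def sim_choice_sets(small_landscape, sim_track):
    """Choice sets built from the simulated track (Rayleigh kernel, M=25)."""
    steps = derive_steps(sim_track)
    mot = estimate_motility(steps, window_hours=np.inf)
    return build_choice_sets(
        steps,
        mot,
        small_landscape,
        M=25,
        sampler="polar",
        rng=np.random.default_rng(11),
    )
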