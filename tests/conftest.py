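"""Shared fixtures: small synthetic datasets reused across test modules."""

import numpy as np
import pandas as pd
import pytest

import pinglab as pl
from pinglab.synth import NoiseModel, make_leadfield


@pytest.fixture(scope="session")
def small_leadfield():
    return make_leadfield("two-dipole-default", n_channels=6)


@pytest.fixture(scope="session")
def oriented_epochs(small_leadfield):
    """One session, 8 orientations, clear tuning, short epoch."""
    noise = NoiseModel(sigma_base=0.5, impulse_window=(0.55, 0.7),
                       reduction_fraction=0.0)
    return pl.simulate_oriented_trials(
        128, n_orientations=8, tuning_gain=0.8, noise=noise,
        lf=small_leadfield, duration=0.8, srate=250.0, seed=7,
    )


@pytest.fixture(scope="session")
def null_epochs(small_leadfield):
    """Same geometry but no orientation information (gain 0)."""
    noise = NoiseModel(sigma_base=0.5, impulse_window=(0.55, 0.7),
                       reduction_fraction=0.0)
    return pl.simulate_oriented_trials(
        128, n_orientations=8, tuning_gain=0.0, noise=noise,
        lf=small_leadfield, duration=0.8, srate=250.0, seed=7,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def plain_epochs():
    """Minimal hand-built EpochSet for container-level tests."""
    rng = np.random.default_rng(3)
    data = rng.standard_normal((10, 3, 50))
    meta = pd.DataFrame({
        "orientation": np.tile([0.0, 90.0], 5),
        "session": ["a"] * 5 + ["b"] * 5,
        "subject": ["s1"] * 10,
    })
    return pl.EpochSet(data, srate=100.0, t0=-0.1,
                       channel_labels=["c1", "c2", "c3"], trial_meta=meta)
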