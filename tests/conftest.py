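"""Shared fixtures: small phantoms, trajectories and simulated k-space."""

import numpy as np
import pytest

from starfat import (
    AcqParams,
    FatModel,
    build_trajectory,
    make_coils,
    make_phantom,
)

FOV_MM = 256.0


@pytest.fixture(scope="session")
def fat_model():
    return FatModel.liver_6peak()


@pytest.fixture(scope="session")
def phantom48():
    return make_phantom(48)


@pytest.fixture(scope="session")
def coils48():
    return make_coils(48, 8, seed=2)


@pytest.fixture(scope="session")
def acq48():
    return AcqParams(n_read=48, n_proj=120, n_echo=6, fov_mm=FOV_MM)


@pytest.fixture(scope="session")
def traj48(acq48):
    return build_trajectory(acq48)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
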