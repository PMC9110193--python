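"""Shared fixtures: small phantoms and toy grids, generated at test time."""

import dataclasses

import numpy as np
import pytest

from ctpdeconv.core import AIFCurve, TimeGrid
from ctpdeconv.phantom import PhantomSpec, synthesize_phantom


@pytest.fixture(scope="session")
def grid8():
    return TimeGrid(dt=1.0, n_frames=8)


@pytest.fixture(scope="session")
def small_spec():
    """Desk-scale phantom: 32x32x2 voxels, 32 frames, default lesion scaled down."""
    return PhantomSpec(
        shape=(32, 32, 2),
        grid=TimeGrid(dt=1.0, n_frames=32, t0_index=5),
        lesion_center=(23, 16),
        core_radius=3.0,
        penumbra_radius=6.0,
        noise_sigma=5.0,
        seed=123,
    )


@pytest.fixture(scope="session")
def small_noiseless_spec(small_spec):
    return dataclasses.replace(small_spec, noise_sigma=0.0)


@pytest.fixture(scope="session")
def small_noiseless(small_noiseless_spec):
    return synthesize_phantom(small_noiseless_spec)


@pytest.fixture(scope="session")
def symmetric_spec(small_spec):
    """Lesion-free, noise-free: exactly mirror-symmetric."""
    return dataclasses.replace(small_spec, lesion=False, noise_sigma=0.0)


@pytest.fixture(scope="session")
def default_spec():
    return PhantomSpec()


def random_aif(grid: TimeGrid, seed: int = 0) -> AIFCurve:
    rng = np.random.default_rng(seed)
    return AIFCurve(values=rng.uniform(0.1, 1.0, grid.n_frames), grid=grid)
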