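"""Shared fixtures: a desk-scale phantom and point-cloud helpers.

The small phantom keeps the full geometry (hemispherical shell, dome hole,
head, stem) at a 128-voxel grid so unit tests run in seconds; the
full-size bench-scale phantom is exercised in the acceptance suite.
"""

import numpy as np
import pytest

from ctwear import (
    ExtractionConfig,
    FitConfig,
    PhantomSpec,
    auto_landmarks,
    generate_phantom,
)


def small_phantom_spec(**overrides) -> PhantomSpec:
    base = dict(
        cup_outer_diameter=20.0,
        cup_shell_thickness=2.5,
        dome_hole_diameter=4.0,
        head_diameter=8.0,
        stem_radius=2.0,
        stem_length=6.0,
        voxel_spacing=(0.2, 0.2, 0.2),
        grid_shape=(128, 128, 128),
        rng_seed=3,
    )
    base.update(overrides)
    return PhantomSpec(**base)


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    return small_phantom_spec()


@pytest.fixture(scope="session")
def noiseless_spec() -> PhantomSpec:
    return small_phantom_spec(psf_sigma=0.0, noise_sd=0.0)


@pytest.fixture(scope="session")
def noiseless_scan(noiseless_spec):
    vol, truth = generate_phantom(noiseless_spec)
    lm = auto_landmarks(truth, noiseless_spec)
    return noiseless_spec, vol, truth, lm


@pytest.fixture(scope="session")
def noisy_scan(small_spec):
    vol, truth = generate_phantom(small_spec)
    lm = auto_landmarks(truth, small_spec)
    return small_spec, vol, truth, lm


@pytest.fixture()
def ext_cfg(small_spec) -> ExtractionConfig:
    return ExtractionConfig(threshold=small_spec.default_threshold())


@pytest.fixture()
def fit_cfg() -> FitConfig:
    return FitConfig(rng_seed=11)


def sphere_points(
    rng: np.random.Generator,
    center,
    radius: float,
    n: int,
    noise_sd: float = 0.0,
    hemisphere_axis=None,
) -> np.ndarray:
    """Uniform random points on a sphere (or a hemisphere) with optional
    radial Gaussian noise."""
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    if hemisphere_axis is not None:
        axis = np.asarray(hemisphere_axis, dtype=float)
        axis = axis / np.linalg.norm(axis)
        flip = (v @ axis) < 0
        v[flip] -= 2.0 * np.outer(v[flip] @ axis, axis)
    r = radius + (noise_sd * rng.normal(size=n) if noise_sd > 0 else np.zeros(n))
    return np.asarray(center, dtype=float) + v * r[:, None]
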