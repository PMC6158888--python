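"""Shared fixtures: small phantoms and their ROIs, generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from halopet.core import SUVVolume
from halopet.phantom import PhantomSpec, generate_phantom, roi_from_truth


@pytest.fixture(scope="session")
def capsule_s10():
    """Noiseless blurred capsule: length 40 mm, S=10, B=1, PSF 7 mm."""
    spec = PhantomSpec(true_length_mm=40.0, peak_suv=10.0, noise_sd=0.0)
    vol, truth = generate_phantom(spec)
    roi = roi_from_truth(vol, truth)
    return vol, truth, roi, spec


@pytest.fixture(scope="session")
def sphere_s10():
    """Noiseless blurred sphere: radius 15 mm, S=10, B=1, PSF 7 mm."""
    spec = PhantomSpec(
        true_length_mm=30.0, diameter_mm=30.0, shape="sphere", peak_suv=10.0, noise_sd=0.0
    )
    vol, truth = generate_phantom(spec)
    roi = roi_from_truth(vol, truth)
    return vol, truth, roi, spec


@pytest.fixture(scope="session")
def noisy_capsule():
    """Capsule with realistic additive noise (SD 0.15 SUV)."""
    spec = PhantomSpec(true_length_mm=50.0, peak_suv=8.0, noise_sd=0.15, rng_seed=11)
    vol, truth = generate_phantom(spec)
    roi = roi_from_truth(vol, truth)
    return vol, truth, roi, spec


@pytest.fixture()
def hot_voxel_volume():
    """Uniform background 1.0 with a single hot voxel of SUV 13.07."""
    values = np.ones((12, 12, 12))
    values[5, 6, 7] = 13.07
    vol = SUVVolume(values=values)
    return vol


@pytest.fixture(scope="session")
def two_blob_volume():
    """Two avid spheres separated by background, on one grid."""
    n = 41
    v = 2.65
    c = (n - 1) / 2.0
    ii, jj, kk = np.indices((n, n, n))
    r1 = np.sqrt((ii - c) ** 2 + (jj - c) ** 2 + (kk - (c - 12)) ** 2) * v
    r2 = np.sqrt((ii - c) ** 2 + (jj - c) ** 2 + (kk - (c + 12)) ** 2) * v
    values = np.ones((n, n, n))
    values[r1 <= 10] = 8.0
    values[r2 <= 10] = 6.0
    return SUVVolume(values=values), (r1 <= 10), (r2 <= 10)
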