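import numpy as np
import pytest

import fiberslice as fs


@pytest.fixture(scope="session")
def straight_tube_mask():
    """Solid straight tube, radius 3 voxels, length 40, axis along x."""
    z, y, x = np.mgrid[0:20, 0:20, 0:60]
    mask = ((y - 9.5) ** 2 + (z - 9.5) ** 2 <= 9.0) & (x >= 10) & (x <= 50)
    return mask


@pytest.fixture(scope="session")
def wavy_phantom():
    """Noisy sinusoidal phantom at imaging scales, with ground truth."""
    spec = fs.preset("wavy", seed=1, noise_sigma=10.0)
    volume, truth = fs.make_phantom(spec, shape=(128, 128, 128))
    return volume, truth


@pytest.fixture(scope="session")
def straight_phantom():
    spec = fs.preset("straight", seed=3, noise_sigma=10.0)
    volume, truth = fs.make_phantom(spec, shape=(96, 128, 128))
    return volume, truth


@pytest.fixture(scope="session")
def helix_curve():
    t = np.linspace(0, 4 * np.pi, 200)
    pts = np.stack([3 * np.cos(t), 3 * np.sin(t), 0.5 * t], axis=1)
    return fs.Curve3D(pts)


def rough_initial_centerline(truth, step=120, noise=0.2, seed=1):
    """Subsampled, perturbed ground-truth centerline as a user would draw."""
    rng = np.random.default_rng(seed)
    sub = truth.centerline.points[::step]
    return sub + rng.normal(0, noise, sub.shape)
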