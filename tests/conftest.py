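import numpy as np
import pytest

from perishell.simulate import CohortSpec, make_anatomy
from perishell.volumes import BoldSeries, LabeledVolume


def symmetric_affine(shape, voxel=1.0):
    """Grid centred on the origin, symmetric about world x = 0."""
    aff = np.diag([voxel, voxel, voxel, 1.0])
    aff[:3, 3] = [-(n - 1) / 2.0 * voxel for n in shape]
    return aff


@pytest.fixture
def rng():
    return np.random.default_rng(20240122)


@pytest.fixture(scope="session")
def small_spec():
    """Small but geometrically valid cohort conditions for fast tests."""
    return CohortSpec(
        n_subjects=3, grid_shape=(36, 36, 24), voxel_mm=2.0,
        lesion_radius_mm=6.0, n_timepoints=60, seed=11,
    )


@pytest.fixture(scope="session")
def small_anatomy(small_spec):
    return make_anatomy(small_spec)


def make_volume(data, voxel=1.0, symmetric=True):
    data = np.asarray(data)
    aff = symmetric_affine(data.shape, voxel) if symmetric else np.diag([voxel] * 3 + [1.0])
    return LabeledVolume(data, aff)


def make_series(data, tr=2.0, voxel=1.0):
    data = np.asarray(data, dtype=np.float32)
    return BoldSeries(data, symmetric_affine(data.shape[:3], voxel), tr)


def sinusoid_series(shape, freqs_amps, t=195, tr=2.0):
    """Spatially-constant sum of sinusoids, one series per voxel."""
    tt = np.arange(t) * tr
    sig = np.zeros(t)
    for f, a in freqs_amps:
        sig += a * np.sin(2 * np.pi * f * tt + 0.3)
    data = np.broadcast_to(sig, shape + (t,)).copy()
    return make_series(data, tr=tr)
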