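import numpy as np
import pytest

from mdevmre import AcquisitionGrid, PhantomSpec, WaveSource, make_plane_wave_field

SQ2 = 1.0 / np.sqrt(2.0)


@pytest.fixture(scope="session")
def brainlike_gstar() -> complex:
    """Brain-like complex shear modulus: 1.2 kPa at loss angle 0.9 rad."""
    return 1200.0 * np.exp(0.9j)


@pytest.fixture(scope="session")
def small_grid() -> AcquisitionGrid:
    return AcquisitionGrid(
        shape=(48, 48, 12),
        voxel_size=(0.002, 0.002, 0.002),
        frequencies=(30.0, 40.0, 50.0, 60.0),
        n_timesteps=8,
        n_components=3,
    )


@pytest.fixture(scope="session")
def inplane_source() -> WaveSource:
    """Single shear source propagating in-plane at 45 deg, polarized along z."""
    return WaveSource(direction=(SQ2, SQ2, 0.0), polarization=(0.0, 0.0, 1.0), amplitude=30e-6)


@pytest.fixture(scope="session")
def plane_phantom(small_grid, inplane_source, brainlike_gstar):
    """Noise-free multifrequency plane-wave phantom and its ground truth."""
    spec = PhantomSpec(
        grid=small_grid,
        gstar=brainlike_gstar,
        sources=(inplane_source,),
        noise_sigma=0.0,
        seed=1,
    )
    field, truth = make_plane_wave_field(spec)
    return spec, field, truth


def interior_mask(shape_zyx, margin_z=2, margin_xy=4) -> np.ndarray:
    sel = np.zeros(shape_zyx, dtype=bool)
    sel[margin_z:-margin_z, margin_xy:-margin_xy, margin_xy:-margin_xy] = True
    return sel
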