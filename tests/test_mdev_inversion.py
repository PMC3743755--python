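import numpy as np
import pytest

from mdevmre import (
    AcquisitionGrid,
    ComplexWaveField,
    ElastogramPair,
    InversionConfig,
    compute_curl,
    helmholtz_scatter,
    mdev_invert,
    to_storage_loss,
)
from mdevmre.mdev_inversion import discrete_laplacian
from mdevmre.wavefield_io import CurlField

from conftest import interior_mask


def plane_wave_curl(gstar, frequencies=(50.0,), shape_xyz=(48, 48, 10), voxel=0.002,
                    density=1000.0):
    """CurlField of an in-plane 45-deg plane shear wave (analytic, no phantom chain)."""
    grid = AcquisitionGrid(shape=shape_xyz, voxel_size=(voxel,) * 3,
                           frequencies=tuple(frequencies), n_timesteps=8,
                           n_components=3, density=density)
    nz, ny, nx = grid.vol_shape_zyx
    y = np.arange(ny)[:, None] * voxel
    x = np.arange(nx)[None, :] * voxel
    s = (x + y) / np.sqrt(2)
    c = np.zeros((len(frequencies), 3, nz, ny, nx), complex)
    for fi, f in enumerate(frequencies):
        k = 2 * np.pi * f * np.sqrt(density / gstar)
        sl = np.exp(-1j * k * s)
        c[fi, 0] = sl
        c[fi, 1] = 0.6 * sl
    return CurlField(grid=grid, c=c, mask=np.ones((nz, ny, nx), bool))


class TestMdevInvert:
    def test_plane_wave_recovery(self):
        gstar = 1200.0 * np.exp(0.9j)
        c = plane_wave_curl(gstar)
        e = mdev_invert(c)
        sel = e.mask & interior_mask(e.mask.shape)
        assert abs(np.median(e.gabs[sel]) / 1200.0 - 1) < 0.02
        assert abs(np.median(e.phi[sel]) - 0.9) < 0.02

    def test_real_standing_wave_gives_zero_phi(self):
        grid = AcquisitionGrid(shape=(32, 32, 6), voxel_size=(0.002,) * 3,
                               frequencies=(50.0,), n_timesteps=8, n_components=3)
        nz, ny, nx = grid.vol_shape_zyx
        x = np.arange(nx)[None, :] * 0.002
        k = 250.0
        sl = np.cos(k * x) * np.ones((ny, nx))
        c = np.broadcast_to(sl, (1, 3, nz, ny, nx)).astype(complex).copy()
        field = CurlField(grid=grid, c=c, mask=np.ones((nz, ny, nx), bool))
        e = mdev_invert(field)
        np.testing.assert_allclose(e.phi[e.mask], 0.0, atol=1e-7)

    def test_invariant_under_global_complex_rescale(self):
        c = plane_wave_curl(1500.0 * np.exp(0.5j))
        e1 = mdev_invert(c)
        c2 = CurlField(grid=c.grid, c=(2.0 - 3.0j) * c.c, mask=c.mask)
        e2 = mdev_invert(c2)
        np.testing.assert_allclose(e2.gabs[e2.mask], e1.gabs[e1.mask], rtol=1e-12)
        np.testing.assert_allclose(e2.phi[e2.mask], e1.phi[e1.mask], atol=1e-12)

    def test_translation_invariance_of_periodic_field(self):
        # periodic in-plane wave: integer-voxel roll leaves the estimates unchanged
        grid = AcquisitionGrid(shape=(40, 40, 8), voxel_size=(0.002,) * 3,
                               frequencies=(50.0,), n_timesteps=8, n_components=3)
        nz, ny, nx = grid.vol_shape_zyx
        x = np.arange(nx)[None, :]
        kx = 2 * np.pi * 5 / nx  # exactly periodic mode
        sl = np.exp(-1j * kx * x) * np.ones((ny, nx))
        c = np.broadcast_to(sl, (1, 3, nz, ny, nx)).copy()
        f1 = CurlField(grid=grid, c=c, mask=np.ones((nz, ny, nx), bool))
        f2 = CurlField(grid=grid, c=np.roll(c, 7, axis=-1), mask=np.ones((nz, ny, nx), bool))
        e1, e2 = mdev_invert(f1), mdev_invert(f2)
        sel = e1.mask & e2.mask & interior_mask(e1.mask.shape, 1, 8)
        np.testing.assert_allclose(np.roll(e1.gabs, 7, axis=-1)[sel], e2.gabs[sel], rtol=1e-9)

    def test_estimator_variants_agree_on_consistent_data(self):
        c = plane_wave_curl(1000.0 * np.exp(0.7j))
        sel = None
        results = []
        for phi_est in ("pooled-cosine", "regression"):
            for g_est in ("least-squares-through-origin", "ratio"):
                e = mdev_invert(c, InversionConfig(phi_estimator=phi_est, gabs_estimator=g_est))
                if sel is None:
                    sel = e.mask & interior_mask(e.mask.shape)
                results.append((np.median(e.gabs[sel]), np.median(e.phi[sel])))
        g0, p0 = results[0]
        for g, p in results[1:]:
            assert g == pytest.approx(g0, rel=1e-9)
            assert p == pytest.approx(p0, abs=1e-9)

    def test_phi_always_in_0_pi(self):
        rng = np.random.default_rng(11)
        grid = AcquisitionGrid(shape=(12, 12, 6), voxel_size=(0.002,) * 3,
                               frequencies=(30.0, 60.0), n_timesteps=8, n_components=3)
        nz, ny, nx = grid.vol_shape_zyx
        c = rng.normal(size=(2, 3, nz, ny, nx)) + 1j * rng.normal(size=(2, 3, nz, ny, nx))
        e = mdev_invert(CurlField(grid=grid, c=c, mask=np.ones((nz, ny, nx), bool)))
        assert np.all(e.phi[e.mask] >= 0) and np.all(e.phi[e.mask] <= np.pi)

    def test_empty_valid_region_rejected(self):
        grid = AcquisitionGrid(shape=(8, 8, 4), voxel_size=(0.002,) * 3,
                               frequencies=(50.0,), n_timesteps=8, n_components=3)
        c = np.zeros((1, 3, 4, 8, 8), complex)
        field = CurlField(grid=grid, c=c, mask=np.zeros((4, 8, 8), bool))
        with pytest.raises(ValueError, match="empty valid region"):
            mdev_invert(field)

    def test_nan_inside_mask_rejected(self):
        c = plane_wave_curl(1000.0 * np.exp(0.4j), shape_xyz=(12, 12, 6))
        c.c[0, 0, 3, 4, 5] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            mdev_invert(c)


class TestLaplacian:
    @pytest.mark.parametrize("mode, expected_axes", [("2d", (0.0, 1.0, 1.0)), ("3d", (1.0, 1.0, 1.0))])
    def test_quadratic_exact(self, mode, expected_axes):
        # f = az z^2 + ay y^2 + ax x^2 -> Laplacian = 2(az + ay + ax) on the used axes
        h = 0.5
        z, y, x = np.mgrid[0:8, 0:8, 0:8] * h
        vol = 3.0 * z**2 + 2.0 * y**2 + 1.0 * x**2
        lap = discrete_laplacian(vol, (h, h, h), mode)
        wz, wy, wx = expected_axes
        expected = 2 * (3.0 * wz + 2.0 * wy + 1.0 * wx)
        inner = lap[1:-1, 1:-1, 1:-1]
        np.testing.assert_allclose(inner, expected, rtol=1e-12)

    def test_boundary_is_nan(self):
        lap = discrete_laplacian(np.ones((5, 5, 5)), (1, 1, 1), "2d")
        assert np.isnan(lap[:, 0]).all() and np.isnan(lap[:, :, -1]).all()
        assert np.isfinite(lap[:, 1:-1, 1:-1]).all()  # 2D mode keeps z edges


class TestHelmholtzScatter:
    def test_noise_free_points_collinear_through_origin(self):
        gstar = 1100.0 * np.exp(0.8j)
        c = plane_wave_curl(gstar, frequencies=(30.0, 40.0, 50.0, 60.0))
        region = interior_mask(c.mask.shape)
        sc = helmholtz_scatter(c, region)
        assert len(sc.mean_lap) == 12  # 4 frequencies x 3 curl components
        assert abs(sc.slope_through_origin / 1100.0 - 1) < 0.02
        assert abs(sc.slope_with_offset / 1100.0 - 1) < 0.02
        # collinearity: residuals of the through-origin fit are tiny
        resid = sc.mean_rhs - sc.slope_through_origin * sc.mean_lap
        assert np.abs(resid).max() < 0.02 * sc.mean_rhs.max()

    def test_noise_reduces_through_origin_slope(self):
        gstar = 1200.0 * np.exp(0.9j)
        c = plane_wave_curl(gstar, frequencies=(40.0, 50.0, 60.0))
        region = interior_mask(c.mask.shape)
        clean_slope = helmholtz_scatter(c, region).slope_through_origin
        for seed in range(10):
            rng = np.random.default_rng(seed)
            sigma = 0.05 * np.abs(c.c).mean()
            noisy = c.c + sigma * (rng.standard_normal(c.c.shape)
                                   + 1j * rng.standard_normal(c.c.shape))
            cn = CurlField(grid=c.grid, c=noisy, mask=c.mask)
            sc = helmholtz_scatter(cn, region)
            assert sc.slope_through_origin < clean_slope
            assert sc.slope_with_offset > sc.slope_through_origin

    def test_region_outside_mask_rejected(self):
        c = plane_wave_curl(1000.0 * np.exp(0.5j), shape_xyz=(12, 12, 6))
        region = np.zeros(c.mask.shape, bool)
        with pytest.raises(ValueError, match="empty"):
            helmholtz_scatter(c, region)
        c.mask[:] = False
        region[:] = True
        with pytest.raises(ValueError, match="outside"):
            helmholtz_scatter(c, region)


class TestStorageLoss:
    def _pair(self, gabs, phi):
        shape = (2, 2, 2)
        return ElastogramPair(
            gabs=np.full(shape, float(gabs)), phi=np.full(shape, float(phi)),
            mask=np.ones(shape, bool),
        )

    def test_elastic_limit(self):
        gp, gpp = to_storage_loss(self._pair(1.0, 0.0))
        np.testing.assert_allclose(gp, 1.0)
        np.testing.assert_allclose(gpp, 0.0)

    def test_purely_viscous_limit(self):
        gp, gpp = to_storage_loss(self._pair(1.0, np.pi / 2))
        np.testing.assert_allclose(gp, 0.0, atol=1e-15)
        np.testing.assert_allclose(gpp, 1.0)

    def test_white_matter_values(self):
        # |G*| = 1252 Pa, phi = 0.854 (healthy white matter scale)
        gp, gpp = to_storage_loss(self._pair(1252.0, 0.854))
        assert gp.flat[0] == pytest.approx(1252.0 * np.cos(0.854), rel=1e-12)
        assert gpp.flat[0] == pytest.approx(1252.0 * np.sin(0.854), rel=1e-12)
        assert gp.flat[0] == pytest.approx(822.0, abs=1.0)
        assert gpp.flat[0] == pytest.approx(944.5, abs=1.0)
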