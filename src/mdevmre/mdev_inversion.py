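"""Multifrequency dual elasto-visco (MDEV) parameter recovery.

Per voxel, the Helmholtz equation ``G* Delta c* + rho omega^2 c* = 0`` holds
for every curl component ``m`` and drive frequency ``n``.  Writing each
complex curl value as a real 2-vector ``x_mn = (Re c*_mn, Im c*_mn)``, the
Laplacian acts as a scaled rotation by the loss angle, which yields two
independent pooled least-squares estimators:

* loss angle (pooled-cosine form)

      phi_hat = arccos( - sum_mn x_mn . Dx_mn / sum_mn |x_mn| |Dx_mn| )

* modulus magnitude (least squares through the origin of
  ``rho omega^2 |c| = |G*| |Delta c|``)

      |G*|_hat = rho * sum_mn omega_n^2 |c_mn| |Dc_mn| / sum_mn |Dc_mn|^2

Both are zero-degree homogeneous in the field, so global amplitude scale and
the phase-to-displacement factor cancel.  Pooling over components and
frequencies is what stabilizes the inversion at amplitude nulls of any
single-frequency field.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .wavefield_io import CurlField, ElastogramPair

__all__ = [
    "InversionConfig",
    "HelmholtzScatter",
    "discrete_laplacian",
    "mdev_invert",
    "helmholtz_scatter",
    "to_storage_loss",
]


@dataclass(frozen=True)
class InversionConfig:
    """Tunable parameters of the MDEV inversion.

    ``laplacian_mode`` selects the 2D in-plane 5-point stencil (default,
    matching the slice-wise k-space filtering) or the 3D 7-point stencil.
    ``min_denominator`` is the relative threshold (vs. the median pooled
    ``sum |Delta c|``) below which a voxel is masked invalid instead of
    dividing by a near-zero denominator.
    """

    density: float = 1000.0
    laplacian_mode: str = "2d"
    phi_estimator: str = "pooled-cosine"
    gabs_estimator: str = "least-squares-through-origin"
    min_denominator: float = 1e-9

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise ValueError(f"density must be > 0, got {self.density}")
        if self.laplacian_mode not in ("2d", "3d"):
            raise ValueError(f"laplacian_mode must be '2d' or '3d', got {self.laplacian_mode!r}")
        if self.phi_estimator not in ("pooled-cosine", "regression"):
            raise ValueError(f"unknown phi_estimator {self.phi_estimator!r}")
        if self.gabs_estimator not in ("least-squares-through-origin", "ratio"):
            raise ValueError(f"unknown gabs_estimator {self.gabs_estimator!r}")
        if self.min_denominator < 0:
            raise ValueError(f"min_denominator must be >= 0, got {self.min_denominator}")


def discrete_laplacian(vol: np.ndarray, spacing_zyx, mode: str = "2d") -> np.ndarray:
    """Discrete Laplacian of a (z, y, x) volume; boundary ring is NaN.

    ``"2d"`` sums the 3-point second differences along y and x only (5-point
    in-plane stencil); ``"3d"`` adds the z term (7-point stencil).
    """
    dz, dy, dx = spacing_zyx
    axes = {"2d": ((1, dy), (2, dx)), "3d": ((0, dz), (1, dy), (2, dx))}[mode]
    lap = np.full(vol.shape, np.nan, dtype=vol.dtype if np.iscomplexobj(vol) else float)
    interior = [slice(None)] * 3
    for ax, _ in axes:
        interior[ax] = slice(1, -1)
    interior = tuple(interior)
    acc = np.zeros(vol[interior].shape, dtype=complex if np.iscomplexobj(vol) else float)
    for ax, h in axes:
        sl_m = list(interior)
        sl_p = list(interior)
        sl_m[ax] = slice(0, -2)
        sl_p[ax] = slice(2, None)
        acc += (vol[tuple(sl_p)] - 2.0 * vol[interior] + vol[tuple(sl_m)]) / h**2
    lap[interior] = acc
    return lap


def _stencil_structure(mode: str) -> np.ndarray:
    s = np.zeros((3, 3, 3), dtype=bool)
    s[1, 1, 1] = True
    s[1, 1, 0] = s[1, 1, 2] = s[1, 0, 1] = s[1, 2, 1] = True
    if mode == "3d":
        s[0, 1, 1] = s[2, 1, 1] = True
    return s


def _pooled_terms(c: CurlField, cfg: InversionConfig):
    """Per-voxel sums over (component, frequency) of the inversion terms."""
    g = c.grid
    omegas = g.omegas
    vol_shape = g.vol_shape_zyx
    dot = np.zeros(vol_shape)        # sum x . Dx
    dotsq = np.zeros(vol_shape)      # sum (x . Dx) * |x||Dx|   (regression phi)
    magprod = np.zeros(vol_shape)    # sum |x||Dx|
    magprodsq = np.zeros(vol_shape)  # sum (|x||Dx|)^2
    w2_cl = np.zeros(vol_shape)      # sum omega^2 |c||Dc|
    lap2 = np.zeros(vol_shape)       # sum |Dc|^2
    w2_c = np.zeros(vol_shape)       # sum omega^2 |c|
    lap1 = np.zeros(vol_shape)       # sum |Dc|
    lap_finite = np.ones(vol_shape, dtype=bool)

    for fi in range(g.n_frequencies):
        for m in range(c.n_curl_components):
            vol = np.where(c.mask, c.c[fi, m], np.nan)
            lap = discrete_laplacian(vol, g.spacing_zyx, cfg.laplacian_mode)
            finite = np.isfinite(vol) & np.isfinite(lap)
            lap_finite &= finite
            vol0 = np.where(finite, vol, 0.0)
            lap0 = np.where(finite, lap, 0.0)
            d = (vol0 * np.conj(lap0)).real  # x . Dx
            a_c, a_l = np.abs(vol0), np.abs(lap0)
            dot += d
            magprod += a_c * a_l
            dotsq += d * a_c * a_l
            magprodsq += (a_c * a_l) ** 2
            w2_cl += omegas[fi] ** 2 * a_c * a_l
            lap2 += a_l**2
            w2_c += omegas[fi] ** 2 * a_c
            lap1 += a_l
    return dot, dotsq, magprod, magprodsq, w2_cl, lap2, w2_c, lap1, lap_finite


def mdev_invert(c: CurlField, cfg: InversionConfig | None = None) -> ElastogramPair:
    """Voxel-wise MDEV inversion of a (filtered) curl field.

    Returns an :class:`ElastogramPair` with ``|G*|`` in Pa and ``phi`` in
    radians.  Voxels whose Laplacian stencil touches invalid data, or whose
    pooled denominator falls below ``min_denominator`` times the median, are
    masked invalid (NaN in the maps).
    """
    cfg = cfg or InversionConfig()
    if not np.all(np.isfinite(c.c[:, :, c.mask])):
        raise ValueError("curl field contains non-finite values inside its mask")

    dot, dotsq, magprod, magprodsq, w2_cl, lap2, w2_c, lap1, lap_finite = _pooled_terms(c, cfg)

    valid = (
        ndimage.binary_erosion(c.mask, structure=_stencil_structure(cfg.laplacian_mode), border_value=0)
        & lap_finite
    )
    if valid.any() and cfg.min_denominator > 0:
        scale = np.median(lap1[valid])
        valid &= lap1 > cfg.min_denominator * scale
        valid &= magprod > 0
    if not valid.any():
        raise ValueError("MDEV inversion produced an empty valid region")

    with np.errstate(invalid="ignore", divide="ignore"):
        if cfg.phi_estimator == "pooled-cosine":
            cosphi = -dot / magprod
        else:  # regression: slope of (x.Dx) on |x||Dx| through the origin
            cosphi = -dotsq / magprodsq
        phi = np.arccos(np.clip(cosphi, -1.0, 1.0))
        if cfg.gabs_estimator == "least-squares-through-origin":
            gabs = cfg.density * w2_cl / lap2
        else:  # ratio form
            gabs = cfg.density * w2_c / lap1

    gabs = np.where(valid, gabs, np.nan)
    phi = np.where(valid, phi, np.nan)
    meta = dict(c.meta)
    meta["inversion"] = {
        "density": cfg.density,
        "laplacian_mode": cfg.laplacian_mode,
        "phi_estimator": cfg.phi_estimator,
        "gabs_estimator": cfg.gabs_estimator,
    }
    e = ElastogramPair(gabs=gabs, phi=phi, mask=valid, voxel_size=c.grid.voxel_size, meta=meta)
    e.validate()
    return e


@dataclass
class HelmholtzScatter:
    """Region-averaged Helmholtz-equation magnitudes per (frequency, component).

    ``mean_lap`` holds the spatial mean of ``|Delta c|`` and ``mean_rhs`` the
    mean of ``rho omega^2 |c|`` over the same region; the region-level
    modulus is the slope of ``mean_rhs`` against ``mean_lap``.  The
    through-origin fit is the pooled inversion's own convention; the
    offset-allowing fit is the noise diagnostic (noise inflates ``|Delta c|``
    and shows up as a positive abscissa intercept).
    """

    frequencies: np.ndarray
    components: np.ndarray
    mean_lap: np.ndarray
    mean_rhs: np.ndarray
    slope_through_origin: float
    slope_with_offset: float
    intercept: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frequency": self.frequencies,
                "component": self.components,
                "mean_lap": self.mean_lap,
                "mean_rhs": self.mean_rhs,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def helmholtz_scatter(
    c: CurlField, region: np.ndarray, cfg: InversionConfig | None = None
) -> HelmholtzScatter:
    """Region-level Helmholtz scatter diagnostic (one point per (freq, comp))."""
    cfg = cfg or InversionConfig()
    region = np.asarray(region, dtype=bool)
    if region.shape != c.mask.shape:
        raise ValueError(f"region shape {region.shape} does not match volume {c.mask.shape}")
    if not region.any():
        raise ValueError("scatter region is empty")
    if not (region & c.mask).any():
        raise ValueError("scatter region lies entirely outside the curl-field mask")

    g = c.grid
    freqs, comps, mean_lap, mean_rhs = [], [], [], []
    for fi, f in enumerate(g.frequencies):
        omega = 2.0 * np.pi * f
        for m in range(c.n_curl_components):
            vol = np.where(c.mask, c.c[fi, m], np.nan)
            lap = discrete_laplacian(vol, g.spacing_zyx, cfg.laplacian_mode)
            sel = region & np.isfinite(vol) & np.isfinite(lap)
            if not sel.any():
                raise ValueError(
                    f"region has no valid voxels for frequency {f:g} Hz, component {m}"
                )
            freqs.append(f)
            comps.append(m)
            mean_lap.append(float(np.mean(np.abs(lap[sel]))))
            mean_rhs.append(float(cfg.density * omega**2 * np.mean(np.abs(vol[sel]))))

    x = np.asarray(mean_lap)
    y = np.asarray(mean_rhs)
    slope0 = float(np.sum(x * y) / np.sum(x * x))
    slope1, intercept = np.polyfit(x, y, 1)
    return HelmholtzScatter(
        frequencies=np.asarray(freqs),
        components=np.asarray(comps),
        mean_lap=x,
        mean_rhs=y,
        slope_through_origin=slope0,
        slope_with_offset=float(slope1),
        intercept=float(intercept),
    )


def to_storage_loss(e: ElastogramPair) -> tuple[np.ndarray, np.ndarray]:
    """Classical representation: storage modulus G' and loss modulus G''.

    ``G' = |G*| cos(phi)``, ``G'' = |G*| sin(phi)``, voxel-wise; invalid
    voxels are NaN.
    """
    e.validate()
    gp = np.where(e.mask, e.gabs * np.cos(e.phi), np.nan)
    gpp = np.where(e.mask, e.gabs * np.sin(e.phi), np.nan)
    return gp, gpp
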