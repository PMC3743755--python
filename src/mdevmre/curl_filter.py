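"""Curl of the displacement field and k-space Butterworth low-pass filtering.

The curl removes the compressional part of the measured wave field, leaving
the pure shear field that the Helmholtz inversion assumes.  Derivatives are
second-order central differences applied independently to real and imaginary
parts; voxels whose stencil touches the volume edge or a masked voxel are
invalidated rather than one-sided-differenced, so boundary artifacts never
leak into downstream statistics.

The Butterworth filter acts slice-wise in the transverse plane (2D k-space),
with a radially symmetric *amplitude* response

    H(k) = 1 / sqrt(1 + (k / k_c)^(2 * order)),

so the gain at the cutoff ``k_c`` is exactly 1/sqrt(2) (half power).  The
conventional cutoff for brain data is 100 cycles/m.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .wavefield_io import ComplexWaveField, CurlField

__all__ = ["compute_curl", "butterworth_lowpass", "butterworth_gain"]


def compute_curl(field: ComplexWaveField) -> CurlField:
    """Curl c = rot(u) of a three-component displacement field.

    Components of ``u`` are ordered (x, y, z); the curl components are
    returned in the same order.  The output mask is the input mask eroded by
    the one-voxel stencil radius on every axis.
    """
    g = field.grid
    if g.n_components < 3:
        raise ValueError(
            f"curl requires all 3 motion components, got {g.n_components}"
        )
    dz, dy, dx = g.spacing_zyx
    nz, ny, nx = g.vol_shape_zyx
    if min(nz, ny, nx) < 3:
        raise ValueError(f"volume {g.vol_shape_zyx} too small for a central-difference stencil")

    c = np.empty_like(field.u)
    for fi in range(g.n_frequencies):
        ux, uy, uz = (np.where(field.mask, field.u[fi, m], np.nan) for m in range(3))
        # gradient axes are (z, y, x)
        duz_dz, duz_dy, duz_dx = np.gradient(uz, dz, dy, dx)
        duy_dz, duy_dy, duy_dx = np.gradient(uy, dz, dy, dx)
        dux_dz, dux_dy, dux_dx = np.gradient(ux, dz, dy, dx)
        c[fi, 0] = duz_dy - duy_dz
        c[fi, 1] = dux_dz - duz_dx
        c[fi, 2] = duy_dx - dux_dy

    # erode by the stencil: any voxel adjacent (6-neighborhood) to an invalid
    # voxel, or on the volume edge, is invalid
    structure = ndimage.generate_binary_structure(3, 1)
    mask = ndimage.binary_erosion(field.mask, structure=structure, border_value=0)
    c[:, :, ~mask] = np.nan
    out = CurlField(grid=g, c=c, mask=mask, meta=dict(field.meta))
    out.validate()
    return out


def butterworth_gain(k: np.ndarray, cutoff: float, order: int) -> np.ndarray:
    """Radial Butterworth amplitude response H(k)."""
    return 1.0 / np.sqrt(1.0 + (np.asarray(k, dtype=float) / cutoff) ** (2 * order))


def butterworth_lowpass(
    curl: CurlField,
    cutoff: float = 100.0,
    order: int = 3,
    mode: str = "2d",
    pad: str | None = None,
) -> CurlField:
    """Low-pass the curl field in k-space with a Butterworth amplitude kernel.

    Parameters
    ----------
    cutoff
        Half-power radial cutoff in cycles per meter (spatial frequency).
    order
        Butterworth order; higher is a steeper roll-off.
    mode
        ``"2d"`` filters each transverse slice (the standard processing);
        ``"3d"`` filters the full volume.
    pad
        ``None`` uses the plain (periodic) FFT; ``"mirror"`` reflects each
        slice before transforming to suppress wrap-around ringing.
    """
    if cutoff <= 0:
        raise ValueError(f"cutoff must be > 0, got {cutoff}")
    if order < 1:
        raise ValueError(f"order must be >= 1, got {order}")
    if mode not in ("2d", "3d"):
        raise ValueError(f"mode must be '2d' or '3d', got {mode!r}")
    if pad not in (None, "mirror"):
        raise ValueError(f"pad must be None or 'mirror', got {pad!r}")
    g = curl.grid
    nz, ny, nx = g.vol_shape_zyx
    if ny < 4 or nx < 4:
        raise ValueError(f"in-plane size {(ny, nx)} smaller than 4x4 cannot be filtered")
    dx, dy, dz = g.voxel_size

    data = np.where(np.isfinite(curl.c), curl.c, 0.0)
    if mode == "2d":
        if pad == "mirror":
            data = np.pad(data, [(0, 0)] * 3 + [(ny, ny), (nx, nx)], mode="reflect")
        py, px = data.shape[-2:]
        ky = np.fft.fftfreq(py, d=dy)[:, None]
        kx = np.fft.fftfreq(px, d=dx)[None, :]
        h = butterworth_gain(np.sqrt(kx**2 + ky**2), cutoff, order)
        filt = np.fft.ifft2(np.fft.fft2(data, axes=(-2, -1)) * h, axes=(-2, -1))
        if pad == "mirror":
            filt = filt[..., ny : 2 * ny, nx : 2 * nx]
    else:
        if pad == "mirror":
            data = np.pad(data, [(0, 0)] * 2 + [(nz, nz), (ny, ny), (nx, nx)], mode="reflect")
        pz, py, px = data.shape[-3:]
        kz = np.fft.fftfreq(pz, d=dz)[:, None, None]
        ky = np.fft.fftfreq(py, d=dy)[None, :, None]
        kx = np.fft.fftfreq(px, d=dx)[None, None, :]
        h = butterworth_gain(np.sqrt(kx**2 + ky**2 + kz**2), cutoff, order)
        filt = np.fft.ifftn(np.fft.fftn(data, axes=(-3, -2, -1)) * h, axes=(-3, -2, -1))
        if pad == "mirror":
            filt = filt[..., nz : 2 * nz, ny : 2 * ny, nx : 2 * nx]

    filt = np.asarray(filt)
    filt[:, :, ~curl.mask] = np.nan
    meta = dict(curl.meta)
    meta["butterworth"] = {"cutoff_per_m": cutoff, "order": order, "mode": mode, "pad": pad}
    return CurlField(grid=g, c=filt, mask=curl.mask.copy(), meta=meta)
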