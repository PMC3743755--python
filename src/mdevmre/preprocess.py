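"""Phase-image preprocessing: unwrapping, smoothing, scaling, harmonic extraction.

The chain mirrors standard multifrequency MRE processing:

1. spatial phase unwrapping of each (frequency, component, timestep) volume,
2. 3x3x3 Gaussian smoothing,
3. scaling from radians to displacement units,
4. temporal Fourier transform over the vibration cycle, keeping the complex
   amplitude at the drive frequency.

Time convention
---------------
The package fixes ``u(t) = Re[u* exp(+i omega t)]`` (``TIME_SIGN = +1``).
Every phase-sensitive quantity — the sign of the loss angle, the decay branch
of the shear wavenumber — follows from this single constant; changing it
anywhere else is a bug.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage.restoration import unwrap_phase as _unwrap_skimage

from .wavefield_io import AcquisitionGrid, ComplexWaveField, RawPhaseSeries

__all__ = [
    "TIME_SIGN",
    "unwrap_phase",
    "smooth_gaussian",
    "scale_to_displacement",
    "temporal_harmonic",
    "gaussian_kernel_3x3x3",
]

#: sign of the complex exponent in u(t) = Re[u* exp(TIME_SIGN * i * omega * t)]
TIME_SIGN: int = +1


def unwrap_phase(series: RawPhaseSeries, backend: str = "slice2d") -> RawPhaseSeries:
    """Spatially unwrap each (frequency, component, timestep) volume.

    Backends
    --------
    ``slice2d``
        Reliability-sorted (Herraez) 2D unwrapping applied per transverse
        slice.  Per-slice global offsets are irrelevant downstream because
        the inversion consumes spatial derivatives.
    ``volume3d``
        The same algorithm run on the full 3D volume.

    The only guaranteed contract is congruence: output minus input is an
    integer multiple of 2*pi at every voxel.
    """
    if not series.wrapped:
        raise ValueError("unwrap_phase expects a wrapped series (series.wrapped is True)")
    if backend not in ("slice2d", "volume3d"):
        raise ValueError(f"unknown unwrap backend {backend!r}")
    g = series.grid
    out = np.empty_like(series.phase)
    for fi in range(g.n_frequencies):
        for m in range(g.n_components):
            for t in range(g.n_timesteps):
                vol = series.phase[fi, m, t]
                if backend == "volume3d":
                    out[fi, m, t] = _unwrap_volume(vol, (fi, m, t))
                else:
                    for z in range(vol.shape[0]):
                        out[fi, m, t, z] = _unwrap_slice(vol[z], (fi, m, t, z))
    return RawPhaseSeries(grid=g, phase=out, wrapped=False, meta=dict(series.meta))


def _unwrap_slice(sl: np.ndarray, index: tuple) -> np.ndarray:
    bad = ~np.isfinite(sl)
    if bad.all():
        raise ValueError(f"all-NaN phase slice at (freq, comp, timestep, z) = {index}")
    if bad.any():
        res = _unwrap_skimage(np.ma.array(sl, mask=bad))
        return np.ma.filled(res, np.nan)
    return np.asarray(_unwrap_skimage(sl))


def _unwrap_volume(vol: np.ndarray, index: tuple) -> np.ndarray:
    bad = ~np.isfinite(vol)
    if bad.all():
        raise ValueError(f"all-NaN phase volume at (freq, comp, timestep) = {index}")
    if bad.any():
        res = _unwrap_skimage(np.ma.array(vol, mask=bad))
        return np.ma.filled(res, np.nan)
    return np.asarray(_unwrap_skimage(vol))


def gaussian_kernel_3x3x3(sigma: float = 0.65) -> np.ndarray:
    """Normalized 3x3x3 truncated-Gaussian kernel (sigma in voxels)."""
    if sigma <= 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    w = np.exp(-0.5 * (np.arange(-1, 2) / sigma) ** 2)
    k = np.einsum("i,j,k->ijk", w, w, w)
    return k / k.sum()


def _smooth_volume(vol: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    if any(s < 3 for s in vol.shape):
        raise ValueError(f"volume shape {vol.shape} is smaller than the 3x3x3 smoothing kernel")
    if np.iscomplexobj(vol):
        return ndimage.convolve(vol.real, kernel, mode="nearest") + 1j * ndimage.convolve(
            vol.imag, kernel, mode="nearest"
        )
    return ndimage.convolve(vol, kernel, mode="nearest")


def smooth_gaussian(obj, sigma: float = 0.65):
    """3D Gaussian smoothing (3-voxel cubic kernel) of every volume in ``obj``.

    Accepts a :class:`RawPhaseSeries` (must be unwrapped) or a
    :class:`ComplexWaveField`; returns the same type.  The kernel weights sum
    to one, so constant volumes pass through unchanged.
    """
    kernel = gaussian_kernel_3x3x3(sigma)
    if isinstance(obj, RawPhaseSeries):
        if obj.wrapped:
            raise ValueError("smoothing must be applied to unwrapped phase")
        g = obj.grid
        out = np.empty_like(obj.phase)
        for fi in range(g.n_frequencies):
            for m in range(g.n_components):
                for t in range(g.n_timesteps):
                    out[fi, m, t] = _smooth_volume(obj.phase[fi, m, t], kernel)
        return RawPhaseSeries(grid=g, phase=out, wrapped=False, meta=dict(obj.meta))
    if isinstance(obj, ComplexWaveField):
        g = obj.grid
        out = np.empty_like(obj.u)
        for fi in range(g.n_frequencies):
            for m in range(g.n_components):
                out[fi, m] = _smooth_volume(obj.u[fi, m], kernel)
        mask = obj.mask & np.all(np.isfinite(out), axis=(0, 1))
        return ComplexWaveField(grid=g, u=out, mask=mask, meta=dict(obj.meta))
    raise TypeError(f"cannot smooth object of type {type(obj).__name__}")


def scale_to_displacement(obj, factor: float):
    """Multiply every voxel by ``factor`` (radians-to-displacement conversion).

    The MDEV estimators are zero-degree homogeneous in the field, so the maps
    do not depend on this factor; it is kept for dimensional bookkeeping and
    recorded in ``meta['scale_factor']``.
    """
    if not np.isfinite(factor) or factor <= 0:
        raise ValueError(f"scale factor must be a positive finite number, got {factor}")
    if isinstance(obj, RawPhaseSeries):
        out = RawPhaseSeries(
            grid=obj.grid, phase=obj.phase * factor, wrapped=obj.wrapped, meta=dict(obj.meta)
        )
    elif isinstance(obj, ComplexWaveField):
        out = ComplexWaveField(grid=obj.grid, u=obj.u * factor, mask=obj.mask, meta=dict(obj.meta))
    else:
        raise TypeError(f"cannot scale object of type {type(obj).__name__}")
    out.meta["scale_factor"] = float(factor) * float(obj.meta.get("scale_factor", 1.0))
    return out


def temporal_harmonic(series: RawPhaseSeries) -> ComplexWaveField:
    """Complex amplitude at the drive frequency from the sampled cycle.

    With samples ``s_t, t = 0..T-1`` over one vibration period and the
    package convention ``s_t = Re[u* exp(+2 pi i t / T)]``, the fundamental
    DFT bin gives ``u* = (2 / T) * sum_t s_t exp(-2 pi i t / T)``.  A pure
    cosine ``A cos(2 pi t / T)`` therefore returns exactly ``A + 0i``.
    """
    if series.wrapped:
        raise ValueError("temporal_harmonic expects unwrapped phase")
    g = series.grid
    if g.n_timesteps < 4:
        raise ValueError(f"need at least 4 timesteps, got {g.n_timesteps}")
    t = np.arange(g.n_timesteps)
    basis = np.exp(-TIME_SIGN * 2j * np.pi * t / g.n_timesteps)
    u = (2.0 / g.n_timesteps) * np.einsum("t,fmtzyx->fmzyx", basis, series.phase)
    mask = np.all(np.isfinite(u), axis=(0, 1))
    u = np.where(np.isfinite(u), u, np.nan)
    meta = dict(series.meta)
    return ComplexWaveField(grid=g, u=u, mask=mask, meta=meta)
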