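"""Synthetic viscoelastic wave-field phantoms with known ground truth.

Three generators make the full reconstruction chain verifiable without any
in vivo data:

* :func:`make_plane_wave_field` — exact time-harmonic plane shear waves in a
  homogeneous medium (the closed-form solutions of the Helmholtz equation);
* :func:`solve_helmholtz_2d` — a sparse finite-difference solve of the
  heterogeneous scalar Helmholtz equation on one slice, used as an
  independent oracle for inclusion phantoms;
* :func:`synthesize_raw_phase` — converts a complex field into the raw
  wrapped-phase acquisition (components x frequencies x timesteps) with
  optional Gaussian phase noise, emulating the scanner export of a
  multifrequency exam (2 mm isotropic voxels, 30 slices, 3 encoding
  directions, 8 samples per cycle, 30-60 Hz drives).

Wavenumber branch
-----------------
Under the package convention ``u(t) = Re[u* exp(+i omega t)]`` a wave
traveling along ``+s`` is ``u* = A exp(-i k s)`` with ``k = omega *
sqrt(rho / G*)`` taken on the principal branch.  For ``0 <= arg G* < pi``
this gives ``Re k > 0`` and ``Im k <= 0``, i.e. the amplitude decays along
the propagation direction — the physical branch.  A sign error here flips
the recovered loss angle, which is why the branch lives in one named,
unit-tested function.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import spsolve

from .preprocess import TIME_SIGN
from .wavefield_io import AcquisitionGrid, ComplexWaveField, RawPhaseSeries, wrap_phase

__all__ = [
    "WaveSource",
    "PhantomSpec",
    "shear_wavenumber",
    "make_plane_wave_field",
    "solve_helmholtz_2d",
    "synthesize_raw_phase",
    "simulate_dataset",
    "default_brain_spec",
]


def shear_wavenumber(gstar: complex, density: float, omega: float) -> complex:
    """Complex shear wavenumber ``k = omega sqrt(rho / G*)``, decaying branch.

    Principal square root; with ``0 <= arg G* < pi`` the result has
    ``Re k > 0, Im k <= 0``, so ``exp(-i k s)`` decays for growing ``s``
    under the ``exp(+i omega t)`` time convention.
    """
    gstar = complex(gstar)
    if abs(gstar) <= 0:
        raise ValueError("G* must be nonzero")
    arg = np.angle(gstar)
    if arg < -1e-12 or arg >= np.pi:
        raise ValueError(f"arg(G*) must lie in [0, pi), got {arg}")
    k = omega * np.sqrt(density / gstar)
    assert k.real > 0 and k.imag <= 1e-15, "wavenumber branch violated"
    return k


@dataclass(frozen=True)
class WaveSource:
    """One plane-wave source: unit propagation direction, transverse unit
    polarization, complex amplitude (meters)."""

    direction: tuple[float, float, float]
    polarization: tuple[float, float, float]
    amplitude: complex = 1.0

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, dtype=float)
        p = np.asarray(self.polarization, dtype=float)
        if np.linalg.norm(d) == 0 or np.linalg.norm(p) == 0:
            raise ValueError("direction and polarization must be nonzero vectors")
        d = d / np.linalg.norm(d)
        p = p / np.linalg.norm(p)
        if abs(np.dot(d, p)) > 1e-8:
            raise ValueError(
                f"polarization must be transverse (perpendicular to propagation); "
                f"dot product is {np.dot(d, p):.3g}"
            )
        object.__setattr__(self, "direction", tuple(d))
        object.__setattr__(self, "polarization", tuple(p))


@dataclass
class PhantomSpec:
    """Ground truth and acquisition settings of one synthetic exam.

    ``gstar`` may be a complex scalar (homogeneous) or a complex volume
    ``(z, y, x)``.  ``amplitude_exponent`` scales the source amplitude with
    drive frequency as ``(f / f_min) ** amplitude_exponent``; the default -2
    (constant drive acceleration) reproduces the empirically larger wave
    amplitudes at low frequencies.
    """

    grid: AcquisitionGrid
    gstar: complex | np.ndarray = 1200.0 * np.exp(0.9j)
    sources: tuple[WaveSource, ...] = ()
    noise_sigma: float = 0.2
    scale_factor: float = 5.0e4
    amplitude_exponent: float = -2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError(f"noise_sigma must be >= 0, got {self.noise_sigma}")
        if self.scale_factor <= 0:
            raise ValueError(f"scale_factor must be > 0, got {self.scale_factor}")
        if not self.sources:
            self.sources = default_sources()
        g = np.asarray(self.gstar)
        if np.any(np.abs(g) <= 0):
            raise ValueError("|G*| must be > 0 everywhere")
        ang = np.angle(g)
        if np.any(ang < -1e-12) or np.any(ang >= np.pi):
            raise ValueError("arg(G*) must lie in [0, pi) everywhere")

    @property
    def is_homogeneous(self) -> bool:
        g = np.asarray(self.gstar)
        return g.ndim == 0 or np.all(g == g.flat[0])


def default_sources(amplitude: float = 30e-6) -> tuple[WaveSource, ...]:
    """Three oblique plane-wave sources, mimicking skull-borne
    multidirectional excitation; amplitude in meters (default 30 um)."""
    raw = [
        ((1.0, 1.0, 0.3), (-0.3, 0.3, 0.0), amplitude),
        ((-0.6, 1.0, 0.4), (1.0, 0.6, 0.0), 0.8 * amplitude * np.exp(0.7j)),
        ((0.2, -1.0, 0.5), (1.0, 0.2, 0.0), 0.6 * amplitude * np.exp(-1.1j)),
    ]
    out = []
    for d, p, a in raw:
        d = np.asarray(d) / np.linalg.norm(d)
        p = np.asarray(p, dtype=float)
        p -= np.dot(p, d) * d
        p /= np.linalg.norm(p)
        out.append(WaveSource(tuple(d), tuple(p), a))
    return tuple(out)


def default_brain_spec(seed: int = 0, **overrides) -> PhantomSpec:
    """Full-size in-silico subject: 96x88x30 voxels at 2 mm, 30-60 Hz,
    3 components, 8 timesteps, brain-like G* = 1.2 kPa * exp(0.9 i)."""
    grid = AcquisitionGrid(
        shape=(96, 88, 30),
        voxel_size=(0.002, 0.002, 0.002),
        frequencies=(30.0, 40.0, 50.0, 60.0),
        n_timesteps=8,
        n_components=3,
        density=1000.0,
    )
    kwargs = dict(grid=grid, seed=seed)
    kwargs.update(overrides)
    return PhantomSpec(**kwargs)


def _coords(grid: AcquisitionGrid) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    nz, ny, nx = grid.vol_shape_zyx
    dx, dy, dz = grid.voxel_size
    z = np.arange(nz)[:, None, None] * dz
    y = np.arange(ny)[None, :, None] * dy
    x = np.arange(nx)[None, None, :] * dx
    return z, y, x


def make_plane_wave_field(spec: PhantomSpec) -> tuple[ComplexWaveField, dict]:
    """Superpose plane shear waves in a homogeneous medium.

    Returns the complex displacement field (per frequency and component) and
    a ground-truth dict with ``gabs`` (Pa), ``phi`` (rad) and the complex
    wavenumber per frequency.
    """
    if not spec.is_homogeneous:
        raise ValueError("plane-wave phantom requires homogeneous G*; use solve_helmholtz_2d")
    g = spec.grid
    gstar = complex(np.asarray(spec.gstar).flat[0])
    z, y, x = _coords(g)
    f_min = g.frequencies[0]
    u = np.zeros((g.n_frequencies, g.n_components, *g.vol_shape_zyx), dtype=complex)
    ks = []
    for fi, f in enumerate(g.frequencies):
        omega = 2.0 * np.pi * f
        k = shear_wavenumber(gstar, g.density, omega)
        ks.append(k)
        amp_scale = (f / f_min) ** spec.amplitude_exponent
        for src in spec.sources:
            dxs, dys, dzs = src.direction
            s = dxs * x + dys * y + dzs * z
            # reference the propagation distance to the wave's entry point so
            # s >= 0 everywhere and the lossy wave decays (never grows)
            s = s - (min(dxs * x.max(), 0.0) + min(dys * y.max(), 0.0) + min(dzs * z.max(), 0.0))
            carrier = (src.amplitude * amp_scale) * np.exp(-1j * k * s)
            for m in range(g.n_components):
                u[fi, m] += src.polarization[m] * carrier
    mask = np.ones(g.vol_shape_zyx, dtype=bool)
    truth = {
        "gabs": np.full(g.vol_shape_zyx, abs(gstar)),
        "phi": np.full(g.vol_shape_zyx, float(np.angle(gstar))),
        "gstar": gstar,
        "wavenumbers": np.asarray(ks),
    }
    return ComplexWaveField(grid=g, u=u, mask=mask, meta={"phantom": "plane-wave"}), truth


def solve_helmholtz_2d(
    gstar_map: np.ndarray,
    voxel_size: tuple[float, float],
    density: float,
    frequency: float,
    boundary: np.ndarray,
) -> np.ndarray:
    """Solve ``rho omega^2 u + div(G* grad u) = 0`` on one slice.

    Heterogeneous-coefficient 5-point discretization with face-averaged
    ``G*`` and Dirichlet data taken from ``boundary`` on the outer ring.
    Returns the complex field ``(ny, nx)``.
    """
    gmap = np.asarray(gstar_map, dtype=complex)
    if gmap.ndim != 2:
        raise ValueError(f"G* map must be 2D, got shape {gmap.shape}")
    ny, nx = gmap.shape
    if ny < 5 or nx < 5:
        raise ValueError(f"grid {gmap.shape} too small for a 2D Helmholtz solve")
    boundary = np.asarray(boundary, dtype=complex)
    if boundary.shape != gmap.shape:
        raise ValueError(f"boundary array shape {boundary.shape} must match G* map {gmap.shape}")
    dy, dx = float(voxel_size[1]), float(voxel_size[0])
    omega = 2.0 * np.pi * frequency
    n = ny * nx

    def idx(i, j):
        return i * nx + j

    rows, cols, vals = [], [], []
    rhs = np.zeros(n, dtype=complex)
    for i in range(ny):
        for j in range(nx):
            p = idx(i, j)
            if i in (0, ny - 1) or j in (0, nx - 1):
                rows.append(p)
                cols.append(p)
                vals.append(1.0)
                rhs[p] = boundary[i, j]
                continue
            diag = density * omega**2
            for (ii, jj, h) in ((i - 1, j, dy), (i + 1, j, dy), (i, j - 1, dx), (i, j + 1, dx)):
                gf = 0.5 * (gmap[i, j] + gmap[ii, jj])
                rows.append(p)
                cols.append(idx(ii, jj))
                vals.append(gf / h**2)
                diag -= gf / h**2
            rows.append(p)
            cols.append(p)
            vals.append(diag)
    a = sparse.csr_matrix((vals, (rows, cols)), shape=(n, n), dtype=complex)
    try:
        u = spsolve(a, rhs)
    except Exception as exc:  # pragma: no cover - solver failure path
        raise RuntimeError(
            f"Helmholtz solve failed at {frequency:g} Hz on a {ny}x{nx} grid: {exc}"
        ) from exc
    if not np.all(np.isfinite(u)):
        raise RuntimeError(
            f"singular Helmholtz system at {frequency:g} Hz on a {ny}x{nx} grid"
        )
    return u.reshape(ny, nx)


def synthesize_raw_phase(field: ComplexWaveField, spec: PhantomSpec) -> RawPhaseSeries:
    """Raw wrapped-phase acquisition of a complex field.

    ``phase[t] = wrap(scale_factor * Re[u* exp(+2 pi i t / T)] + noise)``
    with i.i.d. Gaussian noise (sigma in rad) per voxel and timestep,
    deterministic for a given ``spec.seed``.
    """
    g = field.grid
    rng = np.random.default_rng(spec.seed)
    t = np.arange(g.n_timesteps)
    carrier = np.exp(TIME_SIGN * 2j * np.pi * t / g.n_timesteps)  # (T,)
    # u: (F, M, z, y, x) -> phase (F, M, T, z, y, x)
    clean = spec.scale_factor * (field.u[:, :, None] * carrier[None, None, :, None, None, None]).real
    if spec.noise_sigma > 0:
        clean = clean + rng.normal(0.0, spec.noise_sigma, size=clean.shape)
    series = RawPhaseSeries(grid=g, phase=wrap_phase(clean), wrapped=True,
                            meta={"scale_factor": spec.scale_factor, "seed": spec.seed,
                                  "noise_sigma": spec.noise_sigma})
    return series


def simulate_dataset(spec: PhantomSpec) -> tuple[RawPhaseSeries, dict]:
    """Plane-wave phantom -> raw wrapped phase, plus the ground-truth dict."""
    field, truth = make_plane_wave_field(spec)
    series = synthesize_raw_phase(field, spec)
    truth = dict(truth)
    truth["field"] = field
    return series, truth
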