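"""Domain containers and NIfTI-based I/O for multifrequency MRE data.

Axis convention (fixed package-wide, asserted by the containers):

* raw phase series:   ``[frequency][component][timestep][z][y][x]``
* complex fields:     ``[frequency][component][z][y][x]``
* scalar maps/masks:  ``[z][y][x]``

On disk, each (frequency, component) pair is one NIfTI-1 file holding a 4D
``(x, y, z, timestep)`` volume, with a JSON sidecar (``series.json``)
carrying the acquisition metadata.  This mirrors scanner-export granularity
and keeps individual files small.  Invalid voxels are stored as NaN *and*
flagged in an explicit mask volume, because NaN alone becomes ambiguous
after filtering.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "AcquisitionGrid",
    "RawPhaseSeries",
    "ComplexWaveField",
    "CurlField",
    "ElastogramPair",
    "phase_filename",
    "read_phase_series",
    "write_phase_series",
    "read_elastogram",
    "write_elastogram",
    "read_labeled_mask",
    "write_labeled_mask",
]


@dataclass(frozen=True)
class AcquisitionGrid:
    """Geometry and acquisition parameters of one multifrequency MRE exam.

    Parameters
    ----------
    shape
        Voxel counts ``(nx, ny, nz)``.
    voxel_size
        Physical voxel edge lengths in **meters**, ``(dx, dy, dz)``.
    frequencies
        Drive (vibration) frequencies in Hz, strictly increasing.
    n_timesteps
        Samples per vibration cycle (wave-phase offsets), at least 4.
    n_components
        Motion-encoding directions (1-3).
    density
        Tissue density in kg/m^3 (brain is conventionally 1000).
    """

    shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float]
    frequencies: tuple[float, ...]
    n_timesteps: int = 8
    n_components: int = 3
    density: float = 1000.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "voxel_size", tuple(float(v) for v in self.voxel_size))
        object.__setattr__(self, "frequencies", tuple(float(f) for f in self.frequencies))
        if len(self.shape) != 3 or any(n < 1 for n in self.shape):
            raise ValueError(f"shape must be three positive voxel counts, got {self.shape}")
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel_size components must be > 0, got {self.voxel_size}")
        if not self.frequencies or any(f <= 0 for f in self.frequencies):
            raise ValueError("frequencies must be strictly positive")
        if any(b <= a for a, b in zip(self.frequencies, self.frequencies[1:])):
            raise ValueError(f"frequencies must be strictly increasing, got {self.frequencies}")
        if self.n_timesteps < 4:
            raise ValueError(f"n_timesteps must be >= 4, got {self.n_timesteps}")
        if self.n_components not in (1, 2, 3):
            raise ValueError(f"n_components must be 1, 2 or 3, got {self.n_components}")
        if self.density <= 0:
            raise ValueError(f"density must be > 0, got {self.density}")

    @property
    def n_frequencies(self) -> int:
        return len(self.frequencies)

    @property
    def omegas(self) -> np.ndarray:
        """Angular drive frequencies (rad/s)."""
        return 2.0 * np.pi * np.asarray(self.frequencies)

    @property
    def vol_shape_zyx(self) -> tuple[int, int, int]:
        nx, ny, nz = self.shape
        return (nz, ny, nx)

    @property
    def spacing_zyx(self) -> tuple[float, float, float]:
        dx, dy, dz = self.voxel_size
        return (dz, dy, dx)

    def to_dict(self) -> dict:
        return {
            "shape": list(self.shape),
            "voxel_size_m": list(self.voxel_size),
            "frequencies_hz": list(self.frequencies),
            "n_timesteps": self.n_timesteps,
            "n_components": self.n_components,
            "density_kg_m3": self.density,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionGrid":
        return cls(
            shape=tuple(d["shape"]),
            voxel_size=tuple(d["voxel_size_m"]),
            frequencies=tuple(d["frequencies_hz"]),
            n_timesteps=int(d["n_timesteps"]),
            n_components=int(d["n_components"]),
            density=float(d["density_kg_m3"]),
        )


def _check_shape(name: str, arr: np.ndarray, expected: tuple[int, ...]) -> None:
    if arr.shape != expected:
        for axis, (got, want) in enumerate(zip(arr.shape, expected)):
            if got != want:
                raise ValueError(
                    f"{name}: axis {axis} has length {got}, expected {want} "
                    f"(full shape {arr.shape} vs {expected})"
                )
        raise ValueError(f"{name}: shape {arr.shape} does not match expected {expected}")


@dataclass
class RawPhaseSeries:
    """Wrapped or unwrapped MRI phase, ``[freq][comp][timestep][z][y][x]`` in rad."""

    grid: AcquisitionGrid
    phase: np.ndarray
    wrapped: bool = True
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.phase = np.asarray(self.phase, dtype=float)
        g = self.grid
        _check_shape(
            "RawPhaseSeries.phase",
            self.phase,
            (g.n_frequencies, g.n_components, g.n_timesteps, *g.vol_shape_zyx),
        )

    def validate(self) -> None:
        if not np.all(np.isfinite(self.phase)):
            raise ValueError("RawPhaseSeries contains non-finite phase values")
        if self.wrapped:
            lo, hi = self.phase.min(), self.phase.max()
            if lo <= -np.pi - 1e-12 or hi > np.pi + 1e-12:
                raise ValueError(
                    f"wrapped phase must lie in (-pi, pi], found range [{lo}, {hi}]"
                )


@dataclass
class ComplexWaveField:
    """Complex harmonic displacement field u*, ``[freq][comp][z][y][x]``.

    The global amplitude scale is arbitrary: every downstream estimator is
    zero-degree homogeneous in the field.
    """

    grid: AcquisitionGrid
    u: np.ndarray
    mask: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=complex)
        self.mask = np.asarray(self.mask, dtype=bool)
        g = self.grid
        _check_shape("ComplexWaveField.u", self.u, (g.n_frequencies, g.n_components, *g.vol_shape_zyx))
        _check_shape("ComplexWaveField.mask", self.mask, g.vol_shape_zyx)

    def validate(self) -> None:
        if not np.all(np.isfinite(self.u[:, :, self.mask])):
            raise ValueError("ComplexWaveField has non-finite values inside the mask")


@dataclass
class CurlField:
    """Complex curl components c* of the displacement field (shear-only part)."""

    grid: AcquisitionGrid
    c: np.ndarray
    mask: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.c = np.asarray(self.c, dtype=complex)
        self.mask = np.asarray(self.mask, dtype=bool)
        g = self.grid
        if self.c.ndim != 5 or self.c.shape[0] != g.n_frequencies or self.c.shape[2:] != g.vol_shape_zyx:
            raise ValueError(
                f"CurlField.c shape {self.c.shape} inconsistent with grid "
                f"({g.n_frequencies} frequencies, volume {g.vol_shape_zyx})"
            )
        _check_shape("CurlField.mask", self.mask, g.vol_shape_zyx)

    @property
    def n_curl_components(self) -> int:
        return self.c.shape[1]

    def validate(self) -> None:
        if not np.all(np.isfinite(self.c[:, :, self.mask])):
            raise ValueError("CurlField has non-finite values inside the mask")


@dataclass
class ElastogramPair:
    """Voxel maps of |G*| (Pa) and loss angle phi (rad), plus validity mask."""

    gabs: np.ndarray
    phi: np.ndarray
    mask: np.ndarray
    voxel_size: tuple[float, float, float] = (0.002, 0.002, 0.002)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.gabs = np.asarray(self.gabs, dtype=float)
        self.phi = np.asarray(self.phi, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if not (self.gabs.shape == self.phi.shape == self.mask.shape):
            raise ValueError(
                f"elastogram shapes disagree: |G*| {self.gabs.shape}, "
                f"phi {self.phi.shape}, mask {self.mask.shape}"
            )

    def validate(self) -> None:
        g, p = self.gabs[self.mask], self.phi[self.mask]
        if not np.all(np.isfinite(g)) or not np.all(np.isfinite(p)):
            raise ValueError("elastogram has non-finite values inside the validity mask")
        if g.size and g.min() < 0:
            raise ValueError(f"|G*| must be >= 0 on the mask, min is {g.min()}")
        if p.size and (p.min() < -1e-12 or p.max() > np.pi + 1e-12):
            raise ValueError(f"phi must lie in [0, pi] on the mask, range [{p.min()}, {p.max()}]")


# ---------------------------------------------------------------------------
# NIfTI plumbing


def _affine_mm(voxel_size_m: tuple[float, float, float]) -> np.ndarray:
    """Diagonal affine with voxel dimensions in millimeters (NIfTI convention)."""
    return np.diag([voxel_size_m[0] * 1e3, voxel_size_m[1] * 1e3, voxel_size_m[2] * 1e3, 1.0])


def _save_nifti(data_xyz: np.ndarray, voxel_size_m, path: Path) -> None:
    img = nib.Nifti1Image(np.asarray(data_xyz), _affine_mm(tuple(voxel_size_m)))
    zooms = [v * 1e3 for v in voxel_size_m]
    if data_xyz.ndim == 4:
        zooms.append(1.0)
    img.header.set_zooms(zooms)
    nib.save(img, str(path))


def _load_nifti(path: Path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj)


def _zyx_to_xyz(vol_zyx: np.ndarray) -> np.ndarray:
    return np.transpose(vol_zyx, (2, 1, 0))


def _xyz_to_zyx(vol_xyz: np.ndarray) -> np.ndarray:
    return np.transpose(vol_xyz, (2, 1, 0))


def phase_filename(freq_hz: float, component: int) -> str:
    """Canonical on-disk name for one (frequency, component) phase volume."""
    return f"phase_f{freq_hz:g}Hz_c{component}.nii"


def write_phase_series(series: RawPhaseSeries, out_dir: str | Path) -> list[Path]:
    """Write a phase series as one 4D NIfTI per (frequency, component).

    Each file holds ``(x, y, z, timestep)``; ``series.json`` carries the grid
    metadata plus the ``wrapped`` flag and any entries in ``series.meta``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    g = series.grid
    paths: list[Path] = []
    for fi, f in enumerate(g.frequencies):
        for m in range(g.n_components):
            # [t][z][y][x] -> (x, y, z, t)
            vol = np.transpose(series.phase[fi, m], (3, 2, 1, 0))
            p = out_dir / phase_filename(f, m)
            _save_nifti(vol, g.voxel_size, p)
            paths.append(p)
    sidecar = {"grid": g.to_dict(), "wrapped": bool(series.wrapped), "meta": series.meta}
    (out_dir / "series.json").write_text(json.dumps(sidecar, indent=2))
    return paths


def read_phase_series(in_dir: str | Path, grid: AcquisitionGrid | None = None) -> RawPhaseSeries:
    """Read a phase series written by :func:`write_phase_series`.

    If ``grid`` is None the sidecar metadata is used.  Missing files raise
    ``FileNotFoundError`` naming the (frequency, component); shape mismatches
    raise ``ValueError`` naming the offending axis.
    """
    in_dir = Path(in_dir)
    sidecar_path = in_dir / "series.json"
    wrapped, meta = True, {}
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        wrapped = bool(sidecar.get("wrapped", True))
        meta = sidecar.get("meta", {})
        if grid is None:
            grid = AcquisitionGrid.from_dict(sidecar["grid"])
    if grid is None:
        raise FileNotFoundError(f"no sidecar {sidecar_path} and no grid metadata supplied")

    nx, ny, nz = grid.shape
    phase = np.empty(
        (grid.n_frequencies, grid.n_components, grid.n_timesteps, nz, ny, nx), dtype=float
    )
    for fi, f in enumerate(grid.frequencies):
        for m in range(grid.n_components):
            p = in_dir / phase_filename(f, m)
            if not p.exists():
                raise FileNotFoundError(
                    f"missing phase volume for frequency {f:g} Hz, component {m}: {p}"
                )
            vol = _load_nifti(p)
            _check_shape(f"{p.name}", vol, (nx, ny, nz, grid.n_timesteps))
            phase[fi, m] = np.transpose(vol, (3, 2, 1, 0))
    if not np.all(np.isfinite(phase)):
        raise ValueError(f"phase series under {in_dir} contains non-finite voxels")
    return RawPhaseSeries(grid=grid, phase=phase, wrapped=wrapped, meta=meta)


def write_elastogram(e: ElastogramPair, out_dir: str | Path, prefix: str = "elastogram") -> dict[str, Path]:
    """Write |G*| (converted to kPa for reporting), phi (rad) and the mask.

    Masked-out voxels are stored as NaN in the parameter maps; the mask is a
    separate uint8 volume so validity survives any later filtering.
    """
    e.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    gabs_kpa = np.where(e.mask, e.gabs / 1000.0, np.nan)
    phi = np.where(e.mask, e.phi, np.nan)
    paths = {
        "gabs_kpa": out_dir / f"{prefix}_gabs_kpa.nii",
        "phi_rad": out_dir / f"{prefix}_phi_rad.nii",
        "mask": out_dir / f"{prefix}_mask.nii",
    }
    _save_nifti(_zyx_to_xyz(gabs_kpa), e.voxel_size, paths["gabs_kpa"])
    _save_nifti(_zyx_to_xyz(phi), e.voxel_size, paths["phi_rad"])
    _save_nifti(_zyx_to_xyz(e.mask.astype(np.uint8)), e.voxel_size, paths["mask"])
    return paths


def read_elastogram(in_dir: str | Path, prefix: str = "elastogram") -> ElastogramPair:
    in_dir = Path(in_dir)
    gabs_img = nib.load(str(in_dir / f"{prefix}_gabs_kpa.nii"))
    zooms = gabs_img.header.get_zooms()[:3]
    gabs = _xyz_to_zyx(np.asarray(gabs_img.dataobj)) * 1000.0
    phi = _xyz_to_zyx(_load_nifti(in_dir / f"{prefix}_phi_rad.nii"))
    mask = _xyz_to_zyx(_load_nifti(in_dir / f"{prefix}_mask.nii")).astype(bool)
    gabs = np.where(mask, gabs, np.nan)
    phi = np.where(mask, phi, np.nan)
    voxel_size = tuple(float(z) * 1e-3 for z in zooms)
    return ElastogramPair(gabs=gabs, phi=phi, mask=mask, voxel_size=voxel_size)


def write_labeled_mask(
    labels_zyx: np.ndarray,
    voxel_size: tuple[float, float, float],
    path: str | Path,
    legend: dict[int, str] | None = None,
) -> None:
    """Write an integer ROI label volume, with an optional JSON label legend."""
    path = Path(path)
    _save_nifti(_zyx_to_xyz(np.asarray(labels_zyx, dtype=np.int16)), voxel_size, path)
    if legend is not None:
        Path(str(path) + ".labels.json").write_text(
            json.dumps({str(k): v for k, v in legend.items()}, indent=2)
        )


def read_labeled_mask(path: str | Path) -> tuple[np.ndarray, dict[int, str]]:
    """Read an ROI label volume and its legend (empty dict if absent)."""
    path = Path(path)
    labels = _xyz_to_zyx(_load_nifti(path)).astype(int)
    legend_path = Path(str(path) + ".labels.json")
    legend: dict[int, str] = {}
    if legend_path.exists():
        legend = {int(k): v for k, v in json.loads(legend_path.read_text()).items()}
    return labels, legend


def wrap_phase(x: np.ndarray) -> np.ndarray:
    """Wrap phase values into the interval (-pi, pi]."""
    return np.pi - np.mod(np.pi - np.asarray(x, dtype=float), 2.0 * np.pi)
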