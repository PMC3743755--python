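"""End-to-end reconstruction chain: raw phase -> elastogram.

One function chains the standard processing order (unwrap, smooth, scale,
temporal harmonic, curl, Butterworth, MDEV inversion) with switches for the
filter-ablation variants used to study noise behavior: ``smooth=False,
butterworth=False`` is the raw pipeline, ``smooth=True, butterworth=False``
the intermediate one, and the default is the full procedure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import curl_filter, mdev_inversion, preprocess
from .mdev_inversion import InversionConfig
from .wavefield_io import ComplexWaveField, CurlField, ElastogramPair, RawPhaseSeries

__all__ = ["ReconstructionResult", "reconstruct"]


@dataclass
class ReconstructionResult:
    """Final maps plus the intermediates, for diagnostics and testing."""

    elastogram: ElastogramPair
    wavefield: ComplexWaveField
    curl: CurlField
    filtered_curl: CurlField
    stages: list[str] = field(default_factory=list)


def reconstruct(
    series: RawPhaseSeries,
    config: InversionConfig | None = None,
    smooth: bool = True,
    smooth_sigma: float = 0.65,
    butterworth: bool = True,
    cutoff: float = 100.0,
    order: int = 3,
    scale_factor: float | None = None,
    unwrap_backend: str = "slice2d",
) -> ReconstructionResult:
    """Run the full reconstruction chain on a raw phase series.

    ``scale_factor`` converts radians to displacement; the maps are
    invariant to it (the estimators are zero-degree homogeneous), so it may
    be left None.
    """
    config = config or InversionConfig()
    stages = []
    s = series
    if s.wrapped:
        s = preprocess.unwrap_phase(s, backend=unwrap_backend)
        stages.append(f"unwrap[{unwrap_backend}]")
    if smooth:
        s = preprocess.smooth_gaussian(s, sigma=smooth_sigma)
        stages.append(f"smooth[sigma={smooth_sigma}]")
    if scale_factor is not None:
        s = preprocess.scale_to_displacement(s, scale_factor)
        stages.append(f"scale[{scale_factor:g}]")
    u = preprocess.temporal_harmonic(s)
    stages.append("temporal_harmonic")
    c = curl_filter.compute_curl(u)
    stages.append("curl")
    cf = c
    if butterworth:
        cf = curl_filter.butterworth_lowpass(c, cutoff=cutoff, order=order)
        stages.append(f"butterworth[cutoff={cutoff:g},order={order}]")
    e = mdev_inversion.mdev_invert(cf, config)
    stages.append(
        f"mdev_invert[laplacian={config.laplacian_mode},rho={config.density:g}]"
    )
    e.meta["stages"] = stages
    return ReconstructionResult(elastogram=e, wavefield=u, curl=c, filtered_curl=cf, stages=stages)
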