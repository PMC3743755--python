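"""ROI statistics, group averaging of aligned maps, and regional testing.

Regional means/SDs use the sample SD (n-1 denominator).  Regional
comparisons default to a paired two-tailed t-test at the 5% level, because
regional values typically come from the same subjects; an
independent-samples variant and an optional Bonferroni correction are
available behind flags.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .wavefield_io import ElastogramPair

__all__ = ["ROIStats", "RegionComparison", "roi_stats", "roi_stats_frame", "group_average", "region_compare"]


@dataclass
class ROIStats:
    """Per-region summary of an elastogram pair."""

    label: str
    n_voxels: int
    mean_gabs: float
    sd_gabs: float
    mean_phi: float
    sd_phi: float


@dataclass
class RegionComparison:
    """Result of a two-tailed t-test between two regions."""

    t: float
    p: float
    significant: bool
    degenerate: bool = False
    paired: bool = True
    alpha: float = 0.05


def _sample_sd(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1)) if x.size > 1 else float("nan")


def roi_stats(
    e: ElastogramPair, labels: np.ndarray, legend: dict[int, str] | None = None
) -> list[ROIStats]:
    """Mean and sample SD of |G*| and phi per labeled region.

    Voxels outside the elastogram's validity mask are excluded (and the
    region's voxel count reflects the exclusion).  Regions with zero valid
    voxels are reported with ``n_voxels = 0`` and NaN statistics rather than
    silently dropped.  Label 0 is background by convention.
    """
    labels = np.asarray(labels)
    if labels.shape != e.gabs.shape:
        raise ValueError(f"label volume shape {labels.shape} does not match maps {e.gabs.shape}")
    legend = legend or {}
    out: list[ROIStats] = []
    for lab in np.unique(labels):
        if lab == 0:
            continue
        name = legend.get(int(lab), str(int(lab)))
        sel = (labels == lab) & e.mask
        n = int(sel.sum())
        if n == 0:
            out.append(ROIStats(name, 0, float("nan"), float("nan"), float("nan"), float("nan")))
            continue
        gv, pv = e.gabs[sel], e.phi[sel]
        out.append(
            ROIStats(
                label=name,
                n_voxels=n,
                mean_gabs=float(np.mean(gv)),
                sd_gabs=_sample_sd(gv),
                mean_phi=float(np.mean(pv)),
                sd_phi=_sample_sd(pv),
            )
        )
    return out


def roi_stats_frame(stats_list: list[ROIStats]) -> pd.DataFrame:
    return pd.DataFrame([vars(s) for s in stats_list])


def group_average(maps: list[ElastogramPair]) -> tuple[ElastogramPair, np.ndarray, np.ndarray, np.ndarray]:
    """Voxel-wise mean over aligned subjects, with SD maps and valid counts.

    Returns ``(mean_pair, sd_gabs, sd_phi, count)``; a voxel is valid in the
    mean if at least one subject is valid there, and the per-voxel count
    records how many subjects entered the average.
    """
    if not maps:
        raise ValueError("no maps given")
    shape = maps[0].gabs.shape
    vs = maps[0].voxel_size
    for i, m in enumerate(maps):
        if m.gabs.shape != shape:
            raise ValueError(f"map {i} has shape {m.gabs.shape}, expected {shape}")
        if not np.allclose(m.voxel_size, vs):
            raise ValueError(f"map {i} voxel size {m.voxel_size} differs from {vs}")
    g = np.stack([np.where(m.mask, m.gabs, np.nan) for m in maps])
    p = np.stack([np.where(m.mask, m.phi, np.nan) for m in maps])
    count = np.sum([m.mask for m in maps], axis=0)
    with np.errstate(invalid="ignore"):
        mean_g = np.nanmean(g, axis=0)
        mean_p = np.nanmean(p, axis=0)
        sd_g = np.full(shape, np.nan)
        sd_p = np.full(shape, np.nan)
        multi = count > 1
        if multi.any():
            sd_g[multi] = np.nanstd(g[:, multi], axis=0, ddof=1)
            sd_p[multi] = np.nanstd(p[:, multi], axis=0, ddof=1)
    mask = count >= 1
    pair = ElastogramPair(
        gabs=np.where(mask, mean_g, np.nan),
        phi=np.where(mask, mean_p, np.nan),
        mask=mask,
        voxel_size=vs,
    )
    return pair, sd_g, sd_p, count


def region_compare(
    a: np.ndarray,
    b: np.ndarray,
    paired: bool = True,
    alpha: float = 0.05,
    n_comparisons: int = 1,
) -> RegionComparison:
    """Two-tailed t-test between per-subject regional means.

    Paired by default (the same subjects contribute to both regions).  With
    ``n_comparisons > 1`` a Bonferroni-adjusted threshold is used.  A paired
    sample whose differences have zero variance but nonzero mean is reported
    as degenerate with infinite t and p = 0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError(f"need at least 2 subjects per sample, got {a.size} and {b.size}")
    threshold = alpha / max(1, int(n_comparisons))
    if paired:
        if a.size != b.size:
            raise ValueError(f"paired test needs equal sample sizes, got {a.size} vs {b.size}")
        d = a - b
        if np.all(d == d[0]):
            if d[0] == 0:
                return RegionComparison(0.0, 1.0, False, degenerate=True, paired=True, alpha=alpha)
            t = float(np.sign(d[0]) * np.inf)
            return RegionComparison(t, 0.0, True, degenerate=True, paired=True, alpha=alpha)
        res = stats.ttest_rel(a, b)
    else:
        res = stats.ttest_ind(a, b)
    return RegionComparison(
        t=float(res.statistic),
        p=float(res.pvalue),
        significant=bool(res.pvalue < threshold),
        degenerate=False,
        paired=paired,
        alpha=alpha,
    )
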