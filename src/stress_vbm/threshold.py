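"""Apply expression-ranked per-region thresholds to a voxelwise t-map.

Each atlas region carries its own p threshold from the receptor-expression
ladder; a voxel is significant when its t statistic exceeds the critical t
of its own region. The result is a binary significance map plus a region
report with voxel counts, peak statistics and 26-connected cluster extents.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .exceptions import ConfigurationError, ContractViolationError, GeometryError
from .expression import ThresholdMap
from .glm import StatMap

#: 26-neighbour connectivity for cluster labelling
CONNECTIVITY_26 = np.ones((3, 3, 3), dtype=int)

REPORT_COLUMNS = [
    "region_label",
    "p_threshold",
    "critical_t",
    "n_significant_voxels",
    "n_clusters",
    "max_cluster_size",
    "peak_t",
    "peak_i",
    "peak_j",
    "peak_k",
    "peak_x_mm",
    "peak_y_mm",
    "peak_z_mm",
]


@dataclass
class SignificanceMap:
    """Binary significance grid with the per-voxel threshold applied."""

    significant: np.ndarray
    p_threshold_grid: np.ndarray
    direction: str


def critical_t(p_threshold: float, df: float, two_sided: bool = False) -> float:
    """Student-t critical value for an upper-tail test at ``p_threshold``.

    One-sided by default (the analysis tests directed contrasts);
    ``two_sided=True`` halves p before inversion.
    """
    if not 0.0 < p_threshold < 1.0:
        raise ContractViolationError("p threshold must lie in (0, 1)")
    if df < 1:
        raise ContractViolationError("degrees of freedom must be >= 1")
    p = p_threshold / 2.0 if two_sided else p_threshold
    return float(stats.t.isf(p, df))


def apply_thresholds(
    stat_map: StatMap,
    atlas: np.ndarray,
    threshold_map: ThresholdMap,
    direction: str = "pos",
    lenient: bool = False,
    min_cluster_size: int = 1,
) -> tuple[SignificanceMap, pd.DataFrame]:
    """Threshold a t-map region by region and report per-region results.

    ``direction='pos'`` tests t > t_crit, ``'neg'`` tests -t > t_crit (both
    one-sided at each region's own p). Atlas regions without a threshold
    raise unless ``lenient``, in which case they are skipped. Coordinates
    are reported as 0-based voxel indices and as mm from the grid corner
    (mm = index * voxel_size).
    """
    atlas = np.asarray(atlas)
    if stat_map.t_values.shape != atlas.shape:
        raise GeometryError("t-map grid does not match atlas grid")
    if direction not in ("pos", "neg"):
        raise ConfigurationError(f"unknown direction {direction!r}")
    t = stat_map.t_values if direction == "pos" else -stat_map.t_values

    sig = np.zeros(atlas.shape, dtype=bool)
    p_grid = np.full(atlas.shape, np.nan)
    rows = []
    present = [int(r) for r in np.unique(atlas) if r != 0]
    assigned = set(int(r) for r in threshold_map.table["region_label"])
    missing = sorted(set(present) - assigned)
    if missing and not lenient:
        raise ConfigurationError(
            f"atlas regions without an assigned threshold: {missing}"
        )
    vs = stat_map.voxel_size
    for region in present:
        if region not in assigned:
            continue
        p_thr = threshold_map.p_threshold(region)
        t_crit = critical_t(p_thr, stat_map.df)
        in_region = atlas == region
        p_grid[in_region] = p_thr
        region_sig = in_region & (t > t_crit)
        n_clusters = 0
        max_cluster = 0
        if region_sig.any() and min_cluster_size > 1:
            labels, n_clusters = ndimage.label(region_sig, structure=CONNECTIVITY_26)
            sizes = np.bincount(labels.ravel())[1:]
            keep = np.flatnonzero(sizes >= min_cluster_size) + 1
            region_sig = np.isin(labels, keep)
        if region_sig.any():
            labels, n_clusters = ndimage.label(region_sig, structure=CONNECTIVITY_26)
            sizes = np.bincount(labels.ravel())[1:]
            max_cluster = int(sizes.max())
            t_region = np.where(region_sig, t, -np.inf)
            peak_flat = int(np.argmax(t_region))
            pi, pj, pk = np.unravel_index(peak_flat, atlas.shape)
            peak_t = float(stat_map.t_values[pi, pj, pk])
            row = [
                region, p_thr, t_crit, int(region_sig.sum()), int(n_clusters),
                max_cluster, peak_t, int(pi), int(pj), int(pk),
                pi * vs, pj * vs, pk * vs,
            ]
        else:
            row = [
                region, p_thr, t_crit, 0, 0, 0,
                np.nan, -1, -1, -1, np.nan, np.nan, np.nan,
            ]
        sig |= region_sig
        rows.append(row)
    report = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    sig_map = SignificanceMap(
        significant=sig, p_threshold_grid=p_grid, direction=direction
    )
    return sig_map, report


def significant_regions(report: pd.DataFrame) -> list[int]:
    """Region labels with at least one significant voxel."""
    return [
        int(r)
        for r in report.loc[report["n_significant_voxels"] > 0, "region_label"]
    ]
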