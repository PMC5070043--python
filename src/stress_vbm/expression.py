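"""Receptor-expression-weighted flexible thresholding mask.

Builds the a priori mask from a sample-level table of normalized GR and MR
(glucocorticoid / mineralocorticoid receptor) expression: tissue samples are
averaged within each atlas region, then over the probes targeting each gene
within a donor, then over donors; the two gene values are pooled into one
combined score per region. Regions are ranked by combined expression
(rank 1 = highest) and assigned a voxelwise p threshold on a linear ladder
from p = 0.01 uncorrected (highest expression) down to p = 0.05/N
Bonferroni-corrected over the N in-mask voxels (lowest expression): regions
rich in corticosteroid receptors, where a cortisol–structure association is
biologically plausible, are tested leniently; receptor-poor regions must
clear the fully corrected bar.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, EmptyMaskError, MappingError

GENES = ("GR", "MR")

P_MAX_DEFAULT = 0.01  # uncorrected threshold for the highest-expression rank
ALPHA_BONFERRONI = 0.05  # corrected level defining the strict endpoint

EXPRESSION_COLUMNS = ("donor_id", "probe_id", "gene", "region_label", "expression")


@dataclass
class ThresholdMap:
    """Per-region p thresholds derived from expression ranks.

    ``table`` columns: region_label, mean_gr, mean_mr, combined, rank,
    p_threshold. ``uncovered`` lists atlas regions without usable expression
    for both genes; they are excluded from inference.
    """

    table: pd.DataFrame
    n_voxels_mask: int
    p_max: float
    p_min: float
    uncovered: list[int] = field(default_factory=list)

    def p_threshold(self, region_label: int) -> float:
        row = self.table.loc[self.table["region_label"] == region_label]
        if row.empty:
            raise ConfigurationError(
                f"region {region_label} has no assigned threshold"
            )
        return float(row["p_threshold"].iloc[0])


def validate_expression_table(samples: pd.DataFrame) -> pd.DataFrame:
    missing = set(EXPRESSION_COLUMNS) - set(samples.columns)
    if missing:
        raise MappingError(f"expression table missing columns: {sorted(missing)}")
    bad = set(samples["gene"].unique()) - set(GENES)
    if bad:
        raise MappingError(f"unknown gene symbols {sorted(bad)}; expected {GENES}")
    return samples


def aggregate_samples_to_regions(
    samples: pd.DataFrame, atlas_labels: set[int] | None = None
) -> pd.DataFrame:
    """Average tissue samples within (region, donor, probe, gene).

    A template region can include several sampling sites; their measurements
    are averaged here before any probe or donor pooling. Returns one row per
    (region_label, donor_id, probe_id, gene) with the mean expression.
    """
    samples = validate_expression_table(samples)
    if atlas_labels is not None:
        unknown = set(samples["region_label"].unique()) - set(atlas_labels)
        if unknown:
            raise MappingError(
                f"expression samples reference unknown region labels "
                f"{sorted(unknown)}"
            )
    out = (
        samples.groupby(
            ["region_label", "donor_id", "probe_id", "gene"], sort=True, as_index=False
        )["expression"]
        .mean()
    )
    return out


def average_probes_then_donors(per_probe: pd.DataFrame) -> pd.DataFrame:
    """Pool probes within each donor, then donors, per (region, gene).

    Order matters for unbalanced designs: each gene's value for a donor is
    the mean over that donor's probes, and the region value is the mean of
    the donor values — not the pooled mean over all probe measurements.
    """
    per_donor = (
        per_probe.groupby(["region_label", "donor_id", "gene"], sort=True, as_index=False)[
            "expression"
        ]
        .mean()
    )
    per_gene = (
        per_donor.groupby(["region_label", "gene"], sort=True, as_index=False)[
            "expression"
        ]
        .mean()
    )
    return per_gene


def combine_gr_mr(per_gene: pd.DataFrame) -> tuple[pd.DataFrame, list[int]]:
    """Unweighted mean of the GR and MR values per region, ranked descending.

    Regions missing either gene are dropped from the mask and returned in the
    second element. Tied combined values share the mean of their tied ranks
    (and hence an identical threshold downstream).
    """
    wide = per_gene.pivot(index="region_label", columns="gene", values="expression")
    uncovered = sorted(
        int(r) for r in wide.index[wide.reindex(columns=list(GENES)).isna().any(axis=1)]
    )
    wide = wide.dropna(subset=[g for g in GENES if g in wide.columns])
    if not set(GENES) <= set(wide.columns):
        # one gene absent everywhere: nothing is covered
        return (
            pd.DataFrame(
                columns=["region_label", "mean_gr", "mean_mr", "combined", "rank"]
            ),
            uncovered,
        )
    scores = pd.DataFrame(
        {
            "region_label": wide.index.astype(int),
            "mean_gr": wide["GR"].to_numpy(),
            "mean_mr": wide["MR"].to_numpy(),
        }
    )
    scores["combined"] = (scores["mean_gr"] + scores["mean_mr"]) / 2.0
    # rank 1 = highest combined expression; ties share their mean rank
    scores["rank"] = scores["combined"].rank(ascending=False, method="average")
    scores = scores.sort_values("rank", kind="mergesort").reset_index(drop=True)
    return scores, uncovered


def assign_thresholds(
    scores: pd.DataFrame,
    n_voxels_mask: int,
    p_max: float = P_MAX_DEFAULT,
    alpha: float = ALPHA_BONFERRONI,
    spacing: str = "linear",
) -> ThresholdMap:
    """Map expression ranks to per-region p thresholds.

    With R ranked regions, rank r receives

        p(r) = p_max - (r - 1) * (p_max - p_min) / (R - 1),   p_min = alpha/N

    (linear in p; ``spacing='log'`` interpolates in log10 p instead). Rank 1
    gets exactly ``p_max`` and rank R exactly ``p_min``; a single region gets
    ``p_max``. Fractional (tied) ranks interpolate on the same ladder, so
    tied regions share one threshold.
    """
    if n_voxels_mask < 1:
        raise EmptyMaskError("analysis mask contains no voxels")
    if scores.empty:
        raise ConfigurationError("no regions with expression coverage")
    if spacing not in ("linear", "log"):
        raise ConfigurationError(f"unknown threshold spacing {spacing!r}")
    p_min = alpha / n_voxels_mask
    if p_min > p_max:
        raise ConfigurationError(
            "Bonferroni endpoint exceeds the uncorrected endpoint; "
            "mask too small for the ladder"
        )
    out = scores.copy()
    n_regions = len(out)
    rank = out["rank"].to_numpy(dtype=float)
    if n_regions == 1:
        p = np.array([p_max])
    elif spacing == "linear":
        p = p_max - (rank - 1.0) * (p_max - p_min) / (n_regions - 1.0)
    else:
        lp = np.log10(p_max) - (rank - 1.0) * (
            np.log10(p_max) - np.log10(p_min)
        ) / (n_regions - 1.0)
        p = 10.0**lp
    out["p_threshold"] = p
    return ThresholdMap(
        table=out, n_voxels_mask=int(n_voxels_mask), p_max=p_max, p_min=p_min
    )


def build_threshold_map(
    samples: pd.DataFrame,
    n_voxels_mask: int,
    atlas_labels: set[int] | None = None,
    p_max: float = P_MAX_DEFAULT,
    alpha: float = ALPHA_BONFERRONI,
    spacing: str = "linear",
) -> ThresholdMap:
    """Full path from a sample-level expression table to a ThresholdMap."""
    per_probe = aggregate_samples_to_regions(samples, atlas_labels)
    per_gene = average_probes_then_donors(per_probe)
    scores, uncovered = combine_gr_mr(per_gene)
    tm = assign_thresholds(
        scores, n_voxels_mask, p_max=p_max, alpha=alpha, spacing=spacing
    )
    if atlas_labels is not None:
        covered = set(tm.table["region_label"].astype(int))
        uncovered = sorted(set(uncovered) | (set(atlas_labels) - covered))
    tm.uncovered = uncovered
    return tm
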