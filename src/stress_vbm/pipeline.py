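"""End-to-end orchestration: cortisol QC → CAR stats → GLM → thresholding.

Mirrors the study's analysis order: quality-control the saliva series and
compute CAR measures; compare groups (with standard-score outlier
screening); smooth and proportionally scale the grey-matter volumes; fit
the voxelwise CAR and group-by-CAR models; and threshold both t-maps with
the receptor-expression ladder, yielding per-region significance reports
and a provenance record.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import car as car_mod
from .config import PipelineConfig
from .exceptions import PipelineError
from .expression import ThresholdMap, build_threshold_map
from .glm import (
    StatMap,
    VolumetricImage,
    analysis_mask,
    build_design,
    fit_interaction_glm,
    fit_voxelwise_glm,
    proportional_scale,
    smooth_gaussian,
)
from .threshold import SignificanceMap, apply_thresholds


@dataclass
class PipelineResult:
    car_table: pd.DataFrame
    excluded_qc: list[str]
    outliers: list[str]
    group_stats: dict[str, car_mod.GroupTestResult | None]
    transition_proportion: float | None
    threshold_map: ThresholdMap | None = None
    stat_maps: dict[str, StatMap] = field(default_factory=dict)
    significance: dict[str, SignificanceMap] = field(default_factory=dict)
    reports: dict[str, pd.DataFrame] = field(default_factory=dict)
    mask: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)


def _stage(name: str, exc: Exception) -> PipelineError:
    return PipelineError(f"stage {name!r}: {exc}")


def car_stage(
    samples: pd.DataFrame, covariates: pd.DataFrame, config: PipelineConfig
) -> PipelineResult:
    """QC + CAR + group statistics; the non-imaging half of the pipeline."""
    series = car_mod.series_from_table(samples)
    table = car_mod.car_table(
        series,
        volume_floor_ul=config.volume_floor_ul,
        timing_tolerance_min=config.timing_tolerance_min,
        strict_timing=config.strict_timing,
    )
    table = table.merge(
        covariates[["subject_id", "group", "transition"]], on="subject_id", how="left"
    )
    if table["group"].isna().any():
        missing = table.loc[table["group"].isna(), "subject_id"].tolist()
        raise _stage("car", ValueError(f"subjects without covariates: {missing}"))
    excluded = table.loc[~table["qc_pass"], "subject_id"].tolist()
    retained = table[table["qc_pass"]].reset_index(drop=True)
    if retained.empty:
        raise _stage("car", ValueError("no subjects pass cortisol QC"))

    measure = "auc_i" if config.auc_variant == "i" else "auc_g"
    welch = config.t_test == "welch"

    def group_vals(df: pd.DataFrame, grp: int) -> np.ndarray:
        return df.loc[df["group"] == grp, measure].to_numpy(dtype=float)

    def safe_test(a: np.ndarray, b: np.ndarray):
        if len(a) < 2 or len(b) < 2:
            return None
        return car_mod.pooled_t_test_values(a, b, welch=welch)

    uhr, ctl = group_vals(retained, 1), group_vals(retained, 0)
    stats_out: dict[str, car_mod.GroupTestResult | None] = {
        "uhr_vs_control": safe_test(uhr, ctl)
    }

    outliers: list[str] = []
    if config.exclude_outliers:
        for grp in (1, 0):
            sub = retained[retained["group"] == grp]
            vals = sub[measure].to_numpy(dtype=float)
            if len(vals) >= 3 and np.std(vals, ddof=1) > 0:
                flags, _z = car_mod.detect_outliers(vals, config.z_threshold)
                outliers.extend(sub.loc[flags, "subject_id"].tolist())
    no_out = retained[~retained["subject_id"].isin(outliers)]
    stats_out["uhr_vs_control_no_outlier"] = (
        safe_test(group_vals(no_out, 1), group_vals(no_out, 0))
        if outliers
        else stats_out["uhr_vs_control"]
    )

    trans = retained[(retained["group"] == 1) & (retained["transition"] == 1)]
    stats_out["transition_vs_control"] = safe_test(
        trans[measure].to_numpy(dtype=float), ctl
    )
    n_uhr = int((retained["group"] == 1).sum())
    transition_proportion = (
        100.0 * len(trans) / n_uhr if n_uhr else None
    )

    return PipelineResult(
        car_table=table,
        excluded_qc=excluded,
        outliers=outliers,
        group_stats=stats_out,
        transition_proportion=transition_proportion,
    )


def end_to_end(
    covariates: pd.DataFrame,
    samples: pd.DataFrame,
    expression: pd.DataFrame,
    atlas: np.ndarray,
    images: dict[str, VolumetricImage],
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Run the full analysis on in-memory inputs.

    ``images`` maps subject_id to its grey-matter volume; subjects excluded
    by cortisol QC (or as CAR outliers) are dropped from the imaging stage.
    Deterministic given inputs and config.
    """
    config = (config or PipelineConfig()).validate()
    result = car_stage(samples, covariates, config)
    measure = "auc_i" if config.auc_variant == "i" else "auc_g"

    analysed = result.car_table[
        result.car_table["qc_pass"]
        & ~result.car_table["subject_id"].isin(result.outliers)
    ].reset_index(drop=True)
    missing_imgs = [s for s in analysed["subject_id"] if s not in images]
    if missing_imgs:
        raise _stage("imaging", ValueError(f"no image for subjects {missing_imgs}"))
    cov = covariates.set_index("subject_id", drop=False).loc[
        analysed["subject_id"]
    ].reset_index(drop=True)
    car_values = analysed[measure].to_numpy(dtype=float)

    imgs = [images[s] for s in analysed["subject_id"]]
    voxel_size = imgs[0].voxel_size
    for im in imgs:
        if im.grid_shape != atlas.shape:
            raise _stage("imaging", ValueError("image grid does not match atlas"))
    smoothed = [smooth_gaussian(im, config.fwhm_mm) for im in imgs]
    stack = np.stack([im.values for im in smoothed])

    mask = analysis_mask(stack, atlas)
    if not mask.any():
        raise _stage("imaging", ValueError("empty analysis mask"))
    stack, _factors = proportional_scale(stack, mask)
    atlas_in_mask = np.where(mask, atlas, 0)

    design = build_design(cov, car_values, model="car")
    car_map = fit_voxelwise_glm(stack, design, "car", voxel_size=voxel_size)
    inter_map = fit_interaction_glm(stack, cov, car_values, voxel_size=voxel_size)
    result.stat_maps = {"car": car_map, "interaction": inter_map}

    tm = build_threshold_map(
        expression,
        n_voxels_mask=int(mask.sum()),
        atlas_labels=set(int(r) for r in np.unique(atlas) if r != 0),
        p_max=config.p_max,
        alpha=config.alpha_bonferroni,
        spacing=config.threshold_spacing,
    )
    result.threshold_map = tm
    result.mask = mask

    for name, stat, direction in (
        ("car_pos", car_map, config.direction),
        ("interaction_pos", inter_map, "pos"),
        ("interaction_neg", inter_map, "neg"),
    ):
        sig, report = apply_thresholds(
            stat,
            atlas_in_mask,
            tm,
            direction=direction,
            lenient=True,
            min_cluster_size=config.min_cluster_size,
        )
        result.significance[name] = sig
        result.reports[name] = report

    cfg_json = json.dumps(config.to_dict(), sort_keys=True)
    result.provenance = {
        "config": config.to_dict(),
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "seed": config.seed,
        "n_subjects_in": int(len(covariates)),
        "n_excluded_qc": len(result.excluded_qc),
        "excluded_qc": result.excluded_qc,
        "outliers": result.outliers,
        "n_analysed": int(len(analysed)),
        "n_voxels_mask": int(mask.sum()),
        "n_regions_covered": int(len(tm.table)),
        "regions_uncovered": tm.uncovered,
        "df_car": car_map.df,
        "df_interaction": inter_map.df,
    }
    return result
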