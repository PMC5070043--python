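"""Synthetic inputs with the statistical structure the analysis assumes.

Generates every input the pipeline consumes: a block parcellation of a small
3D grid, a sample-level GR/MR expression table, a cohort of saliva sampling
series with group structure in the cortisol awakening response (blunted in
the at-risk group), planted quality-control failures and an optional extreme
outlier, and modulated grey-matter volume images produced by a forward
linear model so that known effects can be recovered by the voxelwise GLM.

Default cohort parameters mirror the published study conditions: 22 at-risk
(UHR) subjects against 17 controls with group AUC means 223.84 and 320.97
nmol*min/l (SDs 233.52 and 253.85), four eventual transitions to psychosis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import GeometryError, InvalidSpecError
from .glm import VolumetricImage


# --------------------------------------------------------------------------
# specs
# --------------------------------------------------------------------------

@dataclass
class AtlasSpec:
    grid_shape: tuple[int, int, int] = (16, 16, 16)
    voxel_size: float = 2.0
    n_regions: int = 8
    seed: int = 0

    def validate(self) -> None:
        if len(self.grid_shape) != 3 or any(s < 1 for s in self.grid_shape):
            raise InvalidSpecError("grid_shape must be three positive extents")
        if self.n_regions < 2:
            raise InvalidSpecError("need at least 2 regions")
        if self.n_regions > math.prod(self.grid_shape):
            raise InvalidSpecError(
                f"{self.n_regions} regions cannot tile "
                f"{math.prod(self.grid_shape)} voxels"
            )
        if self.voxel_size <= 0:
            raise InvalidSpecError("voxel size must be positive")


@dataclass
class CohortSpec:
    """Cohort structure; defaults are the published study conditions."""

    n_uhr: int = 22
    n_control: int = 17
    car_mean_uhr: float = 223.84
    car_sd_uhr: float = 233.52
    car_mean_control: float = 320.97
    car_sd_control: float = 253.85
    n_transition: int = 4
    outlier_value: float | None = None
    n_qc_fail_volume: int = 0
    n_qc_fail_timing: int = 0
    n_qc_fail_delta30: int = 0
    n_qc_fail_missing: int = 0
    age_range: tuple[float, float] = (18.0, 30.0)
    antidep_fraction: float = 4.0 / 22.0
    transition_assignment: str = "lowest"  # or "random"
    seed: int = 0

    @property
    def n_qc_fail_total(self) -> int:
        return (
            self.n_qc_fail_volume
            + self.n_qc_fail_timing
            + self.n_qc_fail_delta30
            + self.n_qc_fail_missing
        )

    def validate(self) -> None:
        counts = [
            self.n_uhr, self.n_control, self.n_transition,
            self.n_qc_fail_volume, self.n_qc_fail_timing,
            self.n_qc_fail_delta30, self.n_qc_fail_missing,
        ]
        if any(c < 0 for c in counts):
            raise InvalidSpecError("counts must be >= 0")
        if self.n_transition > self.n_uhr:
            raise InvalidSpecError("more transitions than UHR subjects")
        if self.car_sd_uhr < 0 or self.car_sd_control < 0:
            raise InvalidSpecError("SDs must be >= 0")
        if self.n_qc_fail_total > self.n_uhr + self.n_control:
            raise InvalidSpecError("more planted QC failures than subjects")
        if not 0.0 <= self.antidep_fraction <= 1.0:
            raise InvalidSpecError("antidep_fraction must be in [0, 1]")
        if self.transition_assignment not in ("lowest", "random"):
            raise InvalidSpecError(
                f"unknown transition assignment {self.transition_assignment!r}"
            )


@dataclass
class EffectSpec:
    """Forward-model effect structure planted into the GMV images."""

    effect_regions: frozenset[int] = frozenset()
    slope_per_region: float = 0.0  # GMV units per nmol*min/l of CAR
    interaction_regions: frozenset[int] = frozenset()
    interaction_slope_delta: float = 0.0  # extra slope in the UHR group
    covariate_betas: dict[str, float] = field(default_factory=dict)
    noise_sd: float = 10.0
    baseline_per_region: float = 600.0

    def validate(self, atlas_labels: set[int]) -> None:
        if self.noise_sd < 0:
            raise InvalidSpecError("noise_sd must be >= 0")
        for name, regions in (
            ("effect_regions", self.effect_regions),
            ("interaction_regions", self.interaction_regions),
        ):
            unknown = set(regions) - atlas_labels
            if unknown:
                raise InvalidSpecError(f"{name} not in atlas: {sorted(unknown)}")
        bad = set(self.covariate_betas) - {"age", "gender", "antidepressant"}
        if bad:
            raise InvalidSpecError(f"unknown covariates {sorted(bad)}")


# --------------------------------------------------------------------------
# atlas
# --------------------------------------------------------------------------

def generate_atlas(spec: AtlasSpec) -> np.ndarray:
    """Partition the grid into connected axis-aligned blocks, one per region.

    The largest block is split in half along its longest axis until the
    requested region count is reached; labels 1..n_regions are then assigned
    to blocks in a seed-determined order. Every voxel carries exactly one
    label (no background in the synthetic grid).
    """
    spec.validate()
    blocks: list[tuple[tuple[int, int], ...]] = [
        tuple((0, s) for s in spec.grid_shape)
    ]

    def nvox(block: tuple[tuple[int, int], ...]) -> int:
        return math.prod(hi - lo for lo, hi in block)

    while len(blocks) < spec.n_regions:
        blocks.sort(key=nvox, reverse=True)
        big = blocks.pop(0)
        extents = [hi - lo for lo, hi in big]
        axis = int(np.argmax(extents))
        lo, hi = big[axis]
        mid = (lo + hi) // 2
        left = tuple(
            (lo, mid) if a == axis else bounds for a, bounds in enumerate(big)
        )
        right = tuple(
            (mid, hi) if a == axis else bounds for a, bounds in enumerate(big)
        )
        blocks.extend([left, right])

    rng = np.random.default_rng(spec.seed)
    order = rng.permutation(len(blocks))
    labels = np.zeros(spec.grid_shape, dtype=np.int32)
    # sort blocks canonically first so the label layout depends only on seed
    blocks.sort()
    for label0, block_idx in enumerate(order):
        sl = tuple(slice(lo, hi) for lo, hi in blocks[block_idx])
        labels[sl] = label0 + 1
    return labels


# --------------------------------------------------------------------------
# expression table
# --------------------------------------------------------------------------

def generate_expression_table(
    atlas: np.ndarray,
    region_means: dict[int, float | dict[str, float]],
    n_donors: int = 6,
    n_probes_per_gene: int = 2,
    probe_sd: float = 0.0,
    donor_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Sample-level GR/MR expression table covering every atlas region.

    Each donor contributes one sampling site per region (two for the lowest
    region label, so multi-sample averaging is exercised), and each site is
    measured by every probe of both genes. A measurement is

        region mean + donor offset (sd donor_sd) + probe noise (sd probe_sd)

    so with zero noise every value equals its region mean exactly.
    ``region_means`` values may be scalars (shared by GR and MR) or
    ``{"GR": g, "MR": m}`` mappings.
    """
    if n_donors < 1:
        raise InvalidSpecError("need at least one donor")
    if n_probes_per_gene < 1:
        raise InvalidSpecError("need at least one probe per gene")
    labels = sorted(int(r) for r in np.unique(atlas) if r != 0)
    missing = set(labels) - set(region_means)
    if missing:
        raise InvalidSpecError(f"region_means missing regions {sorted(missing)}")
    rng = np.random.default_rng(seed)

    def mean_for(region: int, gene: str) -> float:
        m = region_means[region]
        return float(m[gene]) if isinstance(m, dict) else float(m)

    multi_sample_region = labels[0]
    rows = []
    for d in range(n_donors):
        donor = f"D{d + 1:02d}"
        donor_offset = {g: rng.normal(0.0, donor_sd) for g in ("GR", "MR")}
        for region in labels:
            n_sites = 2 if region == multi_sample_region else 1
            for _site in range(n_sites):
                for gene in ("GR", "MR"):
                    for p in range(n_probes_per_gene):
                        value = (
                            mean_for(region, gene)
                            + donor_offset[gene]
                            + rng.normal(0.0, probe_sd)
                        )
                        rows.append(
                            {
                                "donor_id": donor,
                                "probe_id": f"{gene}_probe{p + 1}",
                                "gene": gene,
                                "region_label": region,
                                "expression": value,
                            }
                        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# cohort: covariates + cortisol sampling series
# --------------------------------------------------------------------------

def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, size: int
) -> np.ndarray:
    """Normal draws truncated below at 0 (a CAR magnitude cannot be negative)."""
    if sd == 0:
        return np.full(size, max(mean, 0.0))
    a = (0.0 - mean) / sd
    return stats.truncnorm.rvs(
        a, np.inf, loc=mean, scale=sd, size=size, random_state=rng
    )


def _triple_from_auc_i(
    auc_i: float, c0: float
) -> tuple[float, float, float]:
    """A concentration triple whose AUCi equals ``auc_i`` with baseline c0.

    Uses a rise-then-partial-decline shape: c30 = c0 + d, c60 = c0 + d/2
    with d = auc_i / 37.5, so Delta30 >= 0 whenever auc_i >= 0 and
    15*(c0 + 2*c30 + c60) - 60*c0 = 37.5*d = auc_i exactly.
    """
    d = auc_i / 37.5
    return c0, c0 + d, c0 + d / 2.0


def generate_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Subject covariate table and long-format cortisol sample table.

    AUCi values are drawn per group from the spec's distributions (truncated
    at 0), converted to consistent concentration triples, then the requested
    QC failures are planted on distinct subjects (UHR first) by corrupting
    one sample each: volume below the 200 µl floor, a 30-min sample 25 min
    late, a negative Delta30, or a dropped 60-min sample. If
    ``outlier_value`` is set, the first UHR subject's AUC is replaced by it.
    Transition flags go to the ``n_transition`` UHR subjects with the lowest
    drawn AUC (or at random with ``transition_assignment='random'``).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    n_total = spec.n_uhr + spec.n_control
    subject_ids = [f"UHR-{i + 1:03d}" for i in range(spec.n_uhr)] + [
        f"CTL-{i + 1:03d}" for i in range(spec.n_control)
    ]
    group = np.array([1] * spec.n_uhr + [0] * spec.n_control)

    auc = np.concatenate(
        [
            _truncated_normal(rng, spec.car_mean_uhr, spec.car_sd_uhr, spec.n_uhr),
            _truncated_normal(
                rng, spec.car_mean_control, spec.car_sd_control, spec.n_control
            ),
        ]
    )
    if spec.outlier_value is not None:
        if spec.n_uhr < 1:
            raise InvalidSpecError("outlier requested but no UHR subjects")
        auc[0] = spec.outlier_value

    age = rng.uniform(*spec.age_range, size=n_total).round(1)
    gender = rng.integers(0, 2, size=n_total)
    antidep = np.zeros(n_total, dtype=int)
    if spec.n_uhr:
        antidep[: spec.n_uhr] = (
            rng.random(spec.n_uhr) < spec.antidep_fraction
        ).astype(int)

    transition = np.zeros(n_total, dtype=int)
    if spec.n_transition:
        uhr_idx = np.arange(spec.n_uhr)
        if spec.transition_assignment == "lowest":
            chosen = uhr_idx[np.argsort(auc[: spec.n_uhr], kind="stable")][
                : spec.n_transition
            ]
        else:
            chosen = rng.choice(uhr_idx, size=spec.n_transition, replace=False)
        transition[chosen] = 1

    covariates = pd.DataFrame(
        {
            "subject_id": subject_ids,
            "group": group,
            "age": age,
            "gender": gender,
            "antidepressant": antidep,
            "transition": transition,
        }
    )

    # clean sampling series
    c0s = rng.uniform(4.0, 12.0, size=n_total)
    jitter = rng.uniform(-5.0, 5.0, size=(n_total, 3))
    volumes = rng.uniform(300.0, 600.0, size=(n_total, 3))
    rows = []
    for i, sid in enumerate(subject_ids):
        c0, c30, c60 = _triple_from_auc_i(auc[i], c0s[i])
        for j, (t, c) in enumerate(zip((0, 30, 60), (c0, c30, c60))):
            rows.append(
                {
                    "subject_id": sid,
                    "nominal_time_min": t,
                    "actual_time_min": round(t + jitter[i, j], 1),
                    "volume_ul": round(volumes[i, j], 1),
                    "cortisol_nmol_l": c,
                }
            )
    samples = pd.DataFrame(rows)

    # plant QC failures on distinct subjects, from the end of the UHR block
    # backwards then through the controls (keeps subject 0 free for the
    # outlier and low-AUC transition structure intact at the front)
    fail_order = list(range(spec.n_uhr - 1, -1, -1)) + list(
        range(n_total - 1, spec.n_uhr - 1, -1)
    )
    fail_targets = fail_order[: spec.n_qc_fail_total]
    cursor = 0

    def take(n: int) -> list[int]:
        nonlocal cursor
        out = fail_targets[cursor : cursor + n]
        cursor += n
        return out

    def row_mask(subject_idx: int, t: int) -> pd.Series:
        return (samples["subject_id"] == subject_ids[subject_idx]) & (
            samples["nominal_time_min"] == t
        )

    for idx in take(spec.n_qc_fail_volume):
        samples.loc[row_mask(idx, 30), "volume_ul"] = 150.0
    for idx in take(spec.n_qc_fail_timing):
        samples.loc[row_mask(idx, 30), "actual_time_min"] = 30.0 + 25.0
    for idx in take(spec.n_qc_fail_delta30):
        c0 = float(samples.loc[row_mask(idx, 0), "cortisol_nmol_l"].iloc[0])
        samples.loc[row_mask(idx, 30), "cortisol_nmol_l"] = 0.8 * c0 - 0.5
    for idx in take(spec.n_qc_fail_missing):
        samples = samples[~row_mask(idx, 60)]

    return covariates, samples.reset_index(drop=True)


# --------------------------------------------------------------------------
# grey-matter volume images
# --------------------------------------------------------------------------

def generate_gmv_images(
    covariates: pd.DataFrame,
    car_values: np.ndarray | pd.Series,
    atlas: np.ndarray,
    effects: EffectSpec,
    voxel_size: float = 2.0,
    seed: int = 0,
) -> list[VolumetricImage]:
    """Forward model: one modulated GMV volume per subject.

    Voxel value = region baseline + region slope * CAR + covariate terms
    + interaction slope * CAR (UHR subjects in interaction regions)
    + i.i.d. Gaussian noise. ``covariates`` rows define the subjects (one
    volume each, aligned with ``car_values``).
    """
    atlas = np.asarray(atlas)
    labels = set(int(r) for r in np.unique(atlas) if r != 0)
    effects.validate(labels)
    car_values = np.asarray(car_values, dtype=float)
    if car_values.shape != (len(covariates),):
        raise GeometryError("car_values length does not match covariate rows")
    rng = np.random.default_rng(seed)

    slope_grid = np.zeros(atlas.shape)
    for r in effects.effect_regions:
        slope_grid[atlas == r] = effects.slope_per_region
    inter_grid = np.zeros(atlas.shape)
    for r in effects.interaction_regions:
        inter_grid[atlas == r] = effects.interaction_slope_delta
    baseline = np.where(atlas > 0, effects.baseline_per_region, 0.0)

    images_list = []
    for i, row in enumerate(covariates.itertuples(index=False)):
        cov_term = sum(
            beta * float(getattr(row, name))
            for name, beta in effects.covariate_betas.items()
        )
        vol = (
            baseline
            + slope_grid * car_values[i]
            + inter_grid * car_values[i] * float(row.group)
            + cov_term
        )
        if effects.noise_sd > 0:
            vol = vol + rng.normal(0.0, effects.noise_sd, size=atlas.shape)
        images_list.append(VolumetricImage(values=vol, voxel_size=voxel_size))
    return images_list


# --------------------------------------------------------------------------
# full study scenario
# --------------------------------------------------------------------------

#: GR/MR region means (arbitrary normalized units) for the 8-region demo
#: grid: a clear expression gradient so ranks are unambiguous.
STUDY_REGION_MEANS = {1: 20.0, 2: 19.0, 3: 18.0, 4: 14.0, 5: 13.0, 6: 12.0,
                      7: 11.0, 8: 10.0}

#: the three highest-expression regions carry the planted CAR effect
STUDY_EFFECT_REGIONS = frozenset({1, 2, 3})


def generate_study_dataset(
    seed: int = 0,
    cohort_spec: CohortSpec | None = None,
    effects: EffectSpec | None = None,
    atlas_spec: AtlasSpec | None = None,
) -> dict:
    """One complete synthetic study on the published cohort conditions.

    Defaults: 22 UHR + 17 control subjects with the published CAR group
    distributions, a 16^3 grid of 2 mm voxels split into 8 regions, an
    expression gradient making regions 1-3 the receptor-richest, and a
    positive CAR->GMV slope of 0.05 GMV units per nmol*min/l planted in
    those three regions over Gaussian noise (sd 10).

    Returns a dict with keys covariates, samples, expression, atlas,
    images (subject_id -> VolumetricImage), effects, and car_truth (the
    drawn AUCi values used by the forward model).
    """
    atlas_spec = atlas_spec or AtlasSpec(seed=0)
    cohort_spec = cohort_spec or CohortSpec(seed=seed)
    effects = effects or EffectSpec(
        effect_regions=STUDY_EFFECT_REGIONS,
        slope_per_region=0.05,
        noise_sd=10.0,
    )
    atlas = generate_atlas(atlas_spec)
    labels = sorted(int(r) for r in np.unique(atlas) if r != 0)
    region_means = (
        STUDY_REGION_MEANS
        if set(labels) == set(STUDY_REGION_MEANS)
        else {r: 20.0 - i for i, r in enumerate(labels)}
    )
    expression = generate_expression_table(
        atlas, region_means, probe_sd=0.5, donor_sd=0.5, seed=seed + 1
    )
    covariates, samples = generate_cohort(cohort_spec)

    # CAR values as the analysis will see them (recomputed from the series)
    from .car import car_table, series_from_table

    table = car_table(series_from_table(samples))
    retained = covariates[
        covariates["subject_id"].isin(table.loc[table["qc_pass"], "subject_id"])
    ].reset_index(drop=True)
    car_vals = (
        table.set_index("subject_id")
        .loc[retained["subject_id"], "auc_i"]
        .to_numpy(dtype=float)
    )
    image_list = generate_gmv_images(
        retained, car_vals, atlas, effects,
        voxel_size=atlas_spec.voxel_size, seed=seed + 2,
    )
    images = dict(zip(retained["subject_id"], image_list))
    return {
        "covariates": covariates,
        "samples": samples,
        "expression": expression,
        "atlas": atlas,
        "images": images,
        "effects": effects,
        "car_truth": dict(zip(retained["subject_id"], car_vals)),
    }
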