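"""Generators: seeded determinism, planted structure, forward-model recovery."""

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage

from stress_vbm import (
    AtlasSpec,
    CohortSpec,
    EffectSpec,
    car_table,
    generate_atlas,
    generate_cohort,
    generate_expression_table,
    generate_gmv_images,
    pooled_t_test_values,
    series_from_table,
)
from stress_vbm.exceptions import InvalidSpecError

from conftest import CONTROLS, UHR_FULL


class TestAtlas:
    def test_seeded_determinism(self):
        spec = AtlasSpec(grid_shape=(12, 12, 12), n_regions=6, seed=7)
        assert np.array_equal(generate_atlas(spec), generate_atlas(spec))

    def test_exact_label_set_and_full_coverage(self, small_atlas):
        assert sorted(np.unique(small_atlas)) == [1, 2, 3, 4, 5, 6]
        assert (small_atlas > 0).all()

    def test_regions_are_connected(self, small_atlas):
        for label in np.unique(small_atlas):
            _lab, n = ndimage.label(small_atlas == label)
            assert n == 1

    def test_pigeonhole_error(self):
        with pytest.raises(InvalidSpecError):
            generate_atlas(AtlasSpec(grid_shape=(2, 2, 2), n_regions=9))

    def test_different_seeds_permute_labels(self):
        a = generate_atlas(AtlasSpec(grid_shape=(8, 8, 8), n_regions=4, seed=1))
        b = generate_atlas(AtlasSpec(grid_shape=(8, 8, 8), n_regions=4, seed=2))
        assert sorted(np.unique(a)) == sorted(np.unique(b))


class TestExpressionTable:
    def test_zero_noise_values_equal_region_means(self, small_atlas):
        means = {int(r): 5.0 + r for r in np.unique(small_atlas)}
        df = generate_expression_table(small_atlas, means, n_donors=6)
        for region, grp in df.groupby("region_label"):
            assert (grp["expression"] == means[int(region)]).all()

    def test_structure_exercises_averaging_paths(self, small_atlas):
        means = {int(r): 1.0 for r in np.unique(small_atlas)}
        df = generate_expression_table(small_atlas, means, n_donors=3)
        assert set(df["gene"]) == {"GR", "MR"}
        # every region sampled by every donor; some region has >1 site
        per = df.groupby(["region_label", "donor_id"]).size().unstack()
        assert per.notna().all().all()
        sites = df.groupby(["region_label", "donor_id", "probe_id"]).size()
        assert (sites > 1).any()
        # more than one probe per gene
        assert df.groupby("gene")["probe_id"].nunique().min() > 1

    def test_seeded_determinism(self, small_atlas):
        means = {int(r): 2.0 for r in np.unique(small_atlas)}
        a = generate_expression_table(small_atlas, means, probe_sd=1.0, seed=4)
        b = generate_expression_table(small_atlas, means, probe_sd=1.0, seed=4)
        assert a.to_csv() == b.to_csv()

    def test_region_mean_recovered_with_many_donors(self, small_atlas):
        # law of large numbers: the per-region sample mean approaches the
        # region mean within 3 standard errors at n_donors = 200
        means = {int(r): 10.0 for r in np.unique(small_atlas)}
        probe_sd, donor_sd, n_donors = 2.0, 1.0, 200
        df = generate_expression_table(
            small_atlas, means, n_donors=n_donors,
            probe_sd=probe_sd, donor_sd=donor_sd, seed=8,
        )
        grp = df[df["region_label"] == 2]
        observed = grp["expression"].mean()
        n = len(grp)
        # donor offsets are shared within a donor: se dominated by donor term
        se = np.sqrt(donor_sd**2 / n_donors + probe_sd**2 / n)
        assert abs(observed - 10.0) < 3 * se

    def test_invalid_donor_count(self, small_atlas):
        with pytest.raises(InvalidSpecError):
            generate_expression_table(small_atlas, {1: 1.0}, n_donors=0)


class TestCohort:
    def test_planted_qc_failures_recovered_exactly(self):
        spec = CohortSpec(
            n_qc_fail_volume=2,
            n_qc_fail_timing=1,
            n_qc_fail_delta30=2,
            n_qc_fail_missing=1,
            seed=3,
        )
        _cov, samples = generate_cohort(spec)
        table = car_table(series_from_table(samples))
        reasons = table.loc[~table["qc_pass"], "qc_reasons"]
        counts = reasons.value_counts()
        assert counts.get("low_volume", 0) == 2
        assert counts.get("timing_deviation", 0) == 1
        assert counts.get("negative_delta30", 0) == 2
        assert counts.get("missing_sample", 0) == 1
        assert table["qc_pass"].sum() == len(table) - 6

    def test_planted_volume_failures_are_below_floor(self):
        _cov, samples = generate_cohort(CohortSpec(n_qc_fail_volume=2, seed=1))
        n_low = (
            samples.groupby("subject_id")["volume_ul"].min() < 200
        ).sum()
        assert n_low == 2

    def test_zero_sd_collapses_to_group_mean(self):
        spec = CohortSpec(
            car_sd_uhr=0.0, car_sd_control=0.0, seed=5,
            car_mean_uhr=200.0, car_mean_control=300.0,
        )
        cov, samples = generate_cohort(spec)
        table = car_table(series_from_table(samples)).merge(cov, on="subject_id")
        uhr = table.loc[table["group"] == 1, "auc_i"]
        ctl = table.loc[table["group"] == 0, "auc_i"]
        assert np.allclose(uhr, 200.0) and np.allclose(ctl, 300.0)

    def test_outlier_planted_on_uhr_subject(self):
        cov, samples = generate_cohort(CohortSpec(outlier_value=928.4, seed=2))
        table = car_table(series_from_table(samples)).merge(cov, on="subject_id")
        uhr_auc = table.loc[table["group"] == 1, "auc_i"].to_numpy()
        assert np.isclose(uhr_auc, 928.4).any()

    def test_transition_flags_lowest_auc_uhr(self):
        cov, samples = generate_cohort(CohortSpec(n_transition=4, seed=6))
        table = car_table(series_from_table(samples)).merge(cov, on="subject_id")
        uhr = table[table["group"] == 1].sort_values("auc_i")
        assert uhr.head(4)["transition"].sum() == 4
        assert uhr.iloc[4:]["transition"].sum() == 0

    def test_infeasible_spec_rejected(self):
        with pytest.raises(InvalidSpecError):
            generate_cohort(CohortSpec(n_uhr=2, n_control=1, n_qc_fail_volume=4))
        with pytest.raises(InvalidSpecError):
            generate_cohort(CohortSpec(n_uhr=3, n_transition=5))

    def test_seeded_determinism(self):
        a_cov, a_samp = generate_cohort(CohortSpec(seed=9))
        b_cov, b_samp = generate_cohort(CohortSpec(seed=9))
        assert a_cov.to_csv() == b_cov.to_csv()
        assert a_samp.to_csv() == b_samp.to_csv()

    def test_group_t_statistic_centred_on_study_value(self):
        # Monte-Carlo around the printed summary statistics: with the study
        # group sizes/means/SDs the pooled t should centre near -1.24
        ts = []
        for seed in range(200):
            cov, samples = generate_cohort(CohortSpec(seed=seed))
            table = car_table(series_from_table(samples)).merge(
                cov, on="subject_id"
            )
            uhr = table.loc[table["group"] == 1, "auc_i"].to_numpy()
            ctl = table.loc[table["group"] == 0, "auc_i"].to_numpy()
            ts.append(pooled_t_test_values(uhr, ctl).t_statistic)
        target = -1.24
        assert abs(np.mean(ts) - target) < 0.3
        assert CohortSpec().n_uhr == UHR_FULL[2] and CohortSpec().n_control == CONTROLS[2]


class TestGmvImages:
    def test_noise_free_slope_recovered_exactly(self, small_atlas):
        rng = np.random.default_rng(0)
        n = 10
        cov = pd.DataFrame(
            {
                "subject_id": [f"S{i}" for i in range(n)],
                "group": [1] * 5 + [0] * 5,
                "age": rng.uniform(18, 30, n),
                "gender": rng.integers(0, 2, n),
                "antidepressant": rng.integers(0, 2, n),
                "transition": 0,
            }
        )
        car = rng.uniform(0, 500, n)
        effects = EffectSpec(
            effect_regions=frozenset({5}), slope_per_region=3.0, noise_sd=0.0
        )
        imgs = generate_gmv_images(cov, car, small_atlas, effects, seed=1)
        stack = np.stack([im.values for im in imgs])
        voxels = stack[:, small_atlas == 5]
        slopes = np.polyfit(car, voxels, 1)[0]
        assert np.allclose(slopes, 3.0, atol=1e-10)
        other = stack[:, small_atlas == 2]
        assert np.allclose(np.polyfit(car, other, 1)[0], 0.0, atol=1e-10)

    def test_seeded_determinism(self, small_atlas):
        rng = np.random.default_rng(0)
        cov = pd.DataFrame(
            {
                "subject_id": ["A", "B", "C"],
                "group": [1, 0, 0],
                "age": [20.0, 25.0, 22.0],
                "gender": [0, 1, 0],
                "antidepressant": [0, 0, 1],
                "transition": 0,
            }
        )
        car = rng.uniform(0, 300, 3)
        effects = EffectSpec(noise_sd=5.0)
        a = generate_gmv_images(cov, car, small_atlas, effects, seed=7)
        b = generate_gmv_images(cov, car, small_atlas, effects, seed=7)
        for x, y in zip(a, b):
            assert np.array_equal(x.values, y.values)

    def test_mismatched_car_length(self, small_atlas):
        cov = pd.DataFrame(
            {
                "subject_id": ["A"],
                "group": [1],
                "age": [20.0],
                "gender": [0],
                "antidepressant": [0],
                "transition": [0],
            }
        )
        with pytest.raises(Exception):
            generate_gmv_images(
                cov, np.array([1.0, 2.0]), small_atlas, EffectSpec(), seed=0
            )

    def test_unknown_effect_region_rejected(self, small_atlas):
        cov = pd.DataFrame(
            {
                "subject_id": ["A"],
                "group": [1],
                "age": [20.0],
                "gender": [0],
                "antidepressant": [0],
                "transition": [0],
            }
        )
        with pytest.raises(InvalidSpecError):
            generate_gmv_images(
                cov,
                np.array([1.0]),
                small_atlas,
                EffectSpec(effect_regions=frozenset({99})),
                seed=0,
            )
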