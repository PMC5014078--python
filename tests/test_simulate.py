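"""Generator tests: atlases, lesions, score model, cohort assembly."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lesionprog import generate_atlas, generate_cohort, generate_lesion_masks, generate_scores
from lesionprog.encoding import largest_component_volume, lesion_load
from lesionprog.simulate import (
    GROUP_A,
    GROUP_B,
    ScoreScale,
    SimulationConfig,
    TerritoryParams,
    _draw_demographics,
    draw_task_weights,
)

from conftest import small_config


class TestGenerateAtlas:
    def test_disjoint_partition_covers_grid(self):
        atlas = generate_atlas((10, 10, 10), 5, overlap_fraction=0.0, seed=1)
        assert atlas.n_regions == 5
        all_idx = np.concatenate([idx for _, idx in atlas.regions])
        assert len(all_idx) == 1000  # a partition: every voxel exactly once
        assert len(np.unique(all_idx)) == 1000
        assert all(idx.size > 0 for _, idx in atlas.regions)

    def test_full_scale_region_count(self):
        atlas = generate_atlas(n_regions=199, seed=5)
        assert atlas.n_regions == 199
        assert len(set(atlas.region_names)) == 199

    def test_deterministic_given_seed(self):
        a1 = generate_atlas((8, 8, 8), 7, 0.3, seed=42)
        a2 = generate_atlas((8, 8, 8), 7, 0.3, seed=42)
        assert a1.region_names == a2.region_names
        for (_, i1), (_, i2) in zip(a1.regions, a2.regions):
            np.testing.assert_array_equal(i1, i2)

    def test_overlap_produces_overlapping_regions(self):
        atlas = generate_atlas((8, 8, 8), 10, overlap_fraction=0.8, seed=0)
        total = sum(idx.size for _, idx in atlas.regions)
        assert total > 512  # union over-counts ⇒ some voxel in >1 region

    def test_grid_too_small(self):
        with pytest.raises(ValueError, match="cannot host"):
            generate_atlas((2, 2, 2), 100, 0.0, seed=0)


class TestGenerateLesionMasks:
    def test_single_component_above_1cm3(self):
        atlas = generate_atlas((10, 12, 10), 8, 0.0, seed=3, voxel_volume=125.0)
        masks = generate_lesion_masks(atlas, 12, seed=7)
        from scipy import ndimage

        for m in masks:
            labels, n = ndimage.label(m, structure=np.ones((3, 3, 3)))
            assert n == 1  # one contiguous lesion
            assert largest_component_volume(m, 125.0) >= 1000.0

    def test_territory_clustering(self):
        atlas = generate_atlas((12, 12, 12), 8, 0.0, seed=0, voxel_volume=125.0)
        params = TerritoryParams(
            count=2, spread=1.0, centers=((3, 3, 3), (9, 9, 9)),
            volume_range_mm3=(1000.0, 4000.0),
        )
        masks = generate_lesion_masks(atlas, 200, params, seed=11)
        freq = masks.mean(axis=0)
        coords = np.indices((12, 12, 12)).reshape(3, -1).T
        centers = np.array([[3, 3, 3], [9, 9, 9]])
        dist = np.min(
            np.linalg.norm(coords[:, None, :] - centers[None], axis=2), axis=1
        ).reshape(12, 12, 12)
        inside, outside = freq[dist <= 3.0], freq[dist > 3.0]
        # two-proportion comparison of voxel lesion frequency
        n_in, n_out = inside.size * 200, outside.size * 200
        k_in, k_out = inside.sum() * 200, outside.sum() * 200
        p_pool = (k_in + k_out) / (n_in + n_out)
        se = np.sqrt(p_pool * (1 - p_pool) * (1 / n_in + 1 / n_out))
        z = (k_in / n_in - k_out / n_out) / se
        assert z > 5.0

    def test_deterministic(self):
        atlas = generate_atlas((8, 8, 8), 4, 0.0, seed=1, voxel_volume=125.0)
        m1 = generate_lesion_masks(atlas, 5, seed=9)
        m2 = generate_lesion_masks(atlas, 5, seed=9)
        np.testing.assert_array_equal(m1, m2)

    def test_center_outside_grid_rejected(self):
        atlas = generate_atlas((8, 8, 8), 4, 0.0, seed=1, voxel_volume=125.0)
        params = TerritoryParams(count=1, centers=((20, 0, 0),))
        with pytest.raises(ValueError, match="outside grid"):
            generate_lesion_masks(atlas, 2, params, seed=0)


class TestGenerateScores:
    def _setup(self, **cfg_kw):
        kw = dict(noise_sd=0.0, missing_rate=0.0)
        kw.update(cfg_kw)
        config = small_config(**kw)
        rng = np.random.default_rng(0)
        demo = pd.concat(
            [
                _draw_demographics(30, GROUP_A, rng),
                _draw_demographics(30, GROUP_B, rng, start=100),
            ]
        )
        loads = pd.DataFrame(
            rng.uniform(0, 60, size=(60, config.n_regions)),
            index=demo.index,
        )
        weights = draw_task_weights(config, rng)
        return config, demo, loads, weights

    def test_noiseless_scores_exactly_affine(self):
        config, demo, loads, weights = self._setup()
        scores = generate_scores(loads, demo, config, scale=None, weights=weights, seed=1)
        # refit task 0 on group a by least squares: recovers true weights
        ia = demo["group"] == GROUP_A
        X = np.column_stack(
            [
                loads.loc[ia].to_numpy(),
                demo.loc[ia, "time_post_stroke_months"],
                demo.loc[ia, "age_at_stroke_years"],
            ]
        )
        y = scores.loc[ia].iloc[:, 0].to_numpy()
        beta, *_ = np.linalg.lstsq(np.column_stack([np.ones(len(y)), X]), y, rcond=None)
        w = weights[0]
        expected = np.concatenate(
            [[w.intercept], w.region_weights, [w.time_weight, w.age_weight]]
        )
        np.testing.assert_allclose(beta, expected, atol=1e-8)

    def test_lambda_lowers_group_b_scores_at_fixed_loads(self):
        config, demo, loads, weights = self._setup(lambda_sensitivity=1.5)
        scores = generate_scores(loads, demo, config, scale=None, weights=weights, seed=1)
        cfg_null = small_config(noise_sd=0.0, missing_rate=0.0)
        base = generate_scores(loads, demo, cfg_null, scale=None, weights=weights, seed=1)
        ib = demo["group"] == GROUP_B
        diff = (scores.loc[ib] - base.loc[ib]).to_numpy()
        for t, w in enumerate(weights):
            hit = loads.loc[ib].to_numpy() @ np.abs(w.region_weights) > 0
            assert (diff[hit, t] < 0).all()  # strictly lower where damaged
            assert (diff[:, t] <= 1e-12).all()
        ia = demo["group"] == GROUP_A
        np.testing.assert_allclose(scores.loc[ia], base.loc[ia])

    def test_null_groups_exchangeable(self):
        """With lambda=1, delta=0 the group label carries no information:
        a two-sample test on residual scores is null-calibrated."""
        config, demo, loads, weights = self._setup(noise_sd=3.0)
        rejections = 0
        n_rep = 200
        for rep in range(n_rep):
            scores = generate_scores(loads, demo, config, scale=None, weights=weights, seed=rep)
            expected = generate_scores(
                loads, demo, small_config(noise_sd=0.0, missing_rate=0.0),
                scale=None, weights=weights, seed=0,
            )
            resid = (scores - expected).iloc[:, 0]
            ia, ib = demo["group"] == GROUP_A, demo["group"] == GROUP_B
            _, p = stats.ttest_ind(resid[ia], resid[ib])
            rejections += p < 0.05
        assert rejections / n_rep < 0.105  # ≈5% nominal, binomial slack

    def test_missing_rate(self):
        config, demo, loads, weights = self._setup()
        config.missing_rate = 0.2
        # 60 patients x 4 tasks = 240 entries per draw; pool several seeds
        # to reach >1000 draws for the binomial 99% interval
        frac = []
        for s in range(5):
            sc = generate_scores(loads, demo, config, scale=None, weights=weights, seed=s)
            frac.append(sc.isna().to_numpy().mean())
        observed = np.mean(frac)
        assert 0.17 <= observed <= 0.23

    def test_dimension_mismatch(self):
        config, demo, loads, weights = self._setup()
        with pytest.raises(ValueError, match="regions"):
            generate_scores(loads.iloc[:, :3], demo, config, scale=None, weights=weights)


class TestScoreScale:
    def test_reference_sample_t_scores_mean50_sd10(self, rng):
        raw = rng.normal(37.0, 6.3, size=60)
        scale = ScoreScale(
            reference_mean=float(raw.mean()),
            reference_sd=float(raw.std(ddof=1)),
            impairment_cutoff=30.0,
        )
        t = np.asarray(scale.to_t(raw))
        assert abs(t.mean() - 50.0) < 1e-9
        assert abs(t.std(ddof=1) - 10.0) < 1e-9

    def test_positive_sd_required(self):
        with pytest.raises(ValueError):
            ScoreScale(reference_mean=0.0, reference_sd=0.0, impairment_cutoff=0.0)


class TestGenerateCohort:
    def test_default_group_sizes(self):
        # structure check only: tiny geometry, default group sizes
        config = small_config(n_group_a=174, n_group_b=33)
        cohort = generate_cohort(config)
        assert (cohort.demographics["group"] == GROUP_A).sum() == 174
        assert (cohort.demographics["group"] == GROUP_B).sum() == 33

    def test_small_counts(self):
        cohort = generate_cohort(small_config(n_group_a=10, n_group_b=5))
        assert len(cohort.patients) == 15

    def test_reproducible(self):
        c1 = generate_cohort(small_config(missing_rate=0.1))
        c2 = generate_cohort(small_config(missing_rate=0.1))
        pd.testing.assert_frame_equal(c1.scores, c2.scores)
        pd.testing.assert_frame_equal(c1.loads, c2.loads)
        pd.testing.assert_frame_equal(c1.demographics, c2.demographics)
        pd.testing.assert_frame_equal(c1.history, c2.history)

    def test_cohort_satisfies_inclusion_rules(self, null_cohort):
        assert (null_cohort.demographics["time_post_stroke_months"] >= 3).all()
        assert (null_cohort.lesion_volume >= 1000.0).all()

    def test_native_scores_group_b_only(self, null_cohort):
        native = null_cohort.native_scores
        a_idx = null_cohort.group_index(GROUP_A)
        assert native.loc[a_idx].isna().all().all()
        b_idx = null_cohort.group_index(GROUP_B)
        assert native.loc[b_idx].notna().any().any()

    def test_loads_in_percent_range(self, null_cohort):
        assert (null_cohort.loads.to_numpy() >= 0).all()
        assert (null_cohort.loads.to_numpy() <= 100).all()

    def test_history_fields_present_for_group_b(self, null_cohort):
        b_idx = null_cohort.group_index(GROUP_B)
        hist = null_cohort.history.loc[b_idx]
        assert hist.notna().sum().sum() > 0


class TestCohortRoundTrip:
    def test_write_read_identical_loads(self, tmp_path):
        from lesionprog.simulate import read_cohort, write_cohort

        cohort = generate_cohort(
            small_config(n_group_a=6, n_group_b=3, n_regions=5), keep_masks=True
        )
        write_cohort(cohort, tmp_path / "cohort")
        loaded = read_cohort(tmp_path / "cohort")
        pd.testing.assert_frame_equal(loaded.loads, cohort.loads)
        pd.testing.assert_series_equal(loaded.lesion_volume, cohort.lesion_volume)
        pd.testing.assert_frame_equal(loaded.scores, cohort.scores, check_exact=False)
        assert loaded.seed == cohort.seed
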