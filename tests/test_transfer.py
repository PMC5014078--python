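"""Transfer predictions, group tests, permutation threshold, screens."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lesionprog import pipeline
from lesionprog.simulate import GROUP_A, GROUP_B, generate_scores
from lesionprog.transfer import (
    PermutationNull,
    errors_by_task,
    history_screen,
    independent_t,
    levene_test,
    paired_t,
    permutation_familywise_threshold,
    random_model_consistency,
    shift_tests,
    t_from_summary,
    transfer_predict,
    wilcoxon_rank_sum,
)

from conftest import small_config


class TestIndependentT:
    def test_summary_age_comparison(self):
        t, p = t_from_summary(174, 53.0, 12.2, 33, 49.0, 13.2)
        assert abs(t - 1.68) < 0.05
        assert 0.05 < p < 0.15

    def test_summary_time_comparison(self):
        t, p = t_from_summary(174, 55.6, 62.6, 33, 49.2, 55.8)
        assert abs(t - 0.54) < 0.05

    def test_identical_samples_zero(self, rng):
        x = rng.normal(size=20)
        t, p = independent_t(x, x.copy())
        assert t == pytest.approx(0.0, abs=1e-12)

    def test_matches_scipy_welch(self, rng):
        a, b = rng.normal(size=25), rng.normal(1, 2, size=18)
        t, p = independent_t(a, b, equal_var=False)
        ref = stats.ttest_ind(a, b, equal_var=False)
        assert np.isclose(t, ref.statistic) and np.isclose(p, ref.pvalue)

    def test_zero_pooled_variance(self):
        with pytest.raises(ValueError, match="pooled variance"):
            independent_t(np.ones(5), np.zeros(5))


class TestLevene:
    def test_identical_samples(self, rng):
        x = rng.normal(size=15)
        f, p = levene_test(x, x.copy())
        assert f == pytest.approx(0.0, abs=1e-12)

    def test_null_calibration(self, rng):
        rejections = 0
        for _ in range(1000):
            a, b = rng.normal(size=25), rng.normal(size=25)
            _, p = levene_test(a, b)
            rejections += p < 0.05
        assert 0.03 <= rejections / 1000 <= 0.07

    def test_detects_scale_difference(self, rng):
        a, b = rng.normal(size=200), 3.0 * rng.normal(size=200)
        _, p = levene_test(a, b)
        assert p < 0.01

    def test_constant_inputs_rejected(self):
        with pytest.raises(ValueError):
            levene_test(np.ones(5), np.ones(5))


class TestWilcoxonRankSum:
    def test_null_mean_z_near_zero(self, rng):
        zs = [
            wilcoxon_rank_sum(rng.normal(size=12), rng.normal(size=12))[0]
            for _ in range(2000)
        ]
        assert abs(np.mean(zs)) < 0.05

    def test_extreme_ranking_matches_exact_enumeration(self):
        a = np.array([6.0, 7.0, 8.0, 9.0, 10.0])
        b = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        z, p = wilcoxon_rank_sum(a, b, method="exact")
        # all a above all b: 2 of C(10,5)=252 equally likely orderings
        assert p == pytest.approx(2.0 / 252.0)
        assert z > 0

    def test_identical_multisets_z_zero(self):
        x = np.array([1.0, 2.0, 2.0, 3.0])
        z, p = wilcoxon_rank_sum(x, x.copy())
        assert z == pytest.approx(0.0, abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum(np.array([]), np.array([]))


class TestPairedT:
    def test_closed_form(self):
        t, p, m = paired_t(np.array([1.0, 2.0, 3.0]))
        assert m == pytest.approx(2.0)
        assert t == pytest.approx(2.0 * np.sqrt(3.0))

    def test_all_zero_differences_error(self):
        with pytest.raises(ValueError, match="zero-variance"):
            paired_t(np.zeros(10))

    def test_l1_deficit_power(self, rng):
        detected = 0
        for _ in range(100):
            d = rng.normal(-1.0, 1.0, size=20)
            t, p, m = paired_t(d)
            detected += (t < 0) and (m < 0)
        assert detected >= 95


def _null_errors(rng, n_tasks=6, n_a=40, n_b=12):
    ids = [f"a{i}" for i in range(n_a)] + [f"b{i}" for i in range(n_b)]
    groups = pd.Series([GROUP_A] * n_a + [GROUP_B] * n_b, index=pd.Index(ids, name="patient"))
    errs = {
        f"t{j}": pd.Series(rng.normal(size=n_a + n_b), index=groups.index)
        for j in range(n_tasks)
    }
    return errs, groups


class TestPermutationThreshold:
    def test_single_task_corrected_alpha_near_nominal(self, rng):
        errs, groups = _null_errors(rng, n_tasks=1)
        null = permutation_familywise_threshold(errs, groups, n_perm=2000, seed=4)
        assert 0.035 < null.corrected_alpha <= 0.05

    def test_multi_task_bracketed_by_bonferroni_and_nominal(self, rng):
        errs, groups = _null_errors(rng, n_tasks=22, n_a=60, n_b=20)
        null = permutation_familywise_threshold(errs, groups, n_perm=1000, seed=9)
        assert 0.05 / 22 < null.corrected_alpha < 0.05

    def test_correlated_tasks_raise_corrected_alpha(self, rng):
        """Strongly correlated task errors need little correction: the
        corrected alpha approaches the nominal level, far above the
        Bonferroni bound for the family size."""
        ids = [f"a{i}" for i in range(50)] + [f"b{i}" for i in range(18)]
        groups = pd.Series(["a"] * 50 + ["b"] * 18, index=pd.Index(ids, name="patient"))
        shared = rng.normal(size=68)
        errs_corr = {
            f"t{j}": pd.Series(shared + 0.15 * rng.normal(size=68), index=groups.index)
            for j in range(12)
        }
        errs_indep = {
            f"t{j}": pd.Series(rng.normal(size=68), index=groups.index)
            for j in range(12)
        }
        a_corr = permutation_familywise_threshold(errs_corr, groups, 1000, seed=3).corrected_alpha
        a_ind = permutation_familywise_threshold(errs_indep, groups, 1000, seed=3).corrected_alpha
        assert a_corr > 3 * a_ind
        assert a_corr > 0.02

    def test_deterministic(self, rng):
        errs, groups = _null_errors(rng)
        n1 = permutation_familywise_threshold(errs, groups, n_perm=300, seed=11)
        n2 = permutation_familywise_threshold(errs, groups, n_perm=300, seed=11)
        np.testing.assert_array_equal(n1.min_p, n2.min_p)
        assert n1.corrected_alpha == n2.corrected_alpha
        for task in n1.t_samples:
            np.testing.assert_array_equal(n1.t_samples[task], n2.t_samples[task])

    def test_permutation_t_matches_scipy_per_task(self, rng):
        """Vectorized permutation t equals scipy's on each shuffled split."""
        errs, groups = _null_errors(rng, n_tasks=2)
        null = permutation_familywise_threshold(errs, groups, n_perm=5, seed=0)
        # reconstruct the label matrix with the same stream
        check_rng = np.random.default_rng(0)
        is_b = (groups == GROUP_B).to_numpy()
        order = np.argsort(check_rng.random((5, len(groups))), axis=1)
        labels = is_b[order]
        for task, e in errs.items():
            ev = e.to_numpy()
            for j in range(5):
                lb = labels[j]
                ref = stats.ttest_ind(ev[lb], ev[~lb], equal_var=True)
                assert np.isclose(null.t_samples[task][j], ref.statistic)

    def test_small_n_perm_warns(self, rng):
        errs, groups = _null_errors(rng)
        with pytest.warns(UserWarning, match="coarse"):
            permutation_familywise_threshold(errs, groups, n_perm=50, seed=0)


class TestTransferPredict:
    def _cohort_bits(self, null_cohort, null_tables):
        table_a, table_b, scores_a, scores_b = null_tables
        feats = {t: list(table_a.columns[:5]) for t in null_cohort.tasks}
        return feats, table_a, table_b, scores_a, scores_b

    def test_record_shape_and_sign_convention(self, null_cohort, null_tables):
        feats, ta, tb, sa, sb = self._cohort_bits(null_cohort, null_tables)
        rec = transfer_predict(feats, ta, sa, tb, sb)
        assert set(rec.columns) == {"patient", "task", "group", "predicted", "actual", "error"}
        np.testing.assert_allclose(rec["error"], rec["predicted"] - rec["actual"])

    def test_group_b_invariant_to_patient_order(self, null_cohort, null_tables):
        feats, ta, tb, sa, sb = self._cohort_bits(null_cohort, null_tables)
        rec1 = transfer_predict(feats, ta, sa, tb, sb)
        perm = np.random.default_rng(0).permutation(len(tb))
        rec2 = transfer_predict(feats, ta, sa, tb.iloc[perm], sb.iloc[perm])
        b1 = rec1[rec1.group == GROUP_B].set_index(["patient", "task"])["predicted"].sort_index()
        b2 = rec2[rec2.group == GROUP_B].set_index(["patient", "task"])["predicted"].sort_index()
        pd.testing.assert_series_equal(b1, b2)

    def test_header_mismatch_rejected(self, null_cohort, null_tables):
        feats, ta, tb, sa, sb = self._cohort_bits(null_cohort, null_tables)
        with pytest.raises(ValueError, match="header"):
            transfer_predict(feats, ta, sa, tb.iloc[:, ::-1], sb)

    def test_null_transfer_errors_centred(self):
        """lambda=1, delta=0 at large n: group-b mean error stays within
        1 T-unit in >=90% of score replicates."""
        from lesionprog import generate_cohort

        cohort = generate_cohort(
            small_config(n_group_a=80, n_group_b=60, noise_sd=1.5, seed=55)
        )
        cfg = cohort.config
        ta, tb, sa, sb = pipeline.split_tables(cohort)
        w = cohort.true_weights
        task = cohort.tasks[0]
        feats = {task: [cohort.loads.columns[i] for i in w[0].active_regions()]
                 + ["time_post_stroke_months", "age_at_stroke_years"]}
        hits = 0
        n_rep = 100
        for rep in range(n_rep):
            scores = generate_scores(
                cohort.loads, cohort.demographics, cfg,
                scale=cohort.scales, weights=w, seed=10_000 + rep,
            )
            rec = transfer_predict(feats, ta, scores.loc[ta.index], tb, scores.loc[tb.index])
            mb = rec.loc[rec.group == GROUP_B, "error"].mean()
            hits += abs(mb) < 1.0
        assert hits >= 90

    def test_sensitivity_shift_positive_errors(self, shifted_cohort):
        """lambda=1.5: the transfer group's mean error is positive (the
        reference-group model overestimates) in >=95% of replicates."""
        cfg = shifted_cohort.config
        ta, tb, sa, sb = pipeline.split_tables(shifted_cohort)
        w = shifted_cohort.true_weights
        hits = 0
        n_rep = 100
        task = shifted_cohort.tasks[0]
        feats = {task: [shifted_cohort.loads.columns[i] for i in w[0].active_regions()]
                 + ["time_post_stroke_months"]}
        for rep in range(n_rep):
            scores = generate_scores(
                shifted_cohort.loads, shifted_cohort.demographics, cfg,
                scale=shifted_cohort.scales, weights=w, seed=20_000 + rep,
            )
            rec = transfer_predict(feats, ta, scores.loc[ta.index], tb, scores.loc[tb.index])
            hits += rec.loc[rec.group == GROUP_B, "error"].mean() > 0
        assert hits >= 95

    def test_intercept_shift_direction(self):
        """A pure negative premorbid-style shift for group b yields positive
        mean group-b error: the models overestimate."""
        from lesionprog import generate_cohort

        cohort = generate_cohort(
            small_config(intercept_shift=-5.0, noise_sd=1.0, seed=77)
        )
        ta, tb, sa, sb = pipeline.split_tables(cohort)
        feats = {
            t: [cohort.loads.columns[i] for i in w.active_regions()] + ["time_post_stroke_months"]
            for t, w in zip(cohort.tasks, cohort.true_weights)
        }
        rec = transfer_predict(feats, ta, sa, tb, sb)
        mb = rec.loc[rec.group == GROUP_B].groupby("task")["error"].mean()
        assert (mb > 0).all()


class TestShiftTests:
    def test_flags_follow_corrected_alpha(self, shifted_cohort):
        ta, tb, sa, sb = pipeline.split_tables(shifted_cohort)
        feats = {
            t: [shifted_cohort.loads.columns[i] for i in w.active_regions()]
            + ["time_post_stroke_months"]
            for t, w in zip(shifted_cohort.tasks, shifted_cohort.true_weights)
        }
        rec = transfer_predict(feats, ta, sa, tb, sb)
        table = shift_tests(rec, corrected_alpha=0.01)
        assert ((table["p"] <= 0.01) == table["significant"]).all()
        table_unc = shift_tests(rec, corrected_alpha=None)
        assert table_unc["significant"].isna().all()


class TestRandomModelConsistency:
    def test_contract_and_power(self):
        from lesionprog import generate_cohort
        from lesionprog.selection import sample_random_feature_sets

        cohort = generate_cohort(
            small_config(n_group_a=80, n_group_b=40, noise_sd=3.0,
                         lambda_sensitivity=1.5, seed=99)
        )
        ta, tb, sa, sb = pipeline.split_tables(cohort)
        sets = sample_random_feature_sets(40, (2, 12), list(ta.columns), seed=5)
        res = random_model_consistency(
            sets, ta, sa, tb, sb, cohort.tasks[:2], threshold_alpha=0.05
        )
        assert 0.0 <= res.fraction_consistent <= 1.0
        assert res.n_tests == 80
        assert res.n_significant_negative >= 0
        # strong lambda effect: most random models show the same shift
        assert res.fraction_consistent > 0.5

    def test_empty_sets_rejected(self, null_tables, null_cohort):
        ta, tb, sa, sb = null_tables
        with pytest.raises(ValueError):
            random_model_consistency([], ta, sa, tb, sb, null_cohort.tasks[:1])


class TestHistoryScreen:
    def test_null_calibration(self, rng):
        positives, total = 0, 0
        for _ in range(1000):
            hist = pd.DataFrame({"prof": rng.normal(size=30)})
            errs = {"task": pd.Series(rng.normal(size=30), index=hist.index)}
            table, _ = history_screen(hist, errs)
            positives += int((table["p"] < 0.05).sum())
            total += len(table)
        assert 0.03 <= positives / total <= 0.07

    def test_detects_injected_association(self, rng):
        """A history field built to correlate with errors at sample
        r = 0.6 (n = 30) is flagged at p < 0.01."""
        detected = 0
        for _ in range(100):
            x = rng.normal(size=30)
            noise = rng.normal(size=30)
            # residualize and rescale so the sample correlation is exactly 0.6
            xc = (x - x.mean()) / x.std()
            nc = noise - noise.mean()
            nc -= xc * (nc @ xc) / (xc @ xc)
            nc /= nc.std()
            y = 0.6 * xc + np.sqrt(1 - 0.36) * nc
            hist = pd.DataFrame({"prof": x})
            errs = {"task": pd.Series(y, index=hist.index)}
            table, _ = history_screen(hist, errs)
            detected += table["p"].iloc[0] < 0.01
        assert detected >= 90

    def test_insufficient_pairs_skipped_and_logged(self):
        hist = pd.DataFrame({"field": [1.0, np.nan, np.nan, np.nan]})
        errs = {"task": pd.Series([0.1, 0.2, 0.3, 0.4], index=hist.index)}
        table, log = history_screen(hist, errs)
        assert table.empty
        assert any("complete pairs" in entry for entry in log)

    def test_note_attached(self, rng):
        hist = pd.DataFrame({"f": rng.normal(size=10)})
        errs = {"t": pd.Series(rng.normal(size=10), index=hist.index)}
        table, _ = history_screen(hist, errs)
        assert "correction" in table.attrs["note"]
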