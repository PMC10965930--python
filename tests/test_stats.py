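"""Group statistics: ANOVA (raw and from summaries), FDR, Tukey, GLM,
ANCOVA, correlations, assumption checks, table rendering."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from qsmcohort import (GroupSummary, analyze_cohort, ancova_handedness,
                       anova_from_summary, anova_oneway, build_tables,
                       check_assumptions, correlation_screen, fdr_bh,
                       glm_group_volume, reproduce_anova, summarize, tukey_hsd)

GROUPS_123 = np.repeat(["HC", "MDD", "SCZ"], [50, 49, 24])


class TestAnova:
    def test_identical_groups_give_zero_f(self):
        v = np.tile([1.0, 2.0, 3.0], 3)
        g = np.repeat(["a", "b", "c"], 3)
        res = anova_oneway(v, g)
        assert res.f == pytest.approx(0.0)
        assert res.df == (2, 6)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            anova_oneway([1.0, 2.0, 3.0], ["a", "a", "b"])

    def test_matches_scipy_f_oneway(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=GROUPS_123.size)
        res = anova_oneway(v, GROUPS_123)
        ref = sps.f_oneway(v[GROUPS_123 == "HC"], v[GROUPS_123 == "MDD"],
                           v[GROUPS_123 == "SCZ"])
        assert res.f == pytest.approx(ref.statistic, rel=1e-12)
        assert res.p_raw == pytest.approx(ref.pvalue, rel=1e-10)
        assert res.df == (2, GROUPS_123.size - 3)

    def test_raw_equals_summary_path(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            v = rng.normal(10, 3, size=GROUPS_123.size)
            raw = anova_oneway(v, GROUPS_123)
            via_summary = anova_from_summary(summarize(v, GROUPS_123))
            assert via_summary.f == pytest.approx(raw.f, rel=1e-9)
            assert via_summary.p_raw == pytest.approx(raw.p_raw, rel=1e-9)

    def test_summary_requires_two_groups(self):
        with pytest.raises(ValueError, match="2 groups"):
            anova_from_summary(GroupSummary("r", "m", ("a",), (1.0,), (1.0,), (2,)))
        # n=2 per group with 2 groups is fine
        anova_from_summary(GroupSummary("r", "m", ("a", "b"), (1.0, 2.0),
                                        (1.0, 1.0), (2, 2)))


class TestFdrBh:
    def test_single_p_is_unchanged(self):
        np.testing.assert_allclose(fdr_bh([0.03]), [0.03])

    def test_hand_worked_stepup(self):
        np.testing.assert_allclose(fdr_bh([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_all_equal_unchanged(self):
        np.testing.assert_allclose(fdr_bh([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_bh([0.5, 1.5])

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=40))
    def test_matches_statsmodels_and_dominates_raw(self, ps):
        q = fdr_bh(ps)
        ref = multipletests(ps, method="fdr_bh")[1]
        np.testing.assert_allclose(q, ref, atol=1e-12)
        assert (q >= np.asarray(ps) - 1e-15).all()


class TestTukey:
    def test_identical_groups_give_zero_stat_p_one(self):
        v = np.tile([1.0, 2.0, 3.0, 4.0], 2)
        g = np.repeat(["a", "b"], 4)
        (res,) = tukey_hsd(v, g)
        assert res.t == pytest.approx(0.0)
        assert res.p_tukey == pytest.approx(1.0)

    def test_large_shift_detected(self):
        rng = np.random.default_rng(3)
        v = rng.normal(size=150)
        v[100:] += 10.0
        g = np.repeat(["a", "b", "c"], 50)
        results = {r.pair: r for r in tukey_hsd(v, g)}
        assert results["c vs a"].p_tukey < 1e-6
        assert results["c vs b"].p_tukey < 1e-6
        assert results["b vs a"].p_tukey > 0.01

    def test_matches_scipy_tukey_hsd(self):
        rng = np.random.default_rng(4)
        samples = [rng.normal(loc, 1, 30) for loc in (0.0, 0.4, 0.1)]
        v = np.concatenate(samples)
        g = np.repeat(["HC", "MDD", "SCZ"], 30)
        mine = {r.pair: r.p_tukey for r in tukey_hsd(v, g)}
        ref = sps.tukey_hsd(*samples)
        assert mine["MDD vs HC"] == pytest.approx(ref.pvalue[0, 1], abs=1e-6)
        assert mine["SCZ vs HC"] == pytest.approx(ref.pvalue[0, 2], abs=1e-6)
        assert mine["SCZ vs MDD"] == pytest.approx(ref.pvalue[1, 2], abs=1e-6)

    def test_adjusted_p_dominates_plain_t(self):
        rng = np.random.default_rng(5)
        v = rng.normal(size=90)
        g = np.repeat(["a", "b", "c"], 30)
        for r in tukey_hsd(v, g):
            pair = r.pair.split(" vs ")
            t_p = sps.ttest_ind(v[g == pair[0]], v[g == pair[1]]).pvalue
            assert r.p_tukey >= t_p - 1e-12

    def test_double_correction_switch(self):
        rng = np.random.default_rng(6)
        v = rng.normal(size=90)
        g = np.repeat(["a", "b", "c"], 30)
        without = tukey_hsd(v, g, fdr_over_pairs=False)
        assert all(r.p_fdr == r.p_tukey for r in without)
        with_fdr = tukey_hsd(v, g, fdr_over_pairs=True)
        assert all(r.p_fdr >= r.p_tukey - 1e-15 for r in with_fdr)


class TestGlm:
    @staticmethod
    def exact_table(beta, n=400, seed=0):
        rng = np.random.default_rng(seed)
        groups = np.repeat(["HC", "MDD", "SCZ"], [n, n, n])
        vol = rng.normal(size=groups.size)
        vol = (vol - vol.mean()) / vol.std(ddof=1)  # exactly standardized
        X = np.column_stack([
            np.ones(groups.size), groups == "MDD", groups == "SCZ",
            vol, (groups == "MDD") * vol, (groups == "SCZ") * vol,
        ]).astype(float)
        y = X @ beta
        return pd.DataFrame({"region": "r", "group": groups,
                             "susceptibility_ppm": y, "volume_mm3": vol}), y

    def test_noise_free_recovery_is_exact(self):
        beta = np.array([0.1, 0.3, -0.2, 0.4, 0.58, 0.0])
        table, y = self.exact_table(beta)
        res = glm_group_volume(table, "r")
        s_y = y.std(ddof=1)
        expected = beta / s_y
        for i, term in enumerate(["group[MDD]", "group[SCZ]", "volume_z",
                                  "group[MDD]:volume_z", "group[SCZ]:volume_z"]):
            assert res.terms.loc[term, "B"] == pytest.approx(expected[i + 1],
                                                             abs=1e-8)
        assert res.df_resid == res.nobs - 6

    def test_rescaling_volume_units_leaves_outputs_identical(self):
        rng = np.random.default_rng(7)
        table = pd.DataFrame({
            "region": "r",
            "group": GROUPS_123,
            "susceptibility_ppm": rng.normal(0.01, 0.005, GROUPS_123.size),
            "volume_mm3": rng.normal(300, 30, GROUPS_123.size),
        })
        r1 = glm_group_volume(table, "r")
        table2 = table.assign(volume_mm3=table.volume_mm3 / 1000.0)  # -> cm^3
        r2 = glm_group_volume(table2, "r")
        np.testing.assert_allclose(r1.terms["B"], r2.terms["B"], rtol=1e-9)
        np.testing.assert_allclose(r1.terms["t"], r2.terms["t"], rtol=1e-9)

    def test_constant_volume_is_rank_deficient(self):
        rng = np.random.default_rng(8)
        table = pd.DataFrame({
            "region": "r", "group": GROUPS_123,
            "susceptibility_ppm": rng.normal(size=GROUPS_123.size),
            "volume_mm3": np.ones(GROUPS_123.size),
        })
        with pytest.raises(ValueError):
            glm_group_volume(table, "r")

    def test_fdr_within_region_over_five_terms(self):
        rng = np.random.default_rng(9)
        table = pd.DataFrame({
            "region": "r", "group": GROUPS_123,
            "susceptibility_ppm": rng.normal(size=GROUPS_123.size),
            "volume_mm3": rng.normal(size=GROUPS_123.size),
        })
        res = glm_group_volume(table, "r")
        non_int = res.terms.drop(index="Intercept")
        assert non_int["q_fdr"].notna().all()
        assert (non_int["q_fdr"] >= non_int["p_raw"] - 1e-15).all()
        assert np.isnan(res.terms.loc["Intercept", "q_fdr"])


class TestAncova:
    def test_denominator_df_counting(self):
        rng = np.random.default_rng(10)
        hand = rng.choice(["right", "mixed", "left"], GROUPS_123.size,
                          p=[0.8, 0.1, 0.1])
        res = ancova_handedness(rng.normal(size=GROUPS_123.size), GROUPS_123, hand)
        assert res.df == (2, 123 - 5)

    def test_nuisance_covariate_tracks_plain_anova(self):
        rng = np.random.default_rng(11)
        n = 3000
        groups = np.repeat(["HC", "MDD", "SCZ"], n)
        y = rng.normal(size=groups.size) + 0.2 * (groups == "MDD")
        hand = rng.choice(["right", "mixed", "left"], groups.size)
        f_ancova = ancova_handedness(y, groups, hand).f
        f_anova = anova_oneway(y, groups).f
        assert abs(f_ancova - f_anova) / f_anova < 0.1

    def test_outcome_explained_by_handedness_leaves_group_null(self):
        rng = np.random.default_rng(12)
        hand = np.tile(["right", "mixed", "left"], 60)
        groups = np.repeat(["a", "b", "c"], 60)  # balanced across handedness
        y = {"right": 0.0, "mixed": 5.0, "left": -3.0}
        values = np.array([y[h] for h in hand]) + rng.normal(0, 0.1, 180)
        res = ancova_handedness(values, groups, hand)
        assert res.p > 0.05

    def test_absent_category_dropped_without_error(self):
        rng = np.random.default_rng(13)
        hand = np.repeat("right", 60)
        groups = np.repeat(["a", "b", "c"], 20)
        res = ancova_handedness(rng.normal(size=60), groups, hand)
        assert res.df == (2, 60 - 3)


class TestCorrelations:
    def test_perfect_linear_relationships(self, cohort_table):
        sub = cohort_table[cohort_table.region == "thalamus"].copy()
        sub["severity"] = 2 * sub["volume_mm3"] + 1
        sub["med_dose"] = -sub["volume_mm3"]
        sub["susceptibility_ppm"] = sub["volume_mm3"]
        out = correlation_screen(sub, "thalamus", ["severity", "med_dose"])
        assert out.loc[out.variable == "severity", "r"].iloc[0] == pytest.approx(1.0)
        assert out.loc[out.variable == "med_dose", "r"].iloc[0] == pytest.approx(-1.0)

    def test_independent_gaussians_near_zero(self):
        rng = np.random.default_rng(14)
        n = 10000
        table = pd.DataFrame({
            "region": "r", "group": "MDD",
            "susceptibility_ppm": rng.normal(size=n),
            "volume_mm3": rng.normal(size=n),
            "severity": rng.normal(size=n),
        })
        out = correlation_screen(table, "r", ["severity"])
        assert abs(out["r"].iloc[0]) < 0.05

    def test_zero_variance_flagged(self):
        table = pd.DataFrame({
            "region": "r", "group": "MDD",
            "susceptibility_ppm": [0.1, 0.2, 0.3, 0.4],
            "severity": [5.0, 5.0, 5.0, 5.0],
        })
        out = correlation_screen(table, "r", ["severity"])
        assert out["flag"].iloc[0] == "zero_variance"
        assert np.isnan(out["r"].iloc[0])

    def test_missing_values_pairwise_deleted(self):
        table = pd.DataFrame({
            "region": "r", "group": "MDD",
            "susceptibility_ppm": [0.1, 0.2, 0.3, 0.4, 0.5],
            "severity": [1.0, np.nan, 3.0, np.nan, 5.0],
        })
        out = correlation_screen(table, "r", ["severity"])
        assert out["n"].iloc[0] == 3


class TestAssumptions:
    def test_gaussian_data_reported(self, cohort_table):
        rep = check_assumptions(cohort_table, "putamen")
        assert set(rep.shapiro) == {"HC", "MDD", "SCZ"}
        for w, p in rep.shapiro.values():
            assert 0 <= p <= 1 and 0 < w <= 1
        assert rep.levene is not None and 0 <= rep.levene[1] <= 1

    def test_variance_difference_detected_by_levene(self):
        rng = np.random.default_rng(15)
        table = pd.DataFrame({
            "region": "r",
            "group": np.repeat(["a", "b"], 200),
            "susceptibility_ppm": np.concatenate([
                rng.normal(0, 1, 200), rng.normal(0, 2, 200)]),
        })
        rep = check_assumptions(table, "r")
        assert rep.levene[1] < 0.01

    def test_constant_groups_flagged_without_crash(self):
        table = pd.DataFrame({
            "region": "r",
            "group": np.repeat(["a", "b"], 5),
            "susceptibility_ppm": np.repeat([1.0, 2.0], 5),
        })
        rep = check_assumptions(table, "r")
        assert any("degenerate" in f for f in rep.flags)


class TestAnalyzeAndTables:
    def test_full_analysis_shapes_and_gating(self, cohort_table):
        results = analyze_cohort(cohort_table)
        frames, markdown = build_tables(results, cohort_table)
        for measure, df in frames.items():
            assert len(df) == 10
            anova = {a.region: a for a in results.anova[measure]}
            for _, row in df.iterrows():
                a = anova[row["region"]]
                assert a.q_fdr >= a.p_raw - 1e-15
                gated = (measure, row["region"]) in results.posthoc
                assert bool(row["post_hoc"]) == gated
                if gated:
                    assert a.q_fdr < 0.05
        assert "nucleus_accumbens" in markdown["susceptibility_ppm"]

    def test_glm_run_for_every_region(self, cohort_table):
        results = analyze_cohort(cohort_table)
        assert set(results.glm) == set(cohort_table.region.unique())

    def test_reproduce_anova_from_summary_csv(self, cohort_table):
        rows = []
        for region in ("thalamus", "caudate"):
            sub = cohort_table[cohort_table.region == region]
            for group, grp in sub.groupby("group"):
                rows.append({"region": region, "measure": "volume",
                             "group": group,
                             "mean": grp.volume_mm3.mean(),
                             "sd": grp.volume_mm3.std(ddof=1),
                             "n": len(grp)})
        out = reproduce_anova(pd.DataFrame(rows))
        for region in ("thalamus", "caudate"):
            sub = cohort_table[cohort_table.region == region]
            direct = anova_oneway(sub.volume_mm3.to_numpy(), sub.group.to_numpy())
            got = out.loc[out.region == region, "F"].iloc[0]
            assert got == pytest.approx(direct.f, rel=1e-9)
        assert (out["q"] >= out["p"] - 1e-15).all()
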