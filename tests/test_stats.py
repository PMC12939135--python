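"""The ANOVA battery against independent oracles, plus its invariants."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from conftest import random_mixed_table, random_rm_table
from ctsrt.stats import (
    DesignError,
    lastvar_rm_anova,
    mixed_anova,
    pairwise_bonferroni,
    rank_transform,
    rm_anova2,
    subblock_slope_test,
    subblock_slopes,
)
from oracles import mixed_anova_oracle, one_sample_t_power, rm_anova2_oracle


class TestRankTransform:
    def test_simple_and_ties(self):
        assert rank_transform([10, 20, 30]).tolist() == [1, 2, 3]
        assert rank_transform([10, 10, 30]).tolist() == [1.5, 1.5, 3]

    @given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=60))
    @settings(deadline=None)
    def test_rank_sum_conserved(self, xs):
        n = len(xs)
        assert rank_transform(xs).sum() == pytest.approx(n * (n + 1) / 2)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            rank_transform([1.0, np.nan])


class TestRmAnova2:
    def test_matches_projection_oracle_many_designs(self):
        rng = np.random.default_rng(42)
        for i in range(25):
            n, a, b = rng.integers(3, 6), rng.integers(2, 4), rng.integers(2, 4)
            df = random_rm_table(rng, n=n, a=a, b=b)
            mine = rm_anova2(df, within=("A", "B"))
            ref = rm_anova2_oracle(df, "subject_id", "A", "B", "mean_rt")
            np.testing.assert_allclose(mine["F"], ref["F"], rtol=1e-8)
            np.testing.assert_allclose(mine["p"], ref["p"], rtol=1e-8)
            assert mine["df_num"].tolist() == ref["df_num"].tolist()
            assert mine["df_den"].tolist() == ref["df_den"].tolist()

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        df = random_rm_table(np.random.default_rng(7), n=8, a=3, b=4)
        mine = rm_anova2(df, within=("A", "B"))
        ref = pg.rm_anova(data=df, dv="mean_rt", within=["A", "B"],
                          subject="subject_id", detailed=True)
        np.testing.assert_allclose(mine["F"], ref["F"], rtol=1e-10)
        np.testing.assert_allclose(mine["p"], ref["p_unc"], rtol=1e-10)
        # main-effect Greenhouse-Geisser epsilons agree too
        np.testing.assert_allclose(mine["eps_gg"][:2], ref["eps"][:2], rtol=1e-8)

    def test_constant_table_gives_zero_f(self):
        df = random_rm_table(np.random.default_rng(0), n=4, a=3, b=2)
        df["mean_rt"] = 500.0
        res = rm_anova2(df, within=("A", "B"))
        assert np.allclose(res["F"], 0.0) and np.allclose(res["p"], 1.0)

    def test_study_design_dfs(self):
        df = random_rm_table(np.random.default_rng(1), n=10, a=5, b=4)
        res = rm_anova2(df, within=("A", "B"))
        assert list(zip(res["df_num"], res["df_den"])) == [(4, 36), (3, 27), (12, 108)]

    def test_rank_anova_invariant_under_monotone_transform(self):
        df = random_rm_table(np.random.default_rng(3), n=6, a=3, b=3)
        a = rm_anova2(df, within=("A", "B"), use_ranks=True)
        df2 = df.assign(mean_rt=np.exp(df["mean_rt"] / 100.0))
        b = rm_anova2(df2, within=("A", "B"), use_ranks=True)
        np.testing.assert_allclose(a["F"], b["F"], rtol=1e-12)

    def test_missing_cell_complete_case_reduction(self):
        df = random_rm_table(np.random.default_rng(9), n=5, a=3, b=2)
        df = df.drop(df[(df.subject_id == "s0") & (df.A == "a1") & (df.B == "b0")].index)
        with pytest.warns(UserWarning, match="dropping subjects"):
            res = rm_anova2(df, within=("A", "B"))
        assert res.attrs["n_subjects"] == 4

    def test_too_small_design_rejected(self):
        df = random_rm_table(np.random.default_rng(2), n=1, a=3, b=2)
        with pytest.raises(DesignError):
            rm_anova2(df, within=("A", "B"))


class TestMixedAnova:
    def test_matches_projection_oracle_many_designs(self):
        rng = np.random.default_rng(11)
        for i in range(25):
            npg, w = rng.integers(3, 6), rng.integers(2, 5)
            df = random_mixed_table(rng, n_per_group=npg, g=2, w=w)
            mine = mixed_anova(df)
            ref = mixed_anova_oracle(df, "subject_id", "group", "event", "mean_rt")
            np.testing.assert_allclose(mine["F"], ref["F"], rtol=1e-8)
            np.testing.assert_allclose(mine["p"], ref["p"], rtol=1e-8)
            assert mine["df_num"].tolist() == ref["df_num"].tolist()
            assert mine["df_den"].tolist() == ref["df_den"].tolist()

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        df = random_mixed_table(np.random.default_rng(13), n_per_group=6, g=2, w=4)
        mine = mixed_anova(df)
        ref = pg.mixed_anova(data=df, dv="mean_rt", within="event",
                             between="group", subject="subject_id")
        np.testing.assert_allclose(mine["F"], ref["F"], rtol=1e-10)
        np.testing.assert_allclose(mine["p"], ref["p_unc"], rtol=1e-10)

    def test_study_design_dfs(self):
        df = random_mixed_table(np.random.default_rng(5), n_per_group=10, g=2, w=4)
        res = mixed_anova(df)
        assert list(zip(res["df_num"], res["df_den"])) == [(1, 18), (3, 54), (3, 54)]

    def test_identical_groups_give_zero_group_f(self):
        df = random_mixed_table(np.random.default_rng(6), n_per_group=4, g=1, w=3)
        dup = df.assign(group="g1", subject_id=df["subject_id"] + "x")
        both = pd.concat([df.assign(group="g0"), dup], ignore_index=True)
        res = mixed_anova(both)
        assert res.loc[res["effect"] == "group", "F"].iloc[0] == pytest.approx(0.0)

    def test_subject_in_two_groups_rejected(self):
        df = random_mixed_table(np.random.default_rng(8), n_per_group=3)
        df.loc[df.index[-1], "subject_id"] = df["subject_id"].iloc[0]
        with pytest.raises(DesignError):
            mixed_anova(df)


class TestLastVarAnova:
    def test_study_design_dfs(self):
        rng = np.random.default_rng(21)
        rows = [{"subject_id": f"s{s}", "event": e, "last_var": lv,
                 "mean_rt": rng.normal(500, 30)}
                for s in range(10) for e in ("F1", "F2", "V2", "V3")
                for lv in ("V2", "V3")]
        res = lastvar_rm_anova(pd.DataFrame(rows))
        assert list(zip(res["df_num"], res["df_den"])) == [(3, 27), (1, 9), (3, 27)]

    def test_symmetric_table_gives_zero_lastvar_f(self):
        rng = np.random.default_rng(22)
        half = [{"subject_id": f"s{s}", "event": e, "last_var": "V2",
                 "mean_rt": rng.normal(500, 30)}
                for s in range(6) for e in ("F1", "F2", "V2", "V3")]
        df = pd.DataFrame(half)
        mirror = df.assign(last_var="V3")
        res = lastvar_rm_anova(pd.concat([df, mirror], ignore_index=True))
        assert res.loc[res["effect"] == "last_var", "F"].iloc[0] == pytest.approx(0.0)


class TestPairwise:
    def test_adjustment_arithmetic(self):
        rng = np.random.default_rng(30)
        rows = [{"subject_id": f"s{s}", "event": e, "mean_rt": rng.normal(500, 20)}
                for s in range(8) for e in ("F1", "F2", "V2", "V3")]
        out = pairwise_bonferroni(pd.DataFrame(rows), "event")
        assert len(out) == 6 and (out["m"] == 6).all()
        np.testing.assert_allclose(out["p_bonf"],
                                   np.minimum(1.0, 6 * out["p_raw"]))
        assert (out["p_bonf"] >= out["p_raw"] - 1e-15).all()

    def test_single_comparison_family_leaves_p_unchanged(self):
        rng = np.random.default_rng(31)
        rows = [{"subject_id": f"s{s}", "event": e, "mean_rt": rng.normal(500, 20)}
                for s in range(8) for e in ("F1", "F2")]
        out = pairwise_bonferroni(pd.DataFrame(rows), "event")
        assert out["p_bonf"].iloc[0] == pytest.approx(out["p_raw"].iloc[0])

    def test_zero_variance_difference_flagged(self):
        rows = [{"subject_id": f"s{s}", "event": e, "mean_rt": 500.0 + s}
                for s in range(5) for e in ("F1", "F2")]
        out = pairwise_bonferroni(pd.DataFrame(rows), "event")
        assert out["note"].iloc[0] == "zero-variance difference"
        assert np.isnan(out["p_raw"].iloc[0])

    def test_unpaired_mode_uses_two_sample_df(self):
        rng = np.random.default_rng(33)
        rows = [{"subject_id": f"{g}s{s}", "group": g, "mean_rt": rng.normal(500, 20)}
                for g in ("g0", "g1") for s in range(6)]
        out = pairwise_bonferroni(pd.DataFrame(rows), "group", paired=False)
        assert out["df"].iloc[0] == 10


class TestSlopes:
    def test_exact_line_recovered(self):
        rows = [{"subject_id": "s1", "group": "ME", "block": 1, "sub_block": k,
                 "mean_rt": 500.0 - 20.0 * (k - 1)} for k in (1, 2, 3)]
        slopes = subblock_slopes(pd.DataFrame(rows))
        assert slopes["slope"].iloc[0] == pytest.approx(-20.0)

    def test_t_test_df_is_n_minus_one(self, kept_trials):
        from ctsrt.preprocessing import subblock_means
        res = subblock_slope_test(subblock_means(kept_trials))
        assert (res["df"] == 9).all() and (res["n"] == 10).all()

    def test_zero_variance_slopes_flagged(self):
        rows = [{"subject_id": f"s{s}", "group": "ME", "block": 1, "sub_block": k,
                 "mean_rt": 500.0 - 10.0 * k} for s in range(4) for k in (1, 2, 3)]
        res = subblock_slope_test(pd.DataFrame(rows))
        assert res["note"].iloc[0] == "zero slope variance"

    def test_rejection_rate_matches_analytic_power(self):
        """Slopes ~ N(-15, 5^2), n=10: t-test rejection rate equals nct power."""
        rng = np.random.default_rng(44)
        mean, sd, n, reps = -15.0, 5.0, 10, 2000
        rej = sum(
            sps.ttest_1samp(rng.normal(mean, sd, n), 0.0).pvalue < 0.05
            for _ in range(reps)
        )
        power = one_sample_t_power(mean, sd, n)
        mc_sd = np.sqrt(power * (1 - power) / reps)
        assert abs(rej / reps - power) <= max(4 * mc_sd, 0.005)
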