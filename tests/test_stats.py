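"""t-tests, Mauchly/GG, split-plot ANOVA against independent oracles."""

import itertools

import numpy as np
import pandas as pd
import pingouin as pg
import pytest
from scipy import stats as sps

from audloc import (analysis_battery, bonferroni, mauchly_and_gg,
                    one_sample_t_test, paired_t_test, rm_anova)


def naive_one_way_rm(y):
    """Loop-based sums-of-squares oracle for a one-within design (n x k)."""
    n, k = y.shape
    grand = y.mean()
    ss_subj = k * sum((y[i].mean() - grand) ** 2 for i in range(n))
    ss_cond = n * sum((y[:, j].mean() - grand) ** 2 for j in range(k))
    ss_tot = sum((y[i, j] - grand) ** 2 for i in range(n) for j in range(k))
    ss_err = ss_tot - ss_subj - ss_cond
    df1, df2 = k - 1, (k - 1) * (n - 1)
    F = (ss_cond / df1) / (ss_err / df2)
    return F, df1, df2, sps.f.sf(F, df1, df2)


def long_frame(y, groups=None):
    n, k = y.shape
    df = pd.DataFrame({
        "s": np.repeat(np.arange(n), k),
        "w": np.tile(np.arange(k), n),
        "y": y.ravel()})
    if groups is not None:
        df["g"] = np.repeat(groups, k)
    return df


class TestTTests:
    def test_identical_vectors(self):
        res = paired_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t_statistic == 0 and res.p_value == 1 and res.df == 2

    def test_hand_computed_differences(self):
        """Differences (1,2,3): t = 2 / (1/sqrt(3)) = 2*sqrt(3)."""
        res = paired_t_test([2.0, 4.0, 6.0], [1.0, 2.0, 3.0])
        assert res.t_statistic == pytest.approx(2 * np.sqrt(3))
        assert res.df == 2
        assert res.mean_difference == pytest.approx(2.0)

    def test_equivalent_to_one_sample_on_differences(self, rng):
        a, b = rng.normal(5, 2, 24), rng.normal(4, 2, 24)
        paired = paired_t_test(a, b)
        onesample = one_sample_t_test(a - b)
        assert paired.t_statistic == pytest.approx(onesample.t_statistic)
        assert paired.p_value == pytest.approx(onesample.p_value)

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            paired_t_test([1.0, 2.0], [1.0, 2.0, 3.0])


class TestMauchlyGG:
    def test_two_levels_epsilon_one(self, rng):
        res = mauchly_and_gg(rng.normal(0, 1, (10, 2)))
        assert res.gg_epsilon == 1.0 and res.mauchly_p == 1.0

    def test_matches_pingouin(self, rng):
        y = rng.normal(0, 1, (12, 4)) + rng.normal(0, 1, (12, 1))
        y[:, 2] *= 2.5  # break sphericity
        mine = mauchly_and_gg(y)
        df = long_frame(y)
        sph = pg.sphericity(df, dv="y", within="w", subject="s")
        eps = pg.epsilon(df, dv="y", within="w", subject="s", correction="gg")
        assert mine.mauchly_w == pytest.approx(sph.W, rel=1e-9)
        assert mine.mauchly_chi2 == pytest.approx(sph.chi2, rel=1e-9)
        assert mine.gg_epsilon == pytest.approx(float(eps), rel=1e-9)

    def test_compound_symmetry_gives_epsilon_near_one(self, rng):
        subj = rng.normal(0, 2, (200, 1))
        y = subj + rng.normal(0, 1, (200, 5))
        assert mauchly_and_gg(y).gg_epsilon > 0.95

    @pytest.mark.parametrize("k", [3, 4, 5])
    def test_epsilon_bounds(self, rng, k):
        for _ in range(20):
            y = rng.normal(0, rng.uniform(0.5, 3, k), (k + 5, k))
            eps = mauchly_and_gg(y).gg_epsilon
            assert 1.0 / (k - 1) - 1e-12 <= eps <= 1.0 + 1e-12

    def test_too_few_subjects_rejected(self, rng):
        with pytest.raises(ValueError):
            mauchly_and_gg(rng.normal(0, 1, (3, 5)))


class TestRmAnova:
    def test_one_way_matches_naive_oracle(self, rng):
        y = rng.normal(0, 1, (8, 3)) + np.array([0.0, 0.6, 1.0])
        res = rm_anova(long_frame(y), "y", "s", ["w"])
        F, df1, df2, p = naive_one_way_rm(y)
        row = res.iloc[0]
        assert row["F"] == pytest.approx(F)
        assert (row["df1"], row["df2"]) == (df1, df2)
        assert row["p"] == pytest.approx(p)

    def test_one_way_matches_pingouin_with_gg(self, rng):
        y = rng.normal(0, 1, (12, 4)) + rng.normal(0, 1, (12, 1))
        y[:, 1] *= 2.0
        res = rm_anova(long_frame(y), "y", "s", ["w"]).iloc[0]
        ping = pg.rm_anova(data=long_frame(y), dv="y", within="w", subject="s",
                           correction=True).iloc[0]
        assert res["F"] == pytest.approx(ping["F"])
        assert res["p"] == pytest.approx(ping["p_unc"])
        assert res["gg_epsilon"] == pytest.approx(ping["eps"], rel=1e-9)
        assert res["p_gg"] == pytest.approx(ping["p_GG_corr"], rel=1e-6)

    def test_mixed_design_matches_pingouin(self, rng):
        groups = np.array([0] * 8 + [1] * 8)
        y = (rng.normal(0, 1, (16, 3)) + rng.normal(0, 1, (16, 1))
             + np.array([0.0, 1.0, 2.0]) + 0.5 * groups[:, None])
        res = rm_anova(long_frame(y, groups), "y", "s", ["w"], between="g")
        res = res.set_index("effect")
        ping = pg.mixed_anova(data=long_frame(y, groups), dv="y", within="w",
                              subject="s", between="g").set_index("Source")
        for mine, theirs in [("g", "g"), ("w", "w"), ("w*g", "Interaction")]:
            assert res.loc[mine, "F"] == pytest.approx(ping.loc[theirs, "F"])
            assert res.loc[mine, "p"] == pytest.approx(ping.loc[theirs, "p_unc"])

    def test_two_within_matches_pingouin(self, rng):
        n, a, b = 10, 3, 2
        y = rng.normal(0, 1, (n, a, b)) + rng.normal(0, 1, (n, 1, 1))
        y += np.arange(a)[None, :, None] * 0.8 + np.arange(b)[None, None, :] * 0.5
        df = pd.DataFrame({
            "s": np.repeat(np.arange(n), a * b),
            "wa": np.tile(np.repeat(np.arange(a), b), n),
            "wb": np.tile(np.arange(b), n * a),
            "y": y.ravel()})
        res = rm_anova(df, "y", "s", ["wa", "wb"]).set_index("effect")
        ping = pg.rm_anova(data=df, dv="y", within=["wa", "wb"],
                           subject="s").set_index("Source")
        for mine, theirs in [("wa", "wa"), ("wb", "wb"), ("wa*wb", "wa * wb")]:
            assert res.loc[mine, "F"] == pytest.approx(ping.loc[theirs, "F"])
            assert res.loc[mine, "p"] == pytest.approx(
                ping.loc[theirs, "p_unc"], rel=1e-6)

    def test_hand_worked_small_fixture(self):
        """3 conditions x 2 subjects with hand-computable sums of squares."""
        y = np.array([[1.0, 2.0, 6.0], [3.0, 4.0, 8.0]])
        # grand mean 4; subject means 3, 5; condition means 2, 3, 7
        # SS_cond = 2*((2-4)^2+(3-4)^2+(7-4)^2) = 28
        # SS_subj = 3*((3-4)^2+(5-4)^2) = 6; SS_tot = 34; SS_err = 0
        res = rm_anova(long_frame(y), "y", "s", ["w"]).iloc[0]
        assert res["ss"] == pytest.approx(28.0)
        assert np.isinf(res["F"])  # zero error term

    def test_gg_correction_never_lowers_p_when_f_large(self, rng):
        y = rng.normal(0, 1, (12, 4)) + np.array([0.0, 1.0, 2.0, 0.5])
        y[:, 3] *= 3.0
        res = rm_anova(long_frame(y), "y", "s", ["w"]).iloc[0]
        if res["F"] > 1 and res["gg_epsilon"] < 1:
            assert res["p_gg"] >= res["p"]
        assert res["df1_gg"] <= res["df1"] and res["df2_gg"] <= res["df2"]

    def test_missing_cell_rejected(self, rng):
        df = long_frame(rng.normal(0, 1, (6, 3))).drop(index=0)
        with pytest.raises(ValueError, match="balanced"):
            rm_anova(df, "y", "s", ["w"])

    def test_replicated_cell_rejected(self, rng):
        df = long_frame(rng.normal(0, 1, (6, 3)))
        df = pd.concat([df, df.iloc[:1]])
        with pytest.raises(ValueError, match="balanced"):
            rm_anova(df, "y", "s", ["w"])


class TestBonferroni:
    def test_scaling_and_cap(self):
        res = bonferroni([0.01, 0.5], family_size=3)
        assert res.comparisons[0]["adjusted_p"] == pytest.approx(0.03)
        assert res.comparisons[1]["adjusted_p"] == 1.0

    def test_near_one_inputs_cap(self):
        res = bonferroni([0.999], family_size=3)
        assert res.comparisons[0]["adjusted_p"] == 1.0

    def test_ordering_preserved(self, rng):
        p = np.sort(rng.uniform(0, 0.2, 5))
        adj = [c["adjusted_p"] for c in bonferroni(p, family_size=5).comparisons]
        assert adj == sorted(adj)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            bonferroni([1.5], family_size=1)
        with pytest.raises(ValueError):
            bonferroni([0.1, 0.2], family_size=1)


class TestAnalysisBattery:
    def test_reproduces_study_directions(self, default_study):
        report = analysis_battery(default_study["summaries"],
                                  default_study["means"])
        tt = report["before_training_t_tests"]
        for key in ("auditory_variability", "auditory_bias",
                    "visual_variability", "visual_bias"):
            assert tt[key]["mean_difference"] > 0
            assert tt[key]["p"] < 0.05

        trained = report["trained_stimulus_phase_anovas"]["bias"]
        phase_row = next(r for r in trained["anova"] if r["effect"] == "phase")
        assert phase_row["p_gg"] < 0.05
        before_vs_training = next(
            c for c in trained["posthoc_phases"] if c["pair"] == "before vs training")
        assert before_vs_training["mean_difference"] > 0
        assert before_vs_training["bonferroni_p"] < 0.05

        for stim in ("A1", "A2"):
            assert report["posttraining_bias_vs_zero"][stim]["mean_difference"] > 0

    def test_missing_phase_named(self, default_study):
        means = default_study["means"].query("phase != 'training'")
        with pytest.raises(ValueError, match="training"):
            analysis_battery(default_study["summaries"], means)

    def test_posthoc_family_is_three_phases(self, default_study):
        report = analysis_battery(default_study["summaries"],
                                  default_study["means"])
        posthocs = report["trained_stimulus_phase_anovas"]["bias"]["posthoc_phases"]
        assert len(posthocs) == 3
        for c in posthocs:
            assert c["bonferroni_p"] == pytest.approx(min(1.0, 3 * c["p"]))
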