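"""Crossover inference: split-plot ANOVA, Tukey HSD, planned contrasts."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from stepsense.errors import FitError, InvalidParameterError
from stepsense.stats import (
    CellMeans,
    balance_anova,
    cohens_d,
    contrast_eq1,
    contrast_eq2,
    fit_rm_anova,
    tukey_pairwise,
)

PRINTED_MEANS = {"nn1": 2.57, "nn2": 2.40, "nt1": 2.78, "nt2": 2.24,
                 "tn1": 2.43, "tn2": 2.05}


def split_plot_oracle(df, dv, subject, between, within):
    """From-scratch balanced split-plot sums-of-squares decomposition."""
    wide = df.pivot_table(index=[subject, between], columns=within, values=dv)
    y = wide.to_numpy()
    groups = wide.index.get_level_values(between)
    levels = sorted(set(groups))
    g, v = len(levels), y.shape[1]
    n = sum(groups == levels[0]) // 1
    grand = y.mean()
    ss_between = v * n * sum((y[groups == lb].mean() - grand) ** 2 for lb in levels)
    ss_within = g * n * ((y.mean(axis=0) - grand) ** 2).sum()
    ss_inter = 0.0
    for lb in levels:
        sub = y[groups == lb]
        ss_inter += n * ((sub.mean(axis=0) - sub.mean() - y.mean(axis=0) + grand) ** 2).sum()
    subj_mean = y.mean(axis=1)
    grp_mean = np.array([y[groups == lb].mean() for lb in groups])
    ss_subj = v * ((subj_mean - grp_mean) ** 2).sum()
    ss_err = 0.0
    for i, lb in enumerate(groups):
        sub_cell = y[groups == lb].mean(axis=0)
        ss_err += ((y[i] - subj_mean[i] - sub_cell + grp_mean[i]) ** 2).sum()
    ms = lambda ss, d: ss / d
    df_subj, df_err = g * (n - 1), g * (n - 1) * (v - 1)
    return {
        between: ms(ss_between, g - 1) / ms(ss_subj, df_subj),
        within: ms(ss_within, v - 1) / ms(ss_err, df_err),
        "interaction": ms(ss_inter, (g - 1) * (v - 1)) / ms(ss_err, df_err),
    }


def random_design(rng, g=3, n=5, v=2, effects=True):
    rows = []
    for gi in range(g):
        for i in range(n):
            subj_eff = rng.normal(0, 0.5)
            for vi in range(1, v + 1):
                mu = 2.0 + (0.3 * gi + 0.4 * vi + 0.2 * gi * vi if effects else 0.0)
                rows.append({
                    "participant_id": f"g{gi}s{i}",
                    "group": f"G{gi}",
                    "visit": vi,
                    "rmse": mu + subj_eff + rng.normal(0, 0.3),
                })
    return pd.DataFrame(rows)


class TestRmAnova:
    def test_matches_sums_of_squares_oracle(self, rng):
        df = random_design(rng)
        table, _ = fit_rm_anova(df)
        oracle = split_plot_oracle(df, "rmse", "participant_id", "group", "visit")
        assert table.effect("group")["F"] == pytest.approx(oracle["group"], rel=1e-8)
        assert table.effect("visit")["F"] == pytest.approx(oracle["visit"], rel=1e-8)
        assert table.effect("group:visit")["F"] == pytest.approx(
            oracle["interaction"], rel=1e-8
        )

    def test_constant_response_gives_zero_f(self):
        df = random_design(np.random.default_rng(0))
        df["rmse"] = 1.7
        table, _ = fit_rm_anova(df)
        assert (table.table["F"] == 0).all()
        assert (table.table["p"] == 1.0).all()

    def test_replicates_average_like_cell_means(self, rng):
        """Per-block replicate rows give the same F tests as pre-averaged data."""
        df = random_design(rng)
        reps = pd.concat(
            [df.assign(block=1), df.assign(block=2, rmse=df["rmse"] + 0.0)],
            ignore_index=True,
        )
        t1, _ = fit_rm_anova(df)
        t2, _ = fit_rm_anova(reps)
        pd.testing.assert_frame_equal(t1.table, t2.table)

    def test_unbalanced_design_rejected(self, rng):
        df = random_design(rng)
        with pytest.raises(FitError):
            fit_rm_anova(df[~((df.participant_id == "g0s0") & (df.visit == 2))])
        with pytest.raises(FitError):  # unequal group sizes
            fit_rm_anova(df[df.participant_id != "g0s0"])


class TestTukey:
    def test_identical_means_give_p_one(self):
        rows = []
        for gi, g in enumerate(["A", "B", "C"]):
            for i in range(4):
                for vi in (1, 2):
                    # same cell means in every group; subject jitter only
                    rows.append({"participant_id": f"{g}{i}", "group": g,
                                 "visit": vi, "rmse": 2.0 + 0.1 * i + 0.05 * vi})
        df = pd.DataFrame(rows)
        _, fit = fit_rm_anova(df)
        comp = tukey_pairwise(fit, "group")
        assert np.allclose(comp["p_tukey"], 1.0)

    def test_extreme_separation(self, rng):
        df = random_design(rng, g=2, n=10, effects=False)
        df.loc[df.group == "G1", "rmse"] += 10.0  # ~10 pooled SDs
        _, fit = fit_rm_anova(df)
        comp = tukey_pairwise(fit, "group")
        assert (comp["p_tukey"] < 0.001).all()

    def test_matches_studentized_range_oracle(self, rng):
        """Adjusted p equals a direct studentized-range CDF evaluation using
        hand-computed marginal means and error terms."""
        df = random_design(rng)
        _, fit = fit_rm_anova(df)
        comp = tukey_pairwise(fit, "group")
        agg = df.groupby(["participant_id", "group", "visit"])["rmse"].mean().reset_index()
        wide = agg.pivot_table(index=["participant_id", "group"], columns="visit",
                               values="rmse")
        subj = wide.mean(axis=1)
        grp = subj.groupby(wide.index.get_level_values("group")).mean()
        # error term: subjects within groups
        ms_subj = (
            2 * ((subj - grp[wide.index.get_level_values("group")].to_numpy()) ** 2).sum()
            / (3 * 4)
        )
        n_per, v = 5, 2
        for _, row in comp.iterrows():
            diff = grp[row.level_1] - grp[row.level_2]
            se_mean = math.sqrt(ms_subj / (v * n_per))
            q = abs(diff) / se_mean
            p = sps.studentized_range.sf(q, 3, 3 * 4)
            assert row.p_tukey == pytest.approx(p, rel=1e-6)

    def test_adjusted_p_not_smaller_than_unadjusted(self, rng):
        df = random_design(rng)
        _, fit = fit_rm_anova(df)
        for factor in ("group", "visit", "group:visit"):
            comp = tukey_pairwise(fit, factor)
            assert (comp["p_tukey"] >= comp["p_unadjusted"] - 1e-12).all()

    def test_unknown_factor_rejected(self, rng):
        _, fit = fit_rm_anova(random_design(rng))
        with pytest.raises(InvalidParameterError):
            tukey_pairwise(fit, "condition")


class TestContrasts:
    def test_eq1_on_printed_cell_means(self):
        cells = CellMeans.from_group_visit(PRINTED_MEANS)
        est = contrast_eq1(cells).estimate
        assert est == pytest.approx((2.78 + 2.57) / 2 - 2.43)
        assert est == pytest.approx(0.24, abs=0.01)  # published value

    def test_eq2_on_printed_cell_means(self):
        cells = CellMeans.from_group_visit(PRINTED_MEANS)
        est = contrast_eq2(cells).estimate
        assert est == pytest.approx((2.78 - 2.24) - (2.57 - 2.40))
        assert est == pytest.approx(0.371, abs=0.01)  # published value

    @pytest.mark.parametrize(
        "means, expected",
        [
            ({"nt1": 3.0, "nn1": 2.0, "tn1": 2.0}, 0.5),
            ({"nt1": 2.0, "nn1": 2.0, "tn1": 2.0}, 0.0),
        ],
    )
    def test_eq1_arithmetic(self, means, expected):
        assert contrast_eq1(CellMeans.from_group_visit(means)).estimate == pytest.approx(
            expected
        )

    def test_eq2_null_under_equal_changes(self):
        cells = CellMeans.from_group_visit(
            {"nt1": 3.0, "nt2": 2.5, "nn1": 2.8, "nn2": 2.3}
        )
        assert contrast_eq2(cells).estimate == pytest.approx(0.0)

    def test_model_based_interval_contains_estimate(self, small_cohort):
        from stepsense.uncertainty import rmse_table

        summaries = rmse_table(small_cohort.trials)
        _, fit = fit_rm_anova(summaries)
        cells = CellMeans.from_table(summaries, "rmse", "group", "visit")
        for contrast in (contrast_eq1(cells, fit), contrast_eq2(cells, fit)):
            assert contrast.ci_low <= contrast.estimate <= contrast.ci_high
            assert contrast.se > 0 and 0 < contrast.p_value <= 1

    def test_contrast_on_model_cells_equals_raw_cells(self, small_cohort):
        """Model marginal means and raw cell means agree in balanced designs."""
        from stepsense.uncertainty import rmse_table

        summaries = rmse_table(small_cohort.trials)
        _, fit = fit_rm_anova(summaries)
        raw = CellMeans.from_table(summaries, "rmse", "group", "visit")
        model_cells = CellMeans(
            {
                (g, v): type(raw.cells[(g, v)])(mean=fit.cell_mean(g, v))
                for g in ("NN", "NT", "TN")
                for v in (1, 2)
            }
        )
        assert contrast_eq1(model_cells).estimate == pytest.approx(
            contrast_eq1(raw).estimate, abs=1e-10
        )
        assert contrast_eq2(model_cells).estimate == pytest.approx(
            contrast_eq2(raw).estimate, abs=1e-10
        )


class TestCohensD:
    def test_values(self):
        assert cohens_d(2.0, 1.0, 2.0, 1.0) == 0.0
        assert cohens_d(2.0, 1.0, 1.0, 1.0) == pytest.approx(1.0)
        # published cells give 1.03 under the pooled-SD definition
        assert cohens_d(2.78, 0.57, 2.24, 0.47) == pytest.approx(1.033, abs=0.001)

    def test_undefined(self):
        with pytest.raises(InvalidParameterError):
            cohens_d(2.0, 0.0, 1.0, 0.0)
        assert cohens_d(2.0, 0.0, 2.0, 0.0) == 0.0


class TestBalanceAnova:
    @staticmethod
    def make_vtc(rng, condition_effect=0.3, tens_effect=0.0):
        rows = []
        for tens in (False, True):
            for i in range(10):
                subj_eff = rng.normal(0, 0.2)
                for c in (1, 2, 3, 4):
                    rows.append({
                        "participant_id": f"{'T' if tens else 'N'}{i}",
                        "tens": tens,
                        "condition": c,
                        "mean_vtc": 2.0 - condition_effect * c
                        + (tens_effect if tens else 0.0)
                        + subj_eff + rng.normal(0, 0.15),
                    })
        return pd.DataFrame(rows)

    def test_identical_vtc_gives_zero_f(self, rng):
        df = self.make_vtc(rng)
        df["mean_vtc"] = 1.0
        table, _, _ = balance_anova(df)
        assert (table.table["F"] == 0).all()

    def test_matches_oracle(self, rng):
        df = self.make_vtc(rng)
        table, _, _ = balance_anova(df)
        oracle = split_plot_oracle(df, "mean_vtc", "participant_id", "tens", "condition")
        assert table.effect("tens")["F"] == pytest.approx(oracle["tens"], rel=1e-8)
        assert table.effect("condition")["F"] == pytest.approx(
            oracle["condition"], rel=1e-8
        )
        # df structure of the 2 x 4 design with 10 per group
        assert tuple(table.effect("tens")[["df1", "df2"]]) == (1.0, 18.0)
        assert tuple(table.effect("condition")[["df1", "df2"]]) == (3.0, 54.0)

    def test_condition_effect_detected_without_tens_effect(self):
        hits_cond, hits_tens_null = 0, 0
        for seed in range(20):
            df = self.make_vtc(np.random.default_rng(seed))
            table, _, _ = balance_anova(df)
            if table.effect("condition")["p"] < 0.05:
                hits_cond += 1
            if table.effect("tens")["p"] >= 0.05:
                hits_tens_null += 1
        assert hits_cond >= 18
        assert hits_tens_null >= 18

    def test_missing_condition_rejected(self, rng):
        df = self.make_vtc(rng)
        with pytest.raises(FitError):
            balance_anova(df[~((df.participant_id == "N0") & (df.condition == 4))])
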