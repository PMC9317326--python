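"""Group-by-visit inference on the uncertainty metric, and the balance ANOVA.

The design is a crossover: a between-participant factor (group, or TENS
on/off) crossed with a within-participant factor (visit, or mCTSIB
condition), every participant measured at every within level.  The
repeated-measures ANOVA is fitted on participant-by-level cell means (block
replicates averaged first), where the classical split-plot decomposition
coincides with the REML linear mixed model with a participant random
intercept.  Pairwise follow-ups use Tukey's honest significant difference
via the studentized range.  Two planned contrasts isolate the stimulation
effect:

* ``contrast_eq1`` — the visit-1 between-group contrast
  ``(nt1 + nn1)/2 - tn1`` (the two unstimulated groups' average minus the
  stimulated group, first visit only);
* ``contrast_eq2`` — the across-visit difference-in-differences
  ``(nt1 - nt2) - (nn1 - nn2)``, the stimulated group's improvement beyond
  the practice effect estimated from the never-stimulated group.

Both are reported unadjusted for multiplicity, as planned exploratory
contrasts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sps

from .errors import FitError, InvalidParameterError, SchemaError

GROUP_VISIT_CELLS = ("nn1", "nn2", "nt1", "nt2", "tn1", "tn2")


@dataclass(frozen=True)
class CellStats:
    mean: float
    sd: float | None = None
    n: int | None = None


@dataclass(frozen=True)
class CellMeans:
    """Per-cell summary of a between x within design, keyed (level_b, level_w)."""

    cells: dict

    def mean(self, level_b, level_w) -> float:
        return self.cells[(level_b, level_w)].mean

    @classmethod
    def from_group_visit(cls, means: dict[str, float], sds: dict[str, float] | None = None,
                         n: int | None = None) -> "CellMeans":
        """Build from flat labels like ``{"nt1": 2.78, ...}`` (group + visit digit)."""
        cells = {}
        for label, m in means.items():
            key = (label[:-1].upper(), int(label[-1]))
            sd = None if sds is None else sds.get(label)
            cells[key] = CellStats(mean=float(m), sd=sd, n=n)
        return cls(cells)

    @classmethod
    def from_table(cls, data: pd.DataFrame, response: str, between: str, within: str,
                   subject: str = "participant_id") -> "CellMeans":
        """Cell means/SDs across participants (replicates averaged within participant)."""
        per_subj = (
            data.groupby([between, within, subject], observed=True)[response].mean().reset_index()
        )
        agg = per_subj.groupby([between, within], observed=True)[response].agg(["mean", "std", "count"])
        cells = {
            key: CellStats(mean=row["mean"], sd=row["std"], n=int(row["count"]))
            for key, row in agg.iterrows()
        }
        return cls(cells)


@dataclass(frozen=True)
class ContrastEstimate:
    """A linear contrast of cell means with (optional) model-based inference."""

    estimate: float
    label: str
    se: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    p_value: float | None = None
    df: float | None = None


@dataclass(frozen=True)
class AnovaTable:
    """F tests for the between effect, within effect and their interaction."""

    table: pd.DataFrame  # columns: effect, F, df1, df2, p

    def effect(self, name: str) -> pd.Series:
        match = self.table[self.table["effect"] == name]
        if match.empty:
            raise KeyError(f"no effect named {name!r}")
        return match.iloc[0]


@dataclass(frozen=True)
class RmAnovaFit:
    """Handle onto a fitted balanced split-plot model.

    Stores the participant-by-level cell means the model was fitted on and
    the two error mean squares: ``ms_subject`` (participants within groups,
    the error term for between comparisons) and ``ms_error`` (the
    within-by-participant residual, the error term for within comparisons).
    """

    data: pd.DataFrame  # aggregated: subject x within cell means
    response: str
    subject: str
    between: str
    within: str
    levels_between: tuple
    levels_within: tuple
    n_per_group: int
    ms_subject: float
    df_subject: float
    ms_error: float
    df_error: float

    @property
    def cell_means(self) -> pd.DataFrame:
        return (
            self.data.groupby([self.between, self.within], observed=True)[self.response]
            .mean()
            .reset_index()
        )

    def cell_mean(self, level_b, level_w) -> float:
        d = self.data
        sel = d[(d[self.between] == level_b) & (d[self.within] == level_w)]
        return float(sel[self.response].mean())

    # -- variance of a single cell mean: (sigma_subj^2 + sigma_eps^2) / n ----
    def _between_cell_var_and_df(self) -> tuple[float, float]:
        v = len(self.levels_within)
        comp = (self.ms_subject + (v - 1) * self.ms_error) / v
        num = comp**2
        den = (self.ms_subject / v) ** 2 / self.df_subject
        if v > 1 and self.ms_error > 0:
            den += ((v - 1) * self.ms_error / v) ** 2 / self.df_error
        df = num / den if den > 0 else self.df_subject
        return comp / self.n_per_group, df


def _validate_layout(data: pd.DataFrame, response: str, subject: str, between: str,
                     within: str) -> None:
    for col in (response, subject, between, within):
        if col not in data.columns:
            raise SchemaError(f"missing column {col!r}")
    counts = data.groupby([subject, within], observed=True).size()
    cell_table = counts.unstack(fill_value=0)
    if (cell_table == 0).any().any():
        raise FitError(
            "unbalanced design: some participants are missing within-factor levels:\n"
            f"{cell_table[(cell_table == 0).any(axis=1)]}"
        )
    group_sizes = data.groupby(between, observed=True)[subject].nunique()
    if group_sizes.nunique() != 1:
        raise FitError(f"groups must have equal sizes; got {group_sizes.to_dict()}")
    grp_per_subj = data.groupby(subject, observed=True)[between].nunique()
    if (grp_per_subj > 1).any():
        raise FitError("each participant must belong to exactly one between-factor level")


def fit_rm_anova(
    data: pd.DataFrame,
    response: str = "rmse",
    subject: str = "participant_id",
    between: str = "group",
    within: str = "visit",
) -> tuple[AnovaTable, RmAnovaFit]:
    """Mixed (split-plot) repeated-measures ANOVA on a long-format table.

    Replicate rows per participant-by-within cell (e.g. per-block RMSE
    values) are averaged before fitting, which for a balanced design leaves
    the F tests identical to the mixed model with participant random
    intercept on the replicate data.  Returns the F table and a model handle
    used for Tukey follow-ups and planned contrasts.
    """
    _validate_layout(data, response, subject, between, within)
    agg = (
        data.groupby([subject, between, within], observed=True)[response]
        .mean()
        .reset_index()
    )
    levels_b = tuple(sorted(agg[between].unique()))
    levels_w = tuple(sorted(agg[within].unique()))
    if len(levels_b) < 2 or len(levels_w) < 2:
        raise FitError("need at least 2 levels of each factor")
    n = agg.groupby(between, observed=True)[subject].nunique().iloc[0]
    if n < 2:
        raise FitError("need at least 2 participants per group")

    g, v = len(levels_b), len(levels_w)
    if np.isclose(agg[response].var(ddof=0), 0.0):
        # all responses identical: every effect is exactly zero, by convention F=0
        rows = [
            {"effect": between, "F": 0.0, "df1": float(g - 1),
             "df2": float(g * (n - 1)), "p": 1.0},
            {"effect": within, "F": 0.0, "df1": float(v - 1),
             "df2": float(g * (n - 1) * (v - 1)), "p": 1.0},
            {"effect": f"{between}:{within}", "F": 0.0, "df1": float((g - 1) * (v - 1)),
             "df2": float(g * (n - 1) * (v - 1)), "p": 1.0},
        ]
    else:
        aov = pg.mixed_anova(
            data=agg, dv=response, within=within, subject=subject, between=between,
            correction=False,
        )
        rows = []
        name_map = {between: between, within: within, "Interaction": f"{between}:{within}"}
        for _, r in aov.iterrows():
            f_val = r["F"]
            p_val = r["p_unc"] if "p_unc" in r else r["p-unc"]
            if not np.isfinite(f_val):  # degenerate error term
                f_val, p_val = 0.0, 1.0
            rows.append(
                {
                    "effect": name_map.get(r["Source"], r["Source"]),
                    "F": float(f_val),
                    "df1": float(r["DF1"]),
                    "df2": float(r["DF2"]),
                    "p": float(p_val),
                }
            )
    table = AnovaTable(table=pd.DataFrame(rows))

    # error mean squares for follow-up comparisons
    g, v = len(levels_b), len(levels_w)
    wide = agg.pivot_table(index=[subject, between], columns=within, values=response)
    subj_means = wide.mean(axis=1)
    group_of = wide.index.get_level_values(between)
    group_means = subj_means.groupby(group_of, observed=True).transform("mean")
    ss_subject = v * float(((subj_means - group_means) ** 2).sum())
    df_subject = g * (n - 1)
    cell = agg.groupby([between, within], observed=True)[response].mean()
    resid = agg.apply(
        lambda r: r[response]
        - subj_means[(r[subject], r[between])]
        - cell[(r[between], r[within])]
        + group_means[(r[subject], r[between])],
        axis=1,
    )
    ss_error = float((resid**2).sum())
    df_error = g * (n - 1) * (v - 1)
    fit = RmAnovaFit(
        data=agg,
        response=response,
        subject=subject,
        between=between,
        within=within,
        levels_between=levels_b,
        levels_within=levels_w,
        n_per_group=int(n),
        ms_subject=ss_subject / df_subject,
        df_subject=float(df_subject),
        ms_error=ss_error / df_error,
        df_error=float(df_error),
    )
    return table, fit


def _tukey_p(diff: float, se_diff: float, k: int, df: float) -> float:
    if se_diff == 0:
        return 1.0 if diff == 0 else 0.0
    q = abs(diff) / (se_diff / math.sqrt(2.0))
    return float(sps.studentized_range.sf(q, k, df))


def _t_p(diff: float, se_diff: float, df: float) -> float:
    if se_diff == 0:
        return 1.0 if diff == 0 else 0.0
    return float(2.0 * sps.t.sf(abs(diff) / se_diff, df))


def tukey_pairwise(fit: RmAnovaFit, factor: str) -> pd.DataFrame:
    """All pairwise comparisons of marginal means with Tukey HSD adjustment.

    ``factor`` may be the between factor, the within factor, or
    ``"<between>:<within>"`` for all cell combinations.  Error terms follow
    the split-plot rules: between comparisons use the participant mean
    square, within comparisons the residual mean square, and cross-group
    cell comparisons a Satterthwaite combination of the two.
    """
    g, v, n = len(fit.levels_between), len(fit.levels_within), fit.n_per_group
    combos: list[tuple] = []
    if factor == fit.between:
        means = {
            lb: float(fit.data.loc[fit.data[fit.between] == lb, fit.response].mean())
            for lb in fit.levels_between
        }
        var_diff = 2.0 * fit.ms_subject / (v * n)
        combos = [
            (a, b, means[a] - means[b], var_diff, fit.df_subject)
            for i, a in enumerate(fit.levels_between)
            for b in fit.levels_between[i + 1:]
        ]
        k = g
    elif factor == fit.within:
        means = {
            lw: float(fit.data.loc[fit.data[fit.within] == lw, fit.response].mean())
            for lw in fit.levels_within
        }
        var_diff = 2.0 * fit.ms_error / (g * n)
        combos = [
            (a, b, means[a] - means[b], var_diff, fit.df_error)
            for i, a in enumerate(fit.levels_within)
            for b in fit.levels_within[i + 1:]
        ]
        k = v
    elif factor == f"{fit.between}:{fit.within}":
        cells = [(lb, lw) for lb in fit.levels_between for lw in fit.levels_within]
        cell_var, cell_df = fit._between_cell_var_and_df()
        for i, ca in enumerate(cells):
            for cb in cells[i + 1:]:
                diff = fit.cell_mean(*ca) - fit.cell_mean(*cb)
                if ca[0] == cb[0]:  # same participant set: subject effect cancels
                    var_diff, df = 2.0 * fit.ms_error / n, fit.df_error
                else:
                    var_diff, df = 2.0 * cell_var, cell_df
                combos.append((f"{ca[0]}/{ca[1]}", f"{cb[0]}/{cb[1]}", diff, var_diff, df))
        k = g * v
    else:
        raise InvalidParameterError(
            f"unknown factor {factor!r}; expected {fit.between!r}, {fit.within!r} "
            f"or '{fit.between}:{fit.within}'"
        )
    rows = []
    for a, b, diff, var_diff, df in combos:
        se = math.sqrt(var_diff)
        rows.append(
            {
                "level_1": a,
                "level_2": b,
                "diff": diff,
                "se": se,
                "df": df,
                "p_tukey": _tukey_p(diff, se, k, df),
                "p_unadjusted": _t_p(diff, se, df),
            }
        )
    return pd.DataFrame(rows)


def _cell_lookup(cells: CellMeans, label: str) -> float:
    key = (label[:-1].upper(), int(label[-1]))
    if key not in cells.cells:
        raise SchemaError(f"missing cell {label!r} (group {key[0]}, visit {key[1]})")
    return cells.cells[key].mean


def contrast_eq1(cells: CellMeans, fit: RmAnovaFit | None = None) -> ContrastEstimate:
    """Visit-1 stimulation contrast: mean of the two unstimulated groups'
    visit-1 cells minus the stimulated group's visit-1 cell,
    ``(nt1 + nn1)/2 - tn1``.

    A positive value means the stimulated group showed less uncertainty at
    visit 1.  With a model handle, the SE uses the between-participant
    error term (this contrast compares disjoint participant sets) and the
    95% CI and p-value are Wald-type, unadjusted.
    """
    est = (_cell_lookup(cells, "nt1") + _cell_lookup(cells, "nn1")) / 2.0 - _cell_lookup(
        cells, "tn1"
    )
    label = "(NT1 + NN1)/2 - TN1"
    if fit is None:
        return ContrastEstimate(estimate=est, label=label)
    cell_var, df = fit._between_cell_var_and_df()
    se = math.sqrt((0.25 + 0.25 + 1.0) * cell_var)
    tcrit = sps.t.ppf(0.975, df)
    return ContrastEstimate(
        estimate=est,
        label=label,
        se=se,
        ci_low=est - tcrit * se,
        ci_high=est + tcrit * se,
        p_value=_t_p(est, se, df),
        df=df,
    )


def contrast_eq2(cells: CellMeans, fit: RmAnovaFit | None = None) -> ContrastEstimate:
    """Across-visit difference-in-differences: ``(nt1 - nt2) - (nn1 - nn2)``.

    The stimulated (NT) group's visit-1 to visit-2 improvement minus the
    never-stimulated (NN) group's improvement — the stimulation effect net
    of practice.  Within-participant differences cancel the participant
    random effect, so the SE uses the residual error term.  Unadjusted.
    """
    est = (_cell_lookup(cells, "nt1") - _cell_lookup(cells, "nt2")) - (
        _cell_lookup(cells, "nn1") - _cell_lookup(cells, "nn2")
    )
    label = "(NT1 - NT2) - (NN1 - NN2)"
    if fit is None:
        return ContrastEstimate(estimate=est, label=label)
    se = math.sqrt(4.0 * fit.ms_error / fit.n_per_group)
    df = fit.df_error
    tcrit = sps.t.ppf(0.975, df)
    return ContrastEstimate(
        estimate=est,
        label=label,
        se=se,
        ci_low=est - tcrit * se,
        ci_high=est + tcrit * se,
        p_value=_t_p(est, se, df),
        df=df,
    )


def cohens_d(mean1: float, sd1: float, mean2: float, sd2: float) -> float:
    """Standardized mean difference with the pooled-SD (independent-cells)
    denominator ``sqrt((sd1^2 + sd2^2) / 2)``."""
    if sd1 < 0 or sd2 < 0:
        raise InvalidParameterError("SDs must be non-negative")
    if sd1 == 0 and sd2 == 0:
        if mean1 == mean2:
            return 0.0
        raise InvalidParameterError("d undefined: zero variance with unequal means")
    return (mean1 - mean2) / math.sqrt((sd1**2 + sd2**2) / 2.0)


def balance_anova(
    vtc: pd.DataFrame,
    response: str = "mean_vtc",
    subject: str = "participant_id",
    between: str = "tens",
    within: str = "condition",
) -> tuple[AnovaTable, RmAnovaFit, pd.DataFrame]:
    """Stimulation-by-condition repeated-measures ANOVA on mean VTC.

    Expects one row per participant per mCTSIB condition (all four
    conditions present).  Returns the F table, the model handle, and Tukey
    pairwise comparisons between conditions.
    """
    table, fit = fit_rm_anova(
        vtc, response=response, subject=subject, between=between, within=within
    )
    followups = tukey_pairwise(fit, within)
    return table, fit, followups
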