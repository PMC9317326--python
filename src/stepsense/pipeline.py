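"""End-to-end driver: simulate, summarize, analyze, report.

Mirrors the study's analysis chain: generate the crossover cohort and the
visit-1 mCTSIB sway traces, compute per-participant regression summaries and
mean VTC, then run the group-by-visit ANOVA with Tukey follow-ups, the two
planned stimulation contrasts, effect sizes, and the stimulation-by-condition
balance ANOVA.  Deterministic given the configured seed.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import stats as st
from .cohort import make_cohort, generate_cop_trace, tens_on
from .io import RunConfig, write_cop, write_trials
from .uncertainty import rmse_table
from .vtc import mean_vtc, vtc_series

log = logging.getLogger("stepsense")


def simulate_balance_trials(config: RunConfig) -> pd.DataFrame:
    """Synthetic visit-1 mCTSIB table for the NN (no TENS) and TN (TENS) groups.

    One 30 s trace per participant per condition; the balance comparison uses
    visit 1, where only the TN group is stimulated.  Returns one row per
    participant-condition with the trial-mean VTC.
    """
    cfg = config.resolved()
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x0C0]))
    rows = []
    bos = cfg.vtc.boundary()
    for group in ("NN", "TN"):
        for i in range(cfg.design.n_per_group):
            pid = f"{group}{i + 1:02d}"
            for condition in (1, 2, 3, 4):
                trace = generate_cop_trace(cfg.cop, condition, rng)
                series = vtc_series(
                    trace, bos=bos, tau_max=cfg.vtc.tau_max_s, cutoff=cfg.vtc.cutoff_hz
                )
                rows.append(
                    {
                        "participant_id": pid,
                        "group": group,
                        "tens": tens_on(group, 1),
                        "condition": condition,
                        "mean_vtc": mean_vtc(series, cfg.vtc.cap_policy),
                        "capped_fraction": series.capped_fraction,
                    }
                )
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Run the full chain and (optionally) write all artifacts to ``out_dir``.

    Returns a results dictionary with the trial table, per-participant
    parameters, RMSE summaries, VTC table, ANOVA tables, Tukey comparisons,
    planned contrasts and effect sizes.
    """
    cfg = config.resolved()
    log.info("generating cohort (seed=%d, %d rows)", cfg.seed, cfg.design.n_rows)
    trials, participants = make_cohort(cfg.design)
    log.info(
        "effective per-participant noise parameters:\n%s",
        participants.to_string(index=False),
    )
    summaries = rmse_table(trials, per_block=cfg.per_block)
    results: dict = {
        "trials": trials,
        "participants": participants,
        "rmse": summaries,
        "warnings": [],
    }

    if summaries["rmse"].std() == 0:
        results["warnings"].append(
            "degenerate variance: all RMSE values identical; inferential "
            "statistics are uninformative"
        )
    anova, fit = st.fit_rm_anova(summaries, response="rmse")
    cells = st.CellMeans.from_table(summaries, "rmse", "group", "visit")
    results["anova"] = anova.table
    results["anova_fit"] = fit
    results["tukey_cells"] = st.tukey_pairwise(fit, "group:visit")
    results["contrasts"] = [
        st.contrast_eq1(cells, fit),
        st.contrast_eq2(cells, fit),
    ]
    results["cell_means"] = cells
    results["effect_sizes"] = {
        g: st.cohens_d(
            cells.cells[(g, 1)].mean,
            cells.cells[(g, 1)].sd,
            cells.cells[(g, 2)].mean,
            cells.cells[(g, 2)].sd,
        )
        for g in ("NN", "NT", "TN")
    }

    log.info("simulating mCTSIB balance traces")
    vtc_df = simulate_balance_trials(cfg)
    results["vtc"] = vtc_df
    bal_table, bal_fit, bal_tukey = st.balance_anova(vtc_df)
    results["balance_anova"] = bal_table.table
    results["balance_fit"] = bal_fit
    results["balance_tukey"] = bal_tukey

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        cfg.to_yaml(out / "config.yaml")
        write_trials(trials, out / "trials.csv")
        participants.to_csv(out / "participants.csv", index=False)
        summaries.to_csv(out / "rmse.csv", index=False)
        vtc_df.to_csv(out / "vtc.csv", index=False)
        from .io import write_report

        write_report(results, out / "report")
        if cfg.make_figures:
            _make_figures(results, out / "figures")
    return results


def _make_figures(results: dict, fig_dir: Path) -> None:
    """Group-by-visit RMSE means with error bars, and one participant's
    deviation-vs-shift scatter with its fitted line."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig_dir.mkdir(parents=True, exist_ok=True)
    cells = results["cell_means"]
    fig, ax = plt.subplots(figsize=(5, 4))
    for group, marker in (("NN", "o"), ("NT", "s"), ("TN", "^")):
        means = [cells.cells[(group, v)].mean for v in (1, 2)]
        sds = [cells.cells[(group, v)].sd for v in (1, 2)]
        n = cells.cells[(group, 1)].n
        sems = [s / np.sqrt(n) for s in sds]
        ax.errorbar([1, 2], means, yerr=sems, marker=marker, capsize=3, label=group)
    ax.set_xticks([1, 2])
    ax.set_xlabel("visit")
    ax.set_ylabel("uncertainty (RMSE, cm)")
    ax.legend(title="group")
    fig.tight_layout()
    fig.savefig(fig_dir / "rmse_by_group_visit.png", dpi=150)
    plt.close(fig)

    trials = results["trials"]
    first = trials[
        (trials["participant_id"] == trials["participant_id"].iloc[0])
        & (trials["visit"] == 1)
    ]
    from .uncertainty import fit_deviation_regression

    summ = fit_deviation_regression(first["shift"].to_numpy(), first["deviation"].to_numpy())
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(first["shift"], first["deviation"], s=8, alpha=0.4)
    xs = np.linspace(first["shift"].min(), first["shift"].max(), 50)
    ax.plot(xs, summ.intercept + summ.slope * xs, color="k",
            label=f"slope={summ.slope:.2f}, RMSE={summ.rmse:.2f} cm")
    ax.set_xlabel("imposed shift (cm)")
    ax.set_ylabel("radial deviation (cm)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(fig_dir / "deviation_vs_shift.png", dpi=150)
    plt.close(fig)


def run_null_interaction_simulation(
    n_sims: int,
    seed: int,
    n_per_group: int = 5,
    n_blocks: int = 1,
) -> float:
    """Fraction of null cohorts whose group-by-visit interaction test rejects
    at alpha = 0.05.

    Null cohorts carry between-participant variability but no stimulation,
    practice or retention effects, so the interaction's rejection rate
    estimates the test's type-I error.
    """
    from .cohort import CohortDesign

    rejections = 0
    for k in range(n_sims):
        design = CohortDesign(
            n_per_group=n_per_group,
            n_blocks=n_blocks,
            tens_effect=0.0,
            visit_effect=0.0,
            retention_effect=0.0,
            seed=int(np.random.SeedSequence([seed, k]).generate_state(1)[0] % (2**31)),
        )
        trials, _ = make_cohort(design)
        summaries = rmse_table(trials, per_block=True)
        anova, _ = st.fit_rm_anova(summaries, response="rmse")
        if anova.effect("group:visit")["p"] < 0.05:
            rejections += 1
    return rejections / n_sims
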