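"""The regression-RMSE uncertainty statistic.

Each participant-visit (optionally per assessment block) contributes an
ordinary least squares regression of trial deviation on imposed shift.  The
slope measures how strongly the learned shift expectation pulls the
response; the root mean squared error about the line is the behavioral
proxy for the uncertainty of the nervous system's position estimate.
RMSE uses the literal sqrt(SSE/n) definition rather than the
degrees-of-freedom-corrected sqrt(SSE/(n-2)); at the 100-500 trials per fit
used here the two differ by under 1%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import (
    DegenerateDesignError,
    InsufficientDataError,
    NonInvertibleError,
    SchemaError,
)

REQUIRED_TRIAL_COLUMNS = ("participant_id", "group", "visit", "block", "shift", "deviation")


@dataclass(frozen=True)
class RegressionSummary:
    """One deviation-vs-shift OLS fit for a participant-visit(-block)."""

    participant_id: str | None
    group: str | None
    visit: int | None
    block: int | None
    n_trials: int
    slope: float
    intercept: float
    rmse: float
    r_squared: float


def fit_deviation_regression(
    shift: np.ndarray,
    deviation: np.ndarray,
    *,
    participant_id: str | None = None,
    group: str | None = None,
    visit: int | None = None,
    block: int | None = None,
) -> RegressionSummary:
    """OLS of deviation on shift; RMSE is sqrt(SSE/n).

    Requires at least 3 trials and non-degenerate shift variance.
    """
    shift = np.asarray(shift, dtype=float)
    deviation = np.asarray(deviation, dtype=float)
    if shift.shape != deviation.shape or shift.ndim != 1:
        raise SchemaError("shift and deviation must be 1-D arrays of equal length")
    n = shift.size
    if n < 3:
        raise InsufficientDataError(f"need >= 3 trials for a regression, got {n}")
    if not (np.all(np.isfinite(shift)) and np.all(np.isfinite(deviation))):
        raise SchemaError("shift and deviation must be finite")
    sx = shift - shift.mean()
    sxx = float(sx @ sx)
    if sxx <= 0:
        raise DegenerateDesignError("zero variance in shift; slope is undefined")
    slope = float(sx @ (deviation - deviation.mean()) / sxx)
    intercept = float(deviation.mean() - slope * shift.mean())
    resid = deviation - (intercept + slope * shift)
    sse = float(resid @ resid)
    sst = float(np.sum((deviation - deviation.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else 1.0
    return RegressionSummary(
        participant_id=participant_id,
        group=group,
        visit=visit,
        block=block,
        n_trials=n,
        slope=slope,
        intercept=intercept,
        rmse=math.sqrt(sse / n),
        r_squared=r2,
    )


def recover_sensory_noise(
    slope: float, rmse: float, sigma_prior: float = 2.5
) -> tuple[float, float, bool]:
    """Invert the observer model: map (slope, rmse) back to noise SDs.

    From ``slope = sv^2/(sv^2 + sp^2)`` comes
    ``sv_hat = sp * sqrt(slope / (1 - slope))``; the motor SD is then the
    residual variance left after the visual term,
    ``sm_hat = sqrt(max(0, rmse^2 - (1-slope)^2 sv_hat^2))``.  Returns
    ``(sv_hat, sm_hat, clamped)`` where ``clamped`` flags an RMSE below the
    visual floor (sampling noise can push it there).
    """
    if not sigma_prior > 0:
        raise NonInvertibleError("sigma_prior must be > 0")
    if not 0.0 < slope < 1.0:
        raise NonInvertibleError(
            f"slope {slope:.4f} outside (0, 1): the weight sv^2/(sv^2+sp^2) "
            "cannot produce it, so no noise parameters exist"
        )
    if rmse < 0:
        raise NonInvertibleError("rmse must be non-negative")
    sv_hat = sigma_prior * math.sqrt(slope / (1.0 - slope))
    visual_var = (1.0 - slope) ** 2 * sv_hat**2
    sm2 = rmse**2 - visual_var
    clamped = sm2 < 0
    return sv_hat, math.sqrt(max(0.0, sm2)), clamped


def rmse_table(trials: pd.DataFrame, per_block: bool = True) -> pd.DataFrame:
    """Fit the deviation regression for every participant-visit(-block).

    With ``per_block=True`` (default) each of the five assessment blocks is
    its own observation, matching an analysis in which every participant
    contributes several values per visit; ``per_block=False`` pools a
    visit's trials into a single fit.  Rows with ``block == 0`` are treated
    as the training block and excluded.
    """
    missing = [c for c in REQUIRED_TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise SchemaError(f"trial table is missing column(s): {', '.join(missing)}")
    data = trials[trials["block"] != 0]
    keys = ["participant_id", "group", "visit"] + (["block"] if per_block else [])
    rows = []
    for key, sub in data.groupby(keys, sort=True):
        ident = dict(zip(keys, key))
        summary = fit_deviation_regression(
            sub["shift"].to_numpy(),
            sub["deviation"].to_numpy(),
            participant_id=ident["participant_id"],
            group=ident["group"],
            visit=int(ident["visit"]),
            block=int(ident["block"]) if per_block else None,
        )
        rows.append(summary.__dict__)
    out = pd.DataFrame(rows)
    if not per_block:
        out = out.drop(columns=["block"])
    return out
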