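"""Bayesian observer model of the shifted-cursor stepping task.

On each trial a backward radial shift ``s`` (cm) is added to the cursor that
tracks the participant's center of mass.  The observer only glimpses the
shifted cursor mid-movement, through visual noise of standard deviation
``sigma_visual``, and combines that likelihood with a prior over shifts
learned during training.  Under quadratic loss the posterior-mean estimate of
the shift is

    s_hat = w * mu_prior + (1 - w) * (s + e_v),      w = sv^2 / (sv^2 + sp^2)

where ``sp`` is the believed prior SD.  The participant compensates by
stepping ``s_hat`` further, so the signed radial deviation of the final
cursor from the target is

    y = s - s_hat + e_m = w * (s - mu_prior) - (1 - w) * e_v + e_m

with motor execution noise ``e_m``.  Regressing ``y`` on ``s`` across trials
therefore has expected slope ``w`` (the prior's influence) and residual RMSE
``sqrt((1 - w)^2 sv^2 + sm^2)`` — the behavioral proxy for the uncertainty of
the central nervous system's position estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .errors import InvalidParameterError

#: Mean (cm) of the imposed backward shift distribution used in the protocol.
DEFAULT_SHIFT_MU = -7.5
#: SD (cm) of the imposed shift distribution.
DEFAULT_SHIFT_SIGMA = 2.5


@dataclass(frozen=True)
class ObserverParams:
    """Generative and believed parameters of one simulated participant-visit.

    Parameters
    ----------
    mu_prior_true, sigma_prior_true
        Mean and SD (cm) of the distribution the imposed shifts are actually
        drawn from.
    mu_prior_belief, sigma_prior_belief
        The observer's learned prior over shifts.  A *well-calibrated*
        observer has belief equal to truth, which is the default after the
        training block is assumed to have converged.
    sigma_visual
        SD (cm) of the noise corrupting the mid-movement glimpse of the
        cursor.
    sigma_motor
        SD (cm) of execution noise added to the final deviation.
    """

    mu_prior_true: float = DEFAULT_SHIFT_MU
    sigma_prior_true: float = DEFAULT_SHIFT_SIGMA
    mu_prior_belief: float | None = None
    sigma_prior_belief: float | None = None
    sigma_visual: float = 0.0
    sigma_motor: float = 0.0

    def __post_init__(self) -> None:
        if self.mu_prior_belief is None:
            object.__setattr__(self, "mu_prior_belief", self.mu_prior_true)
        if self.sigma_prior_belief is None:
            object.__setattr__(self, "sigma_prior_belief", self.sigma_prior_true)
        if not self.sigma_prior_true > 0:
            raise InvalidParameterError("sigma_prior_true must be > 0")
        if not self.sigma_prior_belief > 0:
            raise InvalidParameterError("sigma_prior_belief must be > 0")
        if self.sigma_visual < 0 or self.sigma_motor < 0:
            raise InvalidParameterError("noise SDs must be non-negative")
        for name in ("mu_prior_true", "mu_prior_belief"):
            if not math.isfinite(getattr(self, name)):
                raise InvalidParameterError(f"{name} must be finite")

    @property
    def is_well_calibrated(self) -> bool:
        return (
            self.mu_prior_belief == self.mu_prior_true
            and self.sigma_prior_belief == self.sigma_prior_true
        )

    def with_noise(self, sigma_visual: float, sigma_motor: float) -> "ObserverParams":
        """Return a copy with different noise magnitudes."""
        return replace(self, sigma_visual=sigma_visual, sigma_motor=sigma_motor)


def prior_weight(sigma_visual: float, sigma_prior_belief: float) -> float:
    """Weight the posterior-mean estimate places on the prior mean.

    ``w = sigma_visual^2 / (sigma_visual^2 + sigma_prior_belief^2)`` — the
    standard reliability-weighted cue combination.  Equals the expected slope
    of the deviation-vs-shift regression for a well-calibrated observer:
    noiseless vision (``w = 0``) compensates fully, while an uninformative
    glimpse pushes the response onto the prior (``w -> 1``).
    """
    if not sigma_prior_belief > 0:
        raise InvalidParameterError("sigma_prior_belief must be > 0")
    if sigma_visual < 0:
        raise InvalidParameterError("sigma_visual must be non-negative")
    sv2 = sigma_visual**2
    return sv2 / (sv2 + sigma_prior_belief**2)


def simulate_deviation(
    observer: ObserverParams,
    shift: float | np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw signed radial deviations (cm) for the given imposed shifts.

    Vectorized over ``shift``.  Implements
    ``y = w (s - mu_belief) - (1 - w) e_v + e_m`` with
    ``e_v ~ N(0, sigma_visual^2)`` and ``e_m ~ N(0, sigma_motor^2)``.
    """
    shift = np.asarray(shift, dtype=float)
    if not np.all(np.isfinite(shift)):
        raise InvalidParameterError("shift values must be finite")
    w = prior_weight(observer.sigma_visual, observer.sigma_prior_belief)
    e_v = rng.normal(0.0, observer.sigma_visual, size=shift.shape)
    e_m = rng.normal(0.0, observer.sigma_motor, size=shift.shape)
    return w * (shift - observer.mu_prior_belief) - (1.0 - w) * e_v + e_m


def expected_regression(observer: ObserverParams) -> tuple[float, float]:
    """Population slope and residual RMSE of the deviation-vs-shift regression.

    Because the conditional mean of the deviation is linear in the shift with
    slope ``w`` for any belief parameters, the population regression slope is
    ``w`` and the residual SD about the line is
    ``sqrt((1 - w)^2 sigma_visual^2 + sigma_motor^2)`` regardless of the
    believed prior mean (a mean mis-belief moves only the intercept).
    These are the values the empirical per-participant regression recovers.
    """
    w = prior_weight(observer.sigma_visual, observer.sigma_prior_belief)
    rmse = math.sqrt((1.0 - w) ** 2 * observer.sigma_visual**2 + observer.sigma_motor**2)
    return w, rmse
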