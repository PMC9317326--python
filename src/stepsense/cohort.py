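"""Synthetic crossover-study data: trial tables and CoP sway traces.

Emulates the three-group (NN/NT/TN) two-visit crossover in which
transcutaneous electric nerve stimulation (TENS) is applied to the lower
limbs during one visit for the NT (visit 2) and TN (visit 1) groups.  Each
participant-visit contributes five 100-trial assessment blocks of the
shifted-cursor stepping task, with shifts drawn from N(-7.5, 2.5) cm, plus
four 30 s balance trials in mCTSIB-style sensory conditions.

The noise defaults are calibrated so the expected group-by-visit mean RMSE
reproduces the magnitude and ordering of published human data (about
2.7 cm without TENS at visit 1, dropping to about 2.1 cm with practice and
stimulation); see ``docs/methods.md`` for the closed-form calibration.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, NamedTuple

import numpy as np
import pandas as pd

from .errors import GenerationError, InvalidParameterError
from .observer import (
    DEFAULT_SHIFT_MU,
    DEFAULT_SHIFT_SIGMA,
    ObserverParams,
    expected_regression,
    simulate_deviation,
)
from .vtc import BaseOfSupport, CoPTrace

GROUPS = ("NN", "NT", "TN")

#: Calibrated generator defaults (cm).  With a 2.5 cm prior SD the visual
#: residual term is bounded by 1.25 cm, so execution noise carries most of
#: the ~2.7 cm baseline RMSE; TENS sharpens the sensory likelihood while the
#: practice effect between visits trims execution noise.
SIGMA_VISUAL_DEFAULT = 2.5
SIGMA_MOTOR_DEFAULT = 2.365
TENS_EFFECT_DEFAULT = 1.91
VISIT_EFFECT_DEFAULT = 0.316
RETENTION_EFFECT_DEFAULT = 1.91


def tens_on(group: str, visit: int) -> bool:
    """Whether stimulation is active for a given group and visit."""
    return (group == "TN" and visit == 1) or (group == "NT" and visit == 2)


@dataclass(frozen=True)
class CohortDesign:
    """Design and effect structure of one simulated cohort.

    Effects are expressed as absolute reductions (cm) of a noise SD:
    ``tens_effect`` while stimulation is on, ``visit_effect`` on the second
    visit (practice), and ``retention_effect`` on the TN group's second
    visit (carry-over of the visit-1 stimulation benefit).  Each effect can
    target either the visual or the motor noise SD.
    """

    n_per_group: int = 10
    n_visits: int = 2
    n_blocks: int = 5
    trials_per_block: int = 100
    shift_mu: float = DEFAULT_SHIFT_MU
    shift_sigma: float = DEFAULT_SHIFT_SIGMA
    sigma_visual: float = SIGMA_VISUAL_DEFAULT
    sigma_motor: float = SIGMA_MOTOR_DEFAULT
    tens_effect: float = TENS_EFFECT_DEFAULT
    visit_effect: float = VISIT_EFFECT_DEFAULT
    retention_effect: float = RETENTION_EFFECT_DEFAULT
    tens_target: Literal["visual", "motor"] = "visual"
    visit_target: Literal["visual", "motor"] = "motor"
    retention_target: Literal["visual", "motor"] = "visual"
    between_sd_visual: float = 0.25
    between_sd_motor: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 1 or self.n_blocks < 1 or self.trials_per_block < 1:
            raise InvalidParameterError("cohort counts must be >= 1")
        if self.n_visits != 2:
            raise InvalidParameterError("the crossover design has exactly 2 visits")
        if not self.shift_sigma > 0:
            raise InvalidParameterError("shift_sigma must be > 0")
        if self.sigma_visual < 0 or self.sigma_motor < 0:
            raise InvalidParameterError("baseline noise SDs must be non-negative")
        if self.between_sd_visual < 0 or self.between_sd_motor < 0:
            raise InvalidParameterError("between-participant SDs must be non-negative")

    @property
    def n_rows(self) -> int:
        return len(GROUPS) * self.n_per_group * self.n_visits * self.n_blocks * self.trials_per_block


class CohortTables(NamedTuple):
    """Trial-level table plus the effective per-participant-visit parameters."""

    trials: pd.DataFrame
    participants: pd.DataFrame


def sample_shifts(n: int, mu: float, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` i.i.d. imposed cursor shifts (cm) from N(mu, sigma^2)."""
    if n < 1:
        raise InvalidParameterError("n must be >= 1")
    if not sigma > 0:
        raise InvalidParameterError("sigma must be > 0")
    return rng.normal(mu, sigma, size=n)


def _lognormal_draws(
    mean: float, sd: float, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Lognormal draws moment-matched to the given mean and SD (sd=0 -> constant)."""
    if mean == 0 or sd == 0:
        return np.full(size, mean)
    s2 = math.log1p((sd / mean) ** 2)
    return rng.lognormal(math.log(mean) - s2 / 2, math.sqrt(s2), size=size)


def make_cohort(design: CohortDesign) -> CohortTables:
    """Simulate the full crossover cohort.

    Per-participant baseline noise SDs are drawn once (lognormal around the
    design baselines), then the TENS, practice and retention reductions are
    applied per visit; SDs are clamped at zero (with a warning) if a
    reduction overshoots.  Deviations come from the Bayesian observer.
    The result is a pure function of ``design`` (including its seed).
    """
    rng = np.random.default_rng(design.seed)
    n_p = design.n_per_group
    participants = [(g, f"{g}{i + 1:02d}") for g in GROUPS for i in range(n_p)]
    base_sv = _lognormal_draws(design.sigma_visual, design.between_sd_visual, len(participants), rng)
    base_sm = _lognormal_draws(design.sigma_motor, design.between_sd_motor, len(participants), rng)

    trials_per_visit = design.n_blocks * design.trials_per_block
    trial_frames = []
    param_rows = []
    n_clamped = 0
    for idx, (group, pid) in enumerate(participants):
        for visit in range(1, design.n_visits + 1):
            sv, sm = base_sv[idx], base_sm[idx]
            reductions = []
            if tens_on(group, visit):
                reductions.append((design.tens_target, design.tens_effect))
            if visit == 2:
                reductions.append((design.visit_target, design.visit_effect))
                if group == "TN":
                    reductions.append((design.retention_target, design.retention_effect))
            for target, amount in reductions:
                if target == "visual":
                    sv -= amount
                else:
                    sm -= amount
            if sv < 0 or sm < 0:
                n_clamped += 1
                sv, sm = max(sv, 0.0), max(sm, 0.0)
            observer = ObserverParams(
                mu_prior_true=design.shift_mu,
                sigma_prior_true=design.shift_sigma,
                sigma_visual=sv,
                sigma_motor=sm,
            )
            shifts = sample_shifts(trials_per_visit, design.shift_mu, design.shift_sigma, rng)
            deviations = simulate_deviation(observer, shifts, rng)
            slope, rmse = expected_regression(observer)
            trial_frames.append(
                pd.DataFrame(
                    {
                        "participant_id": pid,
                        "group": group,
                        "visit": visit,
                        "block": np.repeat(
                            np.arange(1, design.n_blocks + 1), design.trials_per_block
                        ),
                        "trial": np.tile(
                            np.arange(1, design.trials_per_block + 1), design.n_blocks
                        ),
                        "target_direction": rng.integers(1, 6, size=trials_per_visit),
                        "shift": shifts,
                        "deviation": deviations,
                    }
                )
            )
            param_rows.append(
                {
                    "participant_id": pid,
                    "group": group,
                    "visit": visit,
                    "tens": tens_on(group, visit),
                    "sigma_visual": sv,
                    "sigma_motor": sm,
                    "expected_slope": slope,
                    "expected_rmse": rmse,
                }
            )
    if n_clamped:
        warnings.warn(
            f"noise SD clamped at 0 for {n_clamped} participant-visit(s); "
            "effect reductions exceed the drawn baseline",
            stacklevel=2,
        )
    trials = pd.concat(trial_frames, ignore_index=True)
    return CohortTables(trials=trials, participants=pd.DataFrame(param_rows))


@dataclass(frozen=True)
class CoPParams:
    """Parameters of the synthetic mCTSIB sway generator.

    ``sway_scale`` sets the stationary anterior-posterior RMS amplitude (cm)
    per sensory condition (rigid/eyes-open through compliant/eyes-closed) and
    must be non-decreasing; medio-lateral sway is ``ml_ratio`` of it.  Sway is
    an exact-discretization Ornstein-Uhlenbeck process with the given
    correlation time constant: zero-mean, stationary, temporally smooth.
    """

    duration: float = 30.0  # s
    rate: float = 25.0  # Hz
    sway_scale: tuple[float, float, float, float] = (0.35, 0.55, 0.65, 1.0)
    time_constant: float = 0.8  # s
    ml_ratio: float = 0.6
    boundary: BaseOfSupport = field(default_factory=BaseOfSupport)

    def __post_init__(self) -> None:
        n = self.duration * self.rate
        if abs(n - round(n)) > 1e-9 or n < 2:
            raise InvalidParameterError("duration * rate must be an integer sample count >= 2")
        if any(s < 0 for s in self.sway_scale):
            raise InvalidParameterError("sway scales must be non-negative")
        if list(self.sway_scale) != sorted(self.sway_scale):
            raise InvalidParameterError("sway scales must be non-decreasing across conditions")
        if not self.time_constant > 0:
            raise InvalidParameterError("time constant must be positive")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.rate))


def _ou_path(n: int, scale: float, phi: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary AR(1)/OU path with SD ``scale`` and lag-1 correlation ``phi``."""
    if scale == 0:
        return np.zeros(n)
    x = np.empty(n)
    x[0] = rng.normal(0.0, scale)
    innov = rng.normal(0.0, scale * math.sqrt(1.0 - phi**2), size=n - 1)
    for k in range(1, n):
        x[k] = phi * x[k - 1] + innov[k - 1]
    return x


def generate_cop_trace(
    params: CoPParams, condition: int, rng: np.random.Generator, max_attempts: int = 100
) -> CoPTrace:
    """Generate one synthetic 2-D CoP sway trace for an mCTSIB condition.

    Traces whose excursion leaves the base of support are rejected and
    redrawn; after ``max_attempts`` failures a ``GenerationError`` is raised
    (the sway scale is then too large for the boundary).
    """
    if condition not in (1, 2, 3, 4):
        raise InvalidParameterError("condition must be in 1..4")
    n = params.n_samples
    dt = 1.0 / params.rate
    phi = math.exp(-dt / params.time_constant)
    scale = params.sway_scale[condition - 1]
    t = np.arange(n) * dt
    bos = params.boundary.recentered((0.0, 0.0))
    for _ in range(max_attempts):
        ap = _ou_path(n, scale, phi, rng)
        ml = _ou_path(n, scale * params.ml_ratio, phi, rng)
        if np.all(bos.signed_outside(ml, ap) < 0):
            return CoPTrace(t=t, ap=ap, ml=ml, rate=params.rate)
    raise GenerationError(
        f"could not keep sway scale {scale} cm inside the base of support "
        f"after {max_attempts} attempts"
    )
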