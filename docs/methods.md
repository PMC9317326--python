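# Methods

## Observer model

The generative core is a Bayesian ideal observer with a posterior-mean
(quadratic-loss) readout, the standard model behind slope/RMSE analyses of
shifted-feedback paradigms. Per trial, with imposed shift `s` (cm):

```
ŝ = w·μ_belief + (1 − w)·(s + e_v),   w = σ_v²/(σ_v² + σ_b²)
y = s − ŝ + e_m = w·(s − μ_belief) − (1 − w)·e_v + e_m
```

where `σ_b` is the believed prior SD, `e_v ~ N(0, σ_v²)` the visual noise on
the mid-movement glimpse and `e_m ~ N(0, σ_m²)` execution noise. The
conditional mean of `y` is linear in `s` for *any* belief parameters, so the
population regression of deviation on shift has slope `w` and residual RMSE
`√((1 − w)²σ_v² + σ_m²)`; a mis-believed prior mean moves only the
intercept. Assumptions worth keeping in mind:

* deviations are one-dimensional signed radial quantities; the five target
  directions are bookkeeping only (the pooled-radial analysis treats them
  identically, and no direction-specific bias is modeled);
* prior learning is taken as converged before the assessment blocks — the
  believed prior defaults to the true shift distribution; mis-calibrated
  beliefs are available for sensitivity studies but no trial-by-trial
  updating is simulated;
* an important structural bound: with prior SD `σ_p = 2.5` cm the visual
  contribution to RMSE, `σ_v σ_p²/(σ_v² + σ_p²)`, is at most `σ_p/2 =
  1.25` cm (maximized at `σ_v = σ_p`). Empirical uncertainty values of
  2–3 cm therefore *require* a motor-noise term; `σ_m > 0` is not optional
  in the defaults.

## Synthetic cohort and calibration

The generator emulates a balanced three-group (NN/NT/TN) × two-visit
crossover, 10 participants per group, five 100-trial assessment blocks per
visit, shifts drawn i.i.d. from N(−7.5, 2.5) cm. Per-participant baseline
noise SDs are drawn once from moment-matched lognormals (SD 0.25 cm around
the baselines) and three deterministic reductions are applied:

| parameter | default (cm) | acts on | meaning |
|---|---|---|---|
| `sigma_visual` | 2.5 | — | baseline glimpse noise |
| `sigma_motor` | 2.365 | — | baseline execution noise |
| `tens_effect` | 1.91 | `σ_v` | sensory-noise reduction while stimulated |
| `visit_effect` | 0.316 | `σ_m` | practice effect on visit 2 |
| `retention_effect` | 1.91 | `σ_v` | carried-over benefit, TN visit 2 |

TENS acts on the sensory likelihood (the interpretation that stimulation
sharpens somatosensory input); the target of each effect is configurable
(`tens_target="motor"` etc.) for sensitivity analyses. Reductions that
overshoot a participant's drawn baseline clamp the SD at zero with a
warning.

The defaults were calibrated once, in closed form, so that the expected
cell-mean RMSE reproduces published human magnitudes: a no-TENS visit-1
baseline of 2.675 cm (`σ_v = 2.5` puts the visual term at its 1.25 cm
maximum, leaving `σ_m = √(2.675² − 1.25²) = 2.365`), a stimulated visit-1
value of 2.43 cm (solve `σ_v·σ_p²/(σ_v²+σ_p²) = √(2.43² − σ_m²)` →
`σ_v = 0.59`, i.e. a 1.91 cm reduction), and an unstimulated visit-2 value
of 2.40 cm (`σ_m = 2.049`, a 0.316 cm reduction). The same closed forms put
the stimulated-and-practiced cells at 2.12 cm. Two consequences are
deliberate: the two no-TENS visit-1 cells share one expected value (their
published difference is between-group sampling noise, which a common-baseline
generator should not build in), and the practice effect must act on `σ_m`
— the bound above makes a visual-only account of the full 2.7 → 2.05 cm
range arithmetically impossible. Between-participant SDs of 0.25 cm produce
realistic person-to-person spread without distorting the expected cell
means (Jensen corrections are < 0.01 cm).

The generator does **not** emulate: the training block's learning curve,
direction-specific biases, within-visit drift or fatigue, trial-level
outliers, or the unequal no-TENS baselines real cohorts show. Passing tests
therefore demonstrate that the estimators and inference machinery behave
correctly under the model's assumptions — not that real participants obey
the model.

## Uncertainty statistic

Per participant-visit(-block), ordinary least squares of deviation on shift.
RMSE is the literal `√(SSE/n)` (not the df-corrected `√(SSE/(n−2))`; at
n = 100–500 they differ by < 1%). The default analysis unit is the
**block** (five regressions per visit), giving 300 observations per cohort
and letting the participant random effect absorb the repeated measures;
per-visit pooling is a flag. No outlier trimming is applied. The inverse
mapping `σ̂_v = σ_p√(slope/(1−slope))`,
`σ̂_m = √(max(0, rmse² − (1−slope)²σ̂_v²))` requires slope ∈ (0, 1) and
flags when sampling noise pushes the RMSE below the visual floor (the
`max(0,·)` clamp).

## Virtual time-to-contact

CoP traces are zero-phase low-pass filtered (2nd-order Butterworth applied
forward-backward, 4th-order effective; default cutoff 10 Hz) before double
differentiation by central differences, because differentiation amplifies
high-frequency noise quadratically. Each sample's state `(p, v, a)` is
projected ballistically and the smallest `τ ∈ (0, τ_max]` with
`p + vτ + ½aτ²` on the base-of-support boundary is found by sign-change
bracketing on a 2000-point τ grid followed by bisection to 10⁻⁶ s — robust
to the quartic boundary equation's root structure and verified against the
closed-form conic intersection in tests. Choices an analyst may care about:

* **Boundary**: published work rarely defines it; we use an ellipse centered
  on the trial-mean CoP with semi-axes `a_ml = 5` cm (half feet-together
  stance width) and `b_ap = 12` cm (half foot length), configurable, with a
  convex-polygon alternative.
* **Cap**: projections that never exit within `τ_max = 10` s return `τ_max`
  flagged as capped; the trial mean defaults to *including* capped samples
  (excluding them is a flag, and the capped fraction is always reported).
  The policy changes the mean, hence it is explicit.
* Coordinates: AP positive forward, ML positive rightward.

Synthetic sway is an exact-discretization Ornstein–Uhlenbeck process
(stationary, zero-mean, correlation time 0.8 s) with per-condition AP RMS
amplitudes (0.35, 0.55, 0.65, 1.0) cm and ML at 0.6 of AP. The values mimic
the mCTSIB pattern — sway roughly tripling from rigid-surface/eyes-open to
compliant/eyes-closed, with the two middle conditions close (they are
empirically near-indistinguishable) but strictly ordered so the generator's
rank structure is well defined. Traces leaving the boundary are rejected
and redrawn (up to 100 attempts). These scales put mean VTC at ≈ 0.5–0.8 s,
the sub-second range reported for feet-together stance.

## Statistical layer

The group × visit (and TENS × condition) analyses are balanced split-plot
designs. We average replicate blocks to participant-by-level cell means and
compute the classical decomposition (via `pingouin.mixed_anova`), whose F
tests coincide exactly with the REML linear-mixed-model (participant random
intercept) tests in the balanced case; this also makes the small-sample
null distribution exact, which Wald-type mixed-model chi-squares are not.
Denominator degrees of freedom are therefore containment-style
(`g(n−1)` for between effects, `g(n−1)(v−1)` for within effects);
Satterthwaite approximations are used only where error terms are combined
(below). Unbalanced or incomplete layouts are rejected with a diagnostic
rather than silently reweighted.

Tukey HSD follow-ups use the studentized range with the split-plot error
terms: the participants-within-groups mean square for between comparisons,
the residual mean square for within comparisons, and for cross-group cell
comparisons the standard composite `(MS_subj + (v−1)MS_err)/v` with
Satterthwaite df. Degenerate all-equal data yields F = 0 and p = 1 by
convention.

The planned contrasts are linear functions of cell means. The visit-1
contrast compares disjoint participant sets and uses the composite error
term; the difference-in-differences is purely within-participant (the
random intercept cancels) and uses the residual term. Both are reported
with Wald-type 95% CIs and deliberately **unadjusted** p-values, as planned
exploratory contrasts. Cohen's d uses the pooled-SD two-cell definition
`(m₁ − m₂)/√((s₁² + s₂²)/2)`; note that published repeated-measures d
values computed with an unknown within-participant correlation will
generally exceed this independent-cells value (e.g. printed cells
2.78 ± 0.57 vs 2.24 ± 0.47 give d = 1.03 here).

## Problem sizes and determinism

Every stochastic stage takes a `numpy` `Generator` or integer seed and is a
pure function of it. The test suite exercises the generator at full
published scale (30,000-trial cohorts) for direction-of-effect checks over
20 seeds, 10⁵–10⁶-trial simulations for estimator-vs-closed-form oracles,
500 reduced null cohorts (5 participants/group, one block) for type-I-error
calibration of the interaction test, and 1,000 random states for the
contact-time oracle.

## Known limitations

* The observer is static; learning dynamics, direction-specific biases and
  lapses are not modeled.
* Group-level inference assumes balanced complete data; real dropout
  requires a true mixed-model fit with approximate dfs, which this package
  intentionally does not provide.
* The VTC boundary is a stylized ellipse; subject-specific foot geometry
  matters for absolute (not relative) VTC values.
* Synthetic sway is Gaussian and stationary; real CoP series show
  intermittency and long-range correlations that OU dynamics do not
  reproduce.
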