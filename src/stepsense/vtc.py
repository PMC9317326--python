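"""Virtual time-to-contact (VTC) from center-of-pressure traces.

VTC projects the CoP ballistically from its instantaneous position, velocity
and acceleration and asks how long the projection takes to reach the boundary
of the base of support.  Larger times mean the CoP state is further, in a
dynamical sense, from destabilizing the stance: VTC is a postural-stability
margin.  The pipeline is: zero-phase low-pass filtering, finite-difference
kinematics, then per-sample boundary-crossing search.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from scipy import signal as _signal

from .errors import (
    InsufficientDataError,
    InvalidParameterError,
    StateError,
)

TAU_MAX_DEFAULT = 10.0  # s; cap for projections that never reach the boundary
_GRID_POINTS = 2000  # dense bracketing grid over (0, tau_max]
_BISECT_TOL = 1e-6  # s


@dataclass(frozen=True)
class CoPTrace:
    """Uniformly sampled center-of-pressure trace.

    ``ap`` is anterior-posterior (positive forward), ``ml`` medio-lateral
    (positive rightward), both in cm; ``t`` in seconds.
    """

    t: np.ndarray
    ap: np.ndarray
    ml: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        ap = np.asarray(self.ap, dtype=float)
        ml = np.asarray(self.ml, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "ap", ap)
        object.__setattr__(self, "ml", ml)
        if not (t.shape == ap.shape == ml.shape) or t.ndim != 1:
            raise InvalidParameterError("t, ap, ml must be 1-D arrays of equal length")
        if t.size < 2 or t[-1] - t[0] < 1.0:
            raise InsufficientDataError("need at least 1 s of CoP data")
        dt = np.diff(t)
        if np.any(np.abs(dt - dt[0]) > 1e-9):
            raise InvalidParameterError("CoP trace must be uniformly sampled")
        if not np.all(np.isfinite(ap)) or not np.all(np.isfinite(ml)):
            raise InvalidParameterError("CoP samples must be finite")

    @property
    def n_samples(self) -> int:
        return int(self.t.size)

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])


@dataclass(frozen=True)
class BaseOfSupport:
    """Stance boundary: an ellipse (default) or a convex polygon.

    The default ellipse models a feet-together stance, centered on the trial
    mean CoP, with semi-axes of half the stance width medio-laterally and
    half the foot length antero-posteriorly.
    """

    shape: Literal["ellipse", "polygon"] = "ellipse"
    center: tuple[float, float] = (0.0, 0.0)  # (ml, ap) cm
    a_ml: float = 5.0  # cm, ML semi-axis
    b_ap: float = 12.0  # cm, AP semi-axis
    vertices: np.ndarray | None = None  # (k, 2) array of (ml, ap), convex

    def __post_init__(self) -> None:
        if self.shape == "ellipse":
            if not (self.a_ml > 0 and self.b_ap > 0):
                raise InvalidParameterError("ellipse semi-axes must be positive")
        elif self.shape == "polygon":
            v = np.asarray(self.vertices, dtype=float)
            if v.ndim != 2 or v.shape[0] < 3 or v.shape[1] != 2:
                raise InvalidParameterError("polygon needs >= 3 (ml, ap) vertices")
            object.__setattr__(self, "vertices", v)
            import shapely.geometry as geom

            poly = geom.Polygon(v)
            if not poly.is_valid or abs(poly.area - poly.convex_hull.area) > 1e-9 * poly.area:
                raise InvalidParameterError("polygon must be simple and convex")
        else:
            raise InvalidParameterError(f"unknown boundary shape {self.shape!r}")

    def recentered(self, center: tuple[float, float]) -> "BaseOfSupport":
        if self.shape == "polygon":
            shiftv = np.asarray(center) - np.asarray(self.center)
            return replace(self, center=tuple(center), vertices=self.vertices + shiftv)
        return replace(self, center=tuple(center))

    def scaled(self, k: float) -> "BaseOfSupport":
        """Uniformly scale the boundary about its center by factor ``k``."""
        if k <= 0:
            raise InvalidParameterError("scale factor must be positive")
        if self.shape == "ellipse":
            return replace(self, a_ml=self.a_ml * k, b_ap=self.b_ap * k)
        c = np.asarray(self.center)
        return replace(self, vertices=c + k * (self.vertices - c))

    def signed_outside(self, ml, ap):
        """Signed boundary function: negative inside, zero on, positive outside.

        For the ellipse this is ``(x/a)^2 + (y/b)^2 - 1`` in centered
        coordinates; for a convex polygon, the maximum over edges of the
        outward-normal signed distance.
        """
        ml = np.asarray(ml, dtype=float)
        ap = np.asarray(ap, dtype=float)
        if self.shape == "ellipse":
            x = (ml - self.center[0]) / self.a_ml
            y = (ap - self.center[1]) / self.b_ap
            return x**2 + y**2 - 1.0
        v = self.vertices
        # ensure counter-clockwise ordering so outward normals point outside
        area2 = np.sum(v[:, 0] * np.roll(v[:, 1], -1) - np.roll(v[:, 0], -1) * v[:, 1])
        if area2 < 0:
            v = v[::-1]
        e = np.roll(v, -1, axis=0) - v  # edge vectors
        normals = np.stack([e[:, 1], -e[:, 0]], axis=1)
        normals /= np.linalg.norm(normals, axis=1, keepdims=True)
        p = np.stack([ml, ap], axis=-1)  # (..., 2)
        d = np.einsum("...kj,kj->...k", p[..., None, :] - v, normals)
        return d.max(axis=-1)

    def contains(self, ml, ap) -> np.ndarray:
        return np.asarray(self.signed_outside(ml, ap)) < 0


@dataclass(frozen=True)
class VTCSeries:
    """Per-sample virtual time-to-contact values for one balance trial."""

    t: np.ndarray
    tau: np.ndarray  # s, finite or capped at tau_max
    capped: np.ndarray = field(default=None)  # bool mask of capped samples
    tau_max: float = TAU_MAX_DEFAULT

    def __post_init__(self) -> None:
        tau = np.asarray(self.tau, dtype=float)
        object.__setattr__(self, "tau", tau)
        object.__setattr__(self, "t", np.asarray(self.t, dtype=float))
        capped = (
            np.zeros(tau.shape, dtype=bool)
            if self.capped is None
            else np.asarray(self.capped, dtype=bool)
        )
        object.__setattr__(self, "capped", capped)
        if np.any(tau <= 0):
            raise InvalidParameterError("contact times must be positive")

    @property
    def capped_fraction(self) -> float:
        return float(np.mean(self.capped))


def preprocess_cop(trace: CoPTrace, cutoff: float = 10.0) -> CoPTrace:
    """Zero-phase low-pass filter both CoP axes.

    2nd-order Butterworth applied forward and backward (4th-order effective,
    no phase distortion).  ``cutoff`` must sit below the Nyquist frequency.
    """
    if not 0 < cutoff < trace.rate / 2:
        raise InvalidParameterError(
            f"cutoff {cutoff} Hz must lie in (0, Nyquist={trace.rate / 2} Hz)"
        )
    b, a = _signal.butter(2, cutoff, fs=trace.rate)
    ap = _signal.filtfilt(b, a, trace.ap)
    ml = _signal.filtfilt(b, a, trace.ml)
    return CoPTrace(t=trace.t, ap=ap, ml=ml, rate=trace.rate)


def kinematics(trace: CoPTrace) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-sample position, velocity (cm/s) and acceleration (cm/s^2).

    Central finite differences, one-sided at the ends.  Returns arrays of
    shape (n, 2) in (ml, ap) order.
    """
    if trace.n_samples < 5:
        raise InsufficientDataError("kinematics needs at least 5 samples")
    pos = np.stack([trace.ml, trace.ap], axis=1)
    vel = np.gradient(pos, trace.dt, axis=0)
    acc = np.gradient(vel, trace.dt, axis=0)
    return pos, vel, acc


def _grid_bisect_tau(
    p: np.ndarray, v: np.ndarray, a: np.ndarray, bos: BaseOfSupport, tau_max: float
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized smallest-crossing search for states (n, 2).

    Signs of the boundary function are evaluated on a dense tau grid; the
    first sign change per state is refined by bisection to ``_BISECT_TOL``.
    States whose projection never leaves the boundary get ``tau_max`` and a
    capped flag.
    """
    n = p.shape[0]
    taus = np.linspace(0.0, tau_max, _GRID_POINTS + 1)  # includes tau=0 (inside)
    # projected positions: (n, m, 2)
    proj = (
        p[:, None, :]
        + v[:, None, :] * taus[None, :, None]
        + 0.5 * a[:, None, :] * taus[None, :, None] ** 2
    )
    f = bos.signed_outside(proj[..., 0], proj[..., 1])  # (n, m)
    outside = f >= 0
    first = np.argmax(outside, axis=1)  # 0 if never outside
    capped = ~outside.any(axis=1)
    first = np.where(capped, 1, first)
    lo = taus[first - 1].copy()
    hi = taus[first].copy()
    # bisection on the bracketed sign change
    active = ~capped
    n_iter = int(np.ceil(np.log2(tau_max / _GRID_POINTS / _BISECT_TOL))) + 1
    for _ in range(max(n_iter, 1)):
        mid = 0.5 * (lo + hi)
        pm = p + v * mid[:, None] + 0.5 * a * mid[:, None] ** 2
        fm = bos.signed_outside(pm[:, 0], pm[:, 1])
        go_hi = (fm < 0) & active
        lo = np.where(go_hi, mid, lo)
        hi = np.where(active & ~go_hi, mid, hi)
    tau = np.where(capped, tau_max, 0.5 * (lo + hi))
    return tau, capped


def contact_time(
    state: tuple,
    bos: BaseOfSupport,
    tau_max: float = TAU_MAX_DEFAULT,
) -> tuple[float, bool]:
    """Smallest time for one ballistic CoP projection to reach the boundary.

    ``state`` is ``(p, v, a)`` with each a length-2 ``(ml, ap)`` sequence.
    Returns ``(tau, capped)``; ``tau == tau_max`` with ``capped=True`` when
    the quadratic path never exits within the horizon.  The position must be
    strictly inside the boundary.
    """
    p, v, a = (np.asarray(x, dtype=float).reshape(1, 2) for x in state)
    if bos.signed_outside(p[0, 0], p[0, 1]) >= 0:
        raise StateError("CoP position lies on or outside the base of support")
    if tau_max <= 0:
        raise InvalidParameterError("tau_max must be positive")
    tau, capped = _grid_bisect_tau(p, v, a, bos, tau_max)
    return float(tau[0]), bool(capped[0])


def vtc_series(
    trace: CoPTrace,
    bos: BaseOfSupport | None = None,
    tau_max: float = TAU_MAX_DEFAULT,
    cutoff: float | None = 10.0,
) -> VTCSeries:
    """Compute per-sample VTC for a balance trial.

    The trace is low-pass filtered (unless ``cutoff`` is None), differentiated,
    and each sample's state projected onto the boundary.  When ``bos`` is not
    supplied, the default feet-together ellipse is centered on the trial-mean
    CoP, per the convention that sway is measured about its own mean.
    """
    filtered = preprocess_cop(trace, cutoff) if cutoff is not None else trace
    pos, vel, acc = kinematics(filtered)
    if bos is None:
        bos = BaseOfSupport()
    bos = bos.recentered((float(filtered.ml.mean()), float(filtered.ap.mean())))
    if np.any(bos.signed_outside(pos[:, 0], pos[:, 1]) >= 0):
        raise StateError("CoP trace leaves the base of support; enlarge the boundary")
    tau, capped = _grid_bisect_tau(pos, vel, acc, bos, tau_max)
    return VTCSeries(t=filtered.t, tau=tau, capped=capped, tau_max=tau_max)


def mean_vtc(
    series: VTCSeries,
    cap_policy: Literal["include_capped", "exclude_capped"] = "include_capped",
) -> float:
    """Trial-average VTC under the stated capping policy.

    ``include_capped`` (default) averages capped samples at ``tau_max``;
    ``exclude_capped`` drops them, which errors when every sample is capped.
    """
    if series.tau.size == 0:
        raise InsufficientDataError("empty VTC series")
    if cap_policy == "include_capped":
        return float(series.tau.mean())
    if cap_policy == "exclude_capped":
        keep = ~series.capped
        if not keep.any():
            raise InsufficientDataError("all samples capped; mean undefined under exclude_capped")
        return float(series.tau[keep].mean())
    raise InvalidParameterError(f"unknown cap policy {cap_policy!r}")
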