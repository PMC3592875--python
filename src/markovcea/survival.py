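"""Parametric survival machinery for the progression-free state.

Weibull survival S(t) = exp(-(t/scale)^shape); shape 1 is the exponential
special case used by the default calibration, which anchors each arm's curve
to its own trial-reported median.  The module also converts curves into
per-cycle transition probabilities, fits Weibull parameters to Kaplan-Meier
data on the complementary log-log scale, and back-calibrates the constant
per-cycle post-progression death probability against a discounted
person-time target.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import bisect

from . import cohort
from .params import ModelStructure

__all__ = [
    "WeibullParams",
    "TransitionSchedule",
    "weibull_survival",
    "weibull_from_median",
    "apply_hazard_ratio",
    "fit_weibull_to_km",
    "cycle_transition_prob",
    "transition_probs",
    "schedule_from_weibull",
    "calibrate_dp_mortality",
    "CalibrationError",
]

LN2 = math.log(2.0)


class CalibrationError(RuntimeError):
    """Raised when a calibration target cannot be reached."""


@dataclass(frozen=True)
class WeibullParams:
    """Weibull survival curve: S(t) = exp(-(t/scale)^shape), t in months."""

    shape: float
    scale: float

    def __post_init__(self) -> None:
        if self.shape <= 0 or self.scale <= 0:
            raise ValueError("Weibull shape and scale must be > 0")

    def survival(self, t):
        return weibull_survival(self, t)

    def median(self) -> float:
        return self.scale * LN2 ** (1.0 / self.shape)

    def to_dict(self) -> dict:
        return {"shape": self.shape, "scale": self.scale}


@dataclass(frozen=True)
class TransitionSchedule:
    """Per-cycle transition probabilities for one arm.

    ``p_pfs_exit[k-1]`` is the probability of leaving PFS during cycle k;
    ``p_pfs_death`` the direct PFS->death component (defaults to all-zero:
    every exit is a progression); ``p_dp_death`` the constant per-cycle
    death probability once progressed.
    """

    p_pfs_exit: np.ndarray
    p_dp_death: float = 0.0
    p_pfs_death: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        exit_ = np.asarray(self.p_pfs_exit, dtype=float)
        object.__setattr__(self, "p_pfs_exit", exit_)
        if self.p_pfs_death is None:
            object.__setattr__(self, "p_pfs_death", np.zeros_like(exit_))
        else:
            pd_ = np.asarray(self.p_pfs_death, dtype=float)
            if pd_.shape != exit_.shape:
                raise ValueError("p_pfs_death must match p_pfs_exit in length")
            if np.any(pd_ > exit_ + 1e-12):
                raise ValueError("p_pfs_death cannot exceed p_pfs_exit")
            object.__setattr__(self, "p_pfs_death", pd_)

    def with_dp_death(self, p: float) -> "TransitionSchedule":
        return TransitionSchedule(
            p_pfs_exit=self.p_pfs_exit,
            p_dp_death=p,
            p_pfs_death=self.p_pfs_death,
        )


def weibull_survival(params: WeibullParams, t):
    """S(t) = exp(-(t/scale)^shape); vectorised over t (months)."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("survival time must be >= 0")
    out = np.exp(-((t_arr / params.scale) ** params.shape))
    return float(out) if np.isscalar(t) else out


def weibull_from_median(median: float, shape: float = 1.0) -> WeibullParams:
    """Weibull with the given shape whose survival median equals ``median``.

    scale = median / (ln 2)^(1/shape), so S(median) = 1/2 exactly.
    """
    if median <= 0 or shape <= 0:
        raise ValueError("median and shape must be > 0")
    return WeibullParams(shape=shape, scale=median / LN2 ** (1.0 / shape))


def apply_hazard_ratio(params: WeibullParams, hr: float) -> WeibullParams:
    """Multiply the cumulative hazard by ``hr`` (proportional hazards).

    Shape is preserved; scale' = scale * hr^(-1/shape).
    """
    if hr <= 0:
        raise ValueError("hazard ratio must be > 0")
    return WeibullParams(shape=params.shape, scale=params.scale * hr ** (-1.0 / params.shape))


def fit_weibull_to_km(km) -> WeibullParams:
    """Least-squares Weibull fit to a Kaplan-Meier curve.

    Regresses log(-log S) on log t over the points with 0 < S < 1 and t > 0
    (the complementary log-log linearisation); the slope is the shape and
    the intercept gives the scale.
    """
    t = np.asarray(km.times, dtype=float)
    s = np.asarray(km.survival, dtype=float)
    mask = (s > 0.0) & (s < 1.0) & (t > 0.0)
    if mask.sum() < 2:
        raise ValueError("need at least two Kaplan-Meier points with 0 < S < 1")
    x = np.log(t[mask])
    y = np.log(-np.log(s[mask]))
    slope, intercept = np.polyfit(x, y, 1)
    shape = float(slope)
    if shape <= 0:
        raise ValueError("fitted shape is non-positive; curve is not Weibull-like")
    scale = float(np.exp(-intercept / shape))
    return WeibullParams(shape=shape, scale=scale)


def cycle_transition_prob(params: WeibullParams, k: int, cycle_months: float) -> float:
    """Probability of the event during cycle k given event-free entry.

    1 - S(k u)/S((k-1) u) for cycle length u months; when the conditioning
    survival has underflowed to zero the tail is treated as absorbing and
    the probability is 1.
    """
    if k < 1:
        raise ValueError("cycle index must be >= 1")
    s_prev = weibull_survival(params, (k - 1) * cycle_months)
    if s_prev == 0.0:
        return 1.0
    return 1.0 - weibull_survival(params, k * cycle_months) / s_prev


def transition_probs(params: WeibullParams, n_cycles: int, cycle_months: float) -> np.ndarray:
    """Vector of per-cycle event probabilities for cycles 1..n_cycles."""
    t = np.arange(n_cycles + 1) * cycle_months
    s = weibull_survival(params, t)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(s[:-1] > 0.0, s[1:] / s[:-1], 0.0)
    return np.clip(1.0 - ratio, 0.0, 1.0)


def schedule_from_weibull(
    params: WeibullParams,
    structure: ModelStructure,
    p_dp_death: float = 0.0,
) -> TransitionSchedule:
    """Build an arm's transition schedule from its PFS survival curve."""
    return TransitionSchedule(
        p_pfs_exit=transition_probs(params, structure.n_cycles,
                                    structure.cycle_length_months),
        p_dp_death=p_dp_death,
    )


def _dp_person_time(p: float, pfs_schedule: TransitionSchedule,
                    structure: ModelStructure) -> float:
    trace = cohort.build_trace(pfs_schedule.with_dp_death(p), structure)
    return cohort.summarize_occupancy(trace, structure).ly_dp


def calibrate_dp_mortality(
    target_dp_ly: float,
    pfs_schedule: TransitionSchedule,
    structure: ModelStructure,
    xtol: float = 1e-12,
) -> float:
    """Constant per-cycle DP death probability hitting a person-time target.

    Finds p such that the discounted person-years spent in the progressed
    state equal ``target_dp_ly``.  Discounted DP person-time is strictly
    decreasing in p, so bisection on [0, 1] converges; the returned p
    reproduces the target to well under 1e-6 years.

    Raises :class:`CalibrationError` when the target exceeds the maximum
    achievable person-time (at p = 0), reporting that maximum.
    """
    if target_dp_ly <= 0:
        raise ValueError("target person-time must be > 0")
    at_zero = _dp_person_time(0.0, pfs_schedule, structure)
    if target_dp_ly > at_zero:
        raise CalibrationError(
            f"target {target_dp_ly} years unreachable: maximum achievable "
            f"discounted DP person-time is {at_zero:.6f} years (at p=0)")
    at_one = _dp_person_time(1.0, pfs_schedule, structure)
    if target_dp_ly < at_one:
        raise CalibrationError(
            f"target {target_dp_ly} years unreachable: minimum achievable "
            f"discounted DP person-time is {at_one:.6f} years (at p=1)")

    def f(p: float) -> float:
        return _dp_person_time(p, pfs_schedule, structure) - target_dp_ly

    return float(bisect(f, 0.0, 1.0, xtol=xtol))
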