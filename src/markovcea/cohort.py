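"""Three-state cohort trace: progression-free (PFS), progressed (DP), dead.

The whole cohort starts in PFS.  Each 3-week cycle a fraction of the PFS
occupants exits (progression, or death if a direct PFS->death probability is
configured); progressors join the DP at-risk pool at the start of the next
cycle and face a constant per-cycle death probability from then on.  Death
is absorbing.  Person-time and costs count end-of-cycle state membership
(cycles k >= 1) with no half-cycle correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import ModelStructure, DAYS_PER_MONTH

__all__ = [
    "CohortTrace",
    "OccupancySummary",
    "build_trace",
    "discount_factor",
    "summarize_occupancy",
]


@dataclass(frozen=True)
class CohortTrace:
    """Per-cycle occupancy fractions and discount factors, cycles 0..n."""

    pfs: np.ndarray
    dp: np.ndarray
    death: np.ndarray
    t_years: np.ndarray
    discount: np.ndarray

    def __post_init__(self) -> None:
        total = self.pfs + self.dp + self.death
        if not np.allclose(total, 1.0, atol=1e-9):
            raise ValueError("state occupancies must sum to 1 every cycle")
        if np.any(np.diff(self.death) < -1e-12):
            raise ValueError("death occupancy must be non-decreasing")

    @property
    def n_cycles(self) -> int:
        return len(self.pfs) - 1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cycle": np.arange(len(self.pfs)),
                "t_years": self.t_years,
                "pfs": self.pfs,
                "dp": self.dp,
                "death": self.death,
                "discount_factor": self.discount,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class OccupancySummary:
    """Discounted person-years by state and the trace's median PFS.

    ``median_pfs_months`` is NaN when PFS occupancy never crosses 0.5 within
    the horizon (median not reached).
    """

    ly_pfs: float
    ly_dp: float
    median_pfs_months: float

    @property
    def ly_total(self) -> float:
        return self.ly_pfs + self.ly_dp

    @property
    def median_reached(self) -> bool:
        return not math.isnan(self.median_pfs_months)


def discount_factor(k: int | np.ndarray, structure: ModelStructure) -> float | np.ndarray:
    """Discount factor (1+r)^(-t_k) at the start of cycle k."""
    t_years = np.asarray(k) * structure.cycle_length_years
    out = (1.0 + structure.discount_rate_annual) ** (-t_years)
    return float(out) if np.isscalar(k) else out


def build_trace(schedule, structure: ModelStructure) -> CohortTrace:
    """Run the cohort forward for ``structure.n_cycles`` cycles.

    ``schedule`` is a :class:`~markovcea.survival.TransitionSchedule`:
    per-cycle PFS exit probabilities (index k-1 for cycle k), optional direct
    PFS->death probabilities, and the constant per-cycle DP->death
    probability.  New progressors are exposed to DP mortality only from the
    cycle after they arrive.
    """
    n = structure.n_cycles
    p_exit = np.asarray(schedule.p_pfs_exit, dtype=float)
    p_pfs_death = np.asarray(schedule.p_pfs_death, dtype=float)
    if len(p_exit) < n or len(p_pfs_death) < n:
        raise ValueError(f"schedule must cover {n} cycles")
    if np.any((p_exit < 0) | (p_exit > 1)) or np.any((p_pfs_death < 0) | (p_pfs_death > 1)):
        raise ValueError("transition probabilities must lie in [0, 1]")
    if np.any(p_pfs_death > p_exit + 1e-12):
        raise ValueError("p_pfs_death cannot exceed p_pfs_exit")
    q = schedule.p_dp_death
    if not 0.0 <= q <= 1.0:
        raise ValueError("p_dp_death must lie in [0, 1]")

    pfs = np.empty(n + 1)
    dp = np.empty(n + 1)
    pfs[0], dp[0] = 1.0, 0.0
    for k in range(1, n + 1):
        inflow = pfs[k - 1] * (p_exit[k - 1] - p_pfs_death[k - 1])
        pfs[k] = pfs[k - 1] * (1.0 - p_exit[k - 1])
        dp[k] = dp[k - 1] * (1.0 - q) + inflow
    # cancellation can leave death a few ulp below zero; clamp, the 1e-9
    # conservation invariant is unaffected
    death = np.maximum(1.0 - pfs - dp, 0.0)

    cycles = np.arange(n + 1)
    t_years = cycles * structure.cycle_length_years
    disc = discount_factor(cycles, structure)
    return CohortTrace(pfs=pfs, dp=dp, death=death, t_years=t_years, discount=disc)


def _median_from_occupancy(pfs: np.ndarray, structure: ModelStructure) -> float:
    """Interpolated time (months) at which PFS occupancy crosses 0.5."""
    below = np.nonzero(pfs < 0.5)[0]
    if len(below) == 0:
        return math.nan
    k = int(below[0])  # first cycle strictly below one half
    prev, cur = pfs[k - 1], pfs[k]
    frac = (prev - 0.5) / (prev - cur)
    k_star = (k - 1) + frac
    return k_star * structure.cycle_length_days / DAYS_PER_MONTH


def summarize_occupancy(trace: CohortTrace, structure: ModelStructure) -> OccupancySummary:
    """Discounted person-years per state and the interpolated PFS median.

    Person-time sums end-of-cycle membership: each of cycles 1..n
    contributes occupancy x discount x cycle length.
    """
    cyl = structure.cycle_length_years
    ly_pfs = float(np.sum(trace.pfs[1:] * trace.discount[1:]) * cyl)
    ly_dp = float(np.sum(trace.dp[1:] * trace.discount[1:]) * cyl)
    return OccupancySummary(
        ly_pfs=ly_pfs,
        ly_dp=ly_dp,
        median_pfs_months=_median_from_occupancy(trace.pfs, structure),
    )
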