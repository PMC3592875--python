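"""Per-strategy economic outcomes and incremental cost-effectiveness.

QALYs weight discounted state person-time by the state utilities; costs are
occupancy-and-discount-weighted sums of the cycle-indexed schedules plus
the one-off adverse-event charge.  Incremental results follow the
CG-minus-erlotinib orientation (the comparator gains QALYs at added cost in
the base case); :func:`icer` takes its two arguments in caller order, so
either orientation is available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .cohort import CohortTrace, OccupancySummary, summarize_occupancy
from .costs import CostSchedule
from .params import ModelStructure, UtilitySet

__all__ = [
    "EconResult",
    "IncrementalResult",
    "evaluate_strategy",
    "econ_from_occupancy",
    "icer",
    "net_monetary_benefit",
]


@dataclass(frozen=True)
class EconResult:
    """Discounted life-years, QALYs and costs for one strategy."""

    strategy: str
    ly_pfs: float
    ly_dp: float
    qaly_pfs: float
    qaly_dp: float
    cost_pfs: float
    cost_dp: float
    cost_mae: float
    median_pfs_months: float = math.nan

    @property
    def ly_total(self) -> float:
        return self.ly_pfs + self.ly_dp

    @property
    def qaly_total(self) -> float:
        return self.qaly_pfs + self.qaly_dp

    @property
    def cost_total(self) -> float:
        return self.cost_pfs + self.cost_dp + self.cost_mae

    def to_dict(self) -> dict:
        return {
            "strategy": self.strategy,
            "ly_pfs": self.ly_pfs,
            "ly_dp": self.ly_dp,
            "ly_total": self.ly_total,
            "qaly_pfs": self.qaly_pfs,
            "qaly_dp": self.qaly_dp,
            "qaly_total": self.qaly_total,
            "cost_pfs": self.cost_pfs,
            "cost_dp": self.cost_dp,
            "cost_mae": self.cost_mae,
            "cost_total": self.cost_total,
            "median_pfs_months": self.median_pfs_months,
        }


@dataclass(frozen=True)
class IncrementalResult:
    """Differences b minus a, with ICERs or a dominance verdict.

    ``dominance`` is "b" when b is cheaper and more effective, "a" when a
    is, and "none" when the deltas share a sign and a ratio is meaningful.
    A zero QALY difference with a non-zero cost difference yields a signed
    infinite ICER sentinel rather than a division error.
    """

    delta_cost: float
    delta_qaly: float
    delta_ly: float
    icer_per_qaly: float
    icer_per_ly: float
    dominance: str

    def to_dict(self) -> dict:
        return {
            "delta_cost": self.delta_cost,
            "delta_qaly": self.delta_qaly,
            "delta_ly": self.delta_ly,
            "icer_per_qaly": self.icer_per_qaly,
            "icer_per_ly": self.icer_per_ly,
            "dominance": self.dominance,
        }


def evaluate_strategy(
    trace: CohortTrace,
    utilities: UtilitySet,
    schedule: CostSchedule,
    structure: ModelStructure,
) -> EconResult:
    """Fold a cohort trace with utilities and a cost schedule."""
    occ = summarize_occupancy(trace, structure)
    cost_pfs = float(np.sum(trace.pfs[1:] * trace.discount[1:] * schedule.pfs_cost))
    cost_dp = float(np.sum(trace.dp[1:] * trace.discount[1:]) * schedule.dp_cost)
    return _assemble(schedule.strategy, occ, utilities, cost_pfs, cost_dp,
                     schedule.one_off_cost)


def econ_from_occupancy(
    strategy: str,
    ly_pfs: float,
    ly_dp: float,
    utilities: UtilitySet,
    cost_pfs: float = 0.0,
    cost_dp: float = 0.0,
    cost_mae: float = 0.0,
) -> EconResult:
    """Recompose an EconResult from already-summed discounted person-years.

    Used to re-derive the published worked examples from their printed state
    occupancies, and for utility-only reanalyses where occupancy is fixed.
    """
    occ = OccupancySummary(ly_pfs=ly_pfs, ly_dp=ly_dp, median_pfs_months=math.nan)
    return _assemble(strategy, occ, utilities, cost_pfs, cost_dp, cost_mae)


def _assemble(strategy, occ, utilities, cost_pfs, cost_dp, cost_mae) -> EconResult:
    u_pfs = utilities.u_pfs(strategy)
    return EconResult(
        strategy=strategy,
        ly_pfs=occ.ly_pfs,
        ly_dp=occ.ly_dp,
        qaly_pfs=occ.ly_pfs * u_pfs,
        qaly_dp=occ.ly_dp * utilities.u_dp,
        cost_pfs=cost_pfs,
        cost_dp=cost_dp,
        cost_mae=cost_mae,
        median_pfs_months=occ.median_pfs_months,
    )


def _safe_ratio(dc: float, de: float) -> float:
    if de == 0.0:
        if dc == 0.0:
            return math.nan
        return math.copysign(math.inf, dc)
    return dc / de


def icer(a: EconResult, b: EconResult) -> IncrementalResult:
    """Incremental result of b versus a (deltas are b - a)."""
    dc = b.cost_total - a.cost_total
    dq = b.qaly_total - a.qaly_total
    dl = b.ly_total - a.ly_total
    if dc > 0 and dq < 0:
        dominance = "a"
    elif dc < 0 and dq > 0:
        dominance = "b"
    else:
        dominance = "none"
    if dominance == "none":
        per_qaly = _safe_ratio(dc, dq)
        per_ly = _safe_ratio(dc, dl)
    else:
        per_qaly = math.nan
        per_ly = math.nan
    return IncrementalResult(
        delta_cost=dc,
        delta_qaly=dq,
        delta_ly=dl,
        icer_per_qaly=per_qaly,
        icer_per_ly=per_ly,
        dominance=dominance,
    )


def net_monetary_benefit(result: EconResult, wtp: float) -> float:
    """NMB = WTP x total QALYs - total cost (USD)."""
    if wtp < 0:
        raise ValueError("willingness-to-pay must be >= 0")
    return wtp * result.qaly_total - result.cost_total
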