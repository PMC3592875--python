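"""Cycle-indexed cost schedules for the two strategies (2010 USD).

Chemotherapy (CG) pays the trial-treatment aggregate for cycles 1-4 and the
best-supportive-care aggregate from cycle 5 while still progression-free.
Erlotinib pays its per-cycle drug aggregate for cycles 1-7; from cycle 8 the
drug is donated and only the blood-test charge remains.  Adverse-event
management is a single expected one-off charge at model entry (rate x unit
cost summed over events) -- it is reported as one lifetime number, not a
per-cycle hazard.  Progressed disease pays a flat per-cycle cost in both
arms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import (
    DAYS_PER_MONTH,
    AdverseEventProfile,
    CostParams,
    ModelStructure,
    ParameterBundle,
)

__all__ = [
    "CostSchedule",
    "erlotinib_pfs_cost",
    "cg_pfs_cost",
    "mae_one_off_cost",
    "erlotinib_cycle_price_from_units",
    "unit_price_cross_check",
    "build_cost_schedule",
    "chemotherapy_dose_audit",
]

ERL_DONATION_START_CYCLE = 8  # drug free from this cycle (after 7 paid cycles)
CG_BSC_START_CYCLE = 5        # best supportive care from this cycle


@dataclass(frozen=True)
class CostSchedule:
    """Per-cycle costs while in each state, plus the one-off entry charge."""

    strategy: str
    pfs_cost: np.ndarray   # index k-1 for cycle k
    dp_cost: float         # flat per-cycle cost while progressed
    one_off_cost: float    # expected adverse-event management charge

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.pfs_cost) < 0) or self.dp_cost < 0 or self.one_off_cost < 0:
            raise ValueError("costs must be >= 0")

    def to_frame(self) -> pd.DataFrame:
        k = np.arange(1, len(self.pfs_cost) + 1)
        return pd.DataFrame(
            {
                "cycle": k,
                "strategy": self.strategy,
                "pfs_cost": self.pfs_cost,
                "dp_cost": self.dp_cost,
            }
        )


def erlotinib_pfs_cost(k: int, params: CostParams, include_blood_tests: bool = True) -> float:
    """Erlotinib-arm PFS cost at cycle k: drug through cycle 7, then donated."""
    if k < 1:
        raise ValueError("cycle index must be >= 1")
    drug = (params.erl_tt_per_cycle if k < ERL_DONATION_START_CYCLE
            else params.erl_after_donation_per_cycle)
    tests = params.blood_test_erl_per_cycle if include_blood_tests else 0.0
    return drug + tests


def cg_pfs_cost(
    k: int,
    params: CostParams,
    include_blood_tests: bool = True,
    blood_tests_stop_at_bsc: bool = True,
) -> float:
    """CG-arm PFS cost at cycle k: chemotherapy cycles 1-4, then BSC.

    Blood tests are charged during active chemotherapy; by default BSC is
    treated as all-inclusive so they stop at the switch (configurable).
    """
    if k < 1:
        raise ValueError("cycle index must be >= 1")
    if k < CG_BSC_START_CYCLE:
        tests = params.blood_test_cg_per_cycle if include_blood_tests else 0.0
        return params.cg_tt_per_cycle + tests
    tests = (params.blood_test_cg_per_cycle
             if include_blood_tests and not blood_tests_stop_at_bsc else 0.0)
    return params.cg_bsc_per_cycle + tests


def mae_one_off_cost(profile: AdverseEventProfile) -> float:
    """Expected adverse-event management cost: sum of rate x unit cost."""
    return float(sum(e.rate * e.unit_cost for e in profile.events))


def erlotinib_cycle_price_from_units(params: CostParams) -> float:
    """Bottom-up erlotinib cycle price: three 7-day packs, no wastage."""
    return 3.0 * params.erl_unit_price_per_week


def unit_price_cross_check(params: CostParams, tolerance: float = 1.0) -> dict:
    """Compare the bottom-up erlotinib cycle price with the configured one.

    Returns the two prices, their difference, and a flag raised when they
    disagree by more than ``tolerance`` USD.
    """
    computed = erlotinib_cycle_price_from_units(params)
    configured = params.erl_tt_per_cycle
    return {
        "computed": computed,
        "configured": configured,
        "difference": computed - configured,
        "flag": abs(computed - configured) > tolerance,
    }


def _dp_cost_per_cycle(bundle: ParameterBundle) -> float:
    # "month" basis prorates the monthly figure over the 21-day cycle
    if bundle.dp_cost_basis == "month":
        return bundle.costs.dp_cost_per_cycle * (
            bundle.structure.cycle_length_days / DAYS_PER_MONTH)
    return bundle.costs.dp_cost_per_cycle


def build_cost_schedule(strategy: str, bundle: ParameterBundle,
                        structure: ModelStructure | None = None) -> CostSchedule:
    """Assemble the full cycle-indexed schedule for one strategy."""
    structure = structure or bundle.structure
    n = structure.n_cycles
    k = np.arange(1, n + 1)
    if strategy == "erlotinib":
        pfs = np.where(
            k < ERL_DONATION_START_CYCLE,
            bundle.costs.erl_tt_per_cycle,
            bundle.costs.erl_after_donation_per_cycle,
        ).astype(float)
        if bundle.include_blood_tests:
            pfs += bundle.costs.blood_test_erl_per_cycle
        one_off = mae_one_off_cost(bundle.erl_adverse_events)
    elif strategy == "cg":
        pfs = np.where(
            k < CG_BSC_START_CYCLE,
            bundle.costs.cg_tt_per_cycle,
            bundle.costs.cg_bsc_per_cycle,
        ).astype(float)
        if bundle.include_blood_tests:
            tests = np.where(
                k < CG_BSC_START_CYCLE,
                bundle.costs.blood_test_cg_per_cycle,
                0.0 if bundle.blood_tests_stop_at_bsc
                else bundle.costs.blood_test_cg_per_cycle,
            )
            pfs += tests
        one_off = mae_one_off_cost(bundle.cg_adverse_events)
    else:
        raise ValueError(f"unknown strategy {strategy!r}")
    return CostSchedule(
        strategy=strategy,
        pfs_cost=pfs,
        dp_cost=_dp_cost_per_cycle(bundle),
        one_off_cost=one_off,
    )


def chemotherapy_dose_audit(
    bsa_m2: float = 1.72,
    gemcitabine_dose_mg_per_m2: float = 1000.0,
    gemcitabine_vial_mg: float = 200.0,
    gemcitabine_vial_price: float = 79.06,
    carboplatin_dose_mg: float | None = None,
    carboplatin_vial_mg: float = 100.0,
    carboplatin_vial_price: float = 11.71,
) -> dict:
    """Bottom-up per-cycle chemotherapy drug cost, for auditing only.

    Gemcitabine is dosed per body surface area on days 1 and 8 (two doses
    per cycle, no wastage).  Carboplatin is dosed by AUC via the Calvert
    formula, which needs a renal clearance that is not an input here, so its
    dose must be supplied explicitly; when omitted only the gemcitabine
    component is reported.  The binding model input remains the published
    per-cycle aggregate.
    """
    gem_mg_per_cycle = 2.0 * gemcitabine_dose_mg_per_m2 * bsa_m2
    gem_cost = gem_mg_per_cycle / gemcitabine_vial_mg * gemcitabine_vial_price
    out = {
        "gemcitabine_mg_per_cycle": gem_mg_per_cycle,
        "gemcitabine_cost_per_cycle": gem_cost,
    }
    if carboplatin_dose_mg is not None:
        carb_cost = carboplatin_dose_mg / carboplatin_vial_mg * carboplatin_vial_price
        out["carboplatin_cost_per_cycle"] = carb_cost
        out["drug_cost_per_cycle"] = gem_cost + carb_cost
    return out
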