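"""Model/Results surface tying calibration, cohort trace and economics together.

Usage mirrors the fit-then-inspect pattern of statistical modelling
packages::

    model = CostEffectivenessModel()            # published base case
    res = model.fit()
    print(res.summary())
    psa = res.run_psa(n_iter=1000, seed=2013)

``fit`` calibrates one parametric PFS curve per arm to its trial median,
back-solves each arm's post-progression death probability against the
published discounted person-time in progressed disease, runs the cohort
trace, and folds in costs and utilities.  The returned results object
carries every intermediate (curves, calibrated probabilities, traces,
per-strategy outcomes, incremental ratios) and is the entry point for
sensitivity analyses and plots.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import cohort, costs, economics, survival
from .params import ParameterBundle, default_bundle, default_parameter_specs, load_config

__all__ = ["CostEffectivenessModel", "CostEffectivenessResults"]

STRATEGIES = ("erlotinib", "cg")


class CostEffectivenessModel:
    """Three-state cohort cost-effectiveness model of two first-line strategies.

    Parameters
    ----------
    bundle:
        Validated input set; defaults to the published base case.
    """

    def __init__(self, bundle: ParameterBundle | None = None):
        self.bundle = bundle or default_bundle()

    @classmethod
    def from_config(cls, path) -> "CostEffectivenessModel":
        """Build a model from a flat YAML configuration file."""
        return cls(load_config(path))

    def calibrate(self, use_hazard_ratio: bool = False) -> dict:
        """Calibrate survival curves and post-progression mortality.

        Each arm's PFS curve is a Weibull (default shape 1, i.e.
        exponential) anchored to that arm's trial median.  With
        ``use_hazard_ratio`` the erlotinib curve is instead derived from the
        CG curve via the trial hazard ratio (scenario analysis; the trial HR
        of 0.16 is steeper than the ratio of median-implied hazards, so this
        is not the default).  The constant per-cycle DP death probability of
        each arm is then bisected to reproduce the published discounted
        person-years in progressed disease.
        """
        sv = self.bundle.survival
        structure = self.bundle.structure
        shape = sv.weibull_shape_default
        weibull_cg = survival.weibull_from_median(sv.median_pfs_cg, shape)
        if use_hazard_ratio:
            weibull_erl = survival.apply_hazard_ratio(weibull_cg, sv.hazard_ratio_erl_vs_cg)
        else:
            weibull_erl = survival.weibull_from_median(sv.median_pfs_erl, shape)
        curves = {"erlotinib": weibull_erl, "cg": weibull_cg}
        targets = {"erlotinib": sv.target_dp_ly_erl, "cg": sv.target_dp_ly_cg}
        schedules, p_dp = {}, {}
        for arm in STRATEGIES:
            base = survival.schedule_from_weibull(curves[arm], structure)
            p = survival.calibrate_dp_mortality(targets[arm], base, structure)
            p_dp[arm] = p
            schedules[arm] = base.with_dp_death(p)
        return {"curves": curves, "p_dp_death": p_dp, "schedules": schedules}

    def fit(self, use_hazard_ratio: bool = False) -> "CostEffectivenessResults":
        """Calibrate, run the cohort trace, and evaluate both strategies."""
        cal = self.calibrate(use_hazard_ratio=use_hazard_ratio)
        structure = self.bundle.structure
        traces = {
            arm: cohort.build_trace(cal["schedules"][arm], structure)
            for arm in STRATEGIES
        }
        econ = _evaluate(self.bundle, traces)
        return CostEffectivenessResults(
            model=self,
            bundle=self.bundle,
            weibull=cal["curves"],
            p_dp_death=cal["p_dp_death"],
            schedules=cal["schedules"],
            traces=traces,
            econ=econ,
        )


def _evaluate(bundle: ParameterBundle, traces: dict) -> dict:
    out = {}
    for arm in STRATEGIES:
        sched = costs.build_cost_schedule(arm, bundle)
        out[arm] = economics.evaluate_strategy(
            traces[arm], bundle.utilities, sched, bundle.structure)
    return out


@dataclass
class CostEffectivenessResults:
    """Fitted base case: calibrated inputs, traces, outcomes, incrementals."""

    model: CostEffectivenessModel
    bundle: ParameterBundle
    weibull: dict
    p_dp_death: dict
    schedules: dict
    traces: dict
    econ: dict
    _cache: dict = field(default_factory=dict, repr=False)

    # -- headline quantities ----------------------------------------------

    @property
    def econ_erlotinib(self) -> economics.EconResult:
        return self.econ["erlotinib"]

    @property
    def econ_cg(self) -> economics.EconResult:
        return self.econ["cg"]

    @property
    def incremental(self) -> economics.IncrementalResult:
        """CG minus erlotinib (the reporting orientation)."""
        return economics.icer(self.econ_erlotinib, self.econ_cg)

    @property
    def incremental_reverse(self) -> economics.IncrementalResult:
        """Erlotinib minus CG, for sign-convention cross-checks."""
        return economics.icer(self.econ_cg, self.econ_erlotinib)

    @property
    def median_pfs_months(self) -> dict:
        return {arm: self.econ[arm].median_pfs_months for arm in STRATEGIES}

    def net_monetary_benefit(self, wtp: float | None = None) -> dict:
        wtp = self.bundle.wtp.wtp_threshold if wtp is None else wtp
        return {
            arm: economics.net_monetary_benefit(self.econ[arm], wtp)
            for arm in STRATEGIES
        }

    # -- re-evaluation under modified inputs -------------------------------

    def reevaluate(self, bundle: ParameterBundle,
                   recalibrate: bool = False) -> dict:
        """Re-run the economic pipeline under a modified bundle.

        Cost, utility and adverse-event changes leave state occupancy
        untouched, so the fitted transition schedules are reused and only
        discounting and the cost/QALY folds are recomputed.  Survival or
        structural changes need ``recalibrate=True``, which redoes the full
        calibration under the new bundle.

        Returns ``{"erlotinib": EconResult, "cg": EconResult,
        "incremental": IncrementalResult}`` (CG minus erlotinib).
        """
        if recalibrate:
            res = CostEffectivenessModel(bundle).fit()
            econ = res.econ
        else:
            structure = bundle.structure
            if (structure.discount_rate_annual
                    != self.bundle.structure.discount_rate_annual):
                traces = {
                    arm: cohort.build_trace(self.schedules[arm], structure)
                    for arm in STRATEGIES
                }
            else:
                traces = self.traces
            econ = _evaluate(bundle, traces)
        return {
            "erlotinib": econ["erlotinib"],
            "cg": econ["cg"],
            "incremental": economics.icer(econ["erlotinib"], econ["cg"]),
        }

    # -- sensitivity analyses ---------------------------------------------

    def tornado(self, specs=None) -> pd.DataFrame:
        from . import sensitivity

        return sensitivity.tornado(self, specs or default_parameter_specs())

    def run_psa(self, n_iter: int = 1000, seed: int = 0, specs=None):
        from . import sensitivity

        return sensitivity.run_psa(
            self, n_iter=n_iter, seed=seed,
            specs=specs or default_parameter_specs())

    # -- reporting ---------------------------------------------------------

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for arm in STRATEGIES:
            rows.append(self.econ[arm].to_dict())
        df = pd.DataFrame(rows).set_index("strategy")
        return df

    def summary(self) -> str:
        """Human-readable base-case report (costs in 2010 USD)."""
        inc = self.incremental
        lines = [
            "Markov cohort cost-effectiveness results (discounted, 2010 USD)",
            "=" * 64,
        ]
        df = self.summary_frame()
        display = df.rename(
            columns={
                "ly_total": "LY",
                "qaly_total": "QALY",
                "cost_total": "Cost",
                "median_pfs_months": "median PFS (mo)",
            }
        )[["LY", "QALY", "Cost", "median PFS (mo)"]]
        lines.append(display.round(2).to_string())
        lines.append("-" * 64)
        lines.append(
            f"Calibrated per-cycle DP death probability: "
            f"erlotinib {self.p_dp_death['erlotinib']:.5f}, "
            f"cg {self.p_dp_death['cg']:.5f}"
        )
        lines.append(
            "Incremental (CG minus erlotinib): "
            f"dCost {inc.delta_cost:.2f}, dQALY {inc.delta_qaly:.2f}, "
            f"dLY {inc.delta_ly:.2f}"
        )
        if inc.dominance == "none":
            lines.append(
                f"ICER: {inc.icer_per_qaly:.2f} USD/QALY, "
                f"{inc.icer_per_ly:.2f} USD/LY"
            )
        else:
            winner = "CG" if inc.dominance == "b" else "erlotinib"
            lines.append(f"Dominance: {winner} dominates")
        wtp = self.bundle.wtp.wtp_threshold
        nmb = self.net_monetary_benefit(wtp)
        preferred = max(nmb, key=nmb.get)
        lines.append(
            f"At WTP {wtp:.0f} USD/QALY the preferred strategy is {preferred} "
            f"(NMB erlotinib {nmb['erlotinib']:.2f}, cg {nmb['cg']:.2f})"
        )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "weibull": {a: self.weibull[a].to_dict() for a in STRATEGIES},
            "p_dp_death": dict(self.p_dp_death),
            "median_pfs_months": self.median_pfs_months,
            "strategies": {a: self.econ[a].to_dict() for a in STRATEGIES},
            "incremental_cg_minus_erlotinib": self.incremental.to_dict(),
            "incremental_erlotinib_minus_cg": self.incremental_reverse.to_dict(),
        }

    def to_json(self, path=None) -> str:
        def _default(o):
            if isinstance(o, float) and math.isnan(o):
                return None
            raise TypeError(type(o))

        text = json.dumps(self.to_dict(), indent=2, default=_default)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    # -- plots --------------------------------------------------------------

    def plot_survival(self, ax=None):
        from . import plots

        return plots.plot_survival(self, ax=ax)
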