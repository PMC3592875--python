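"""Deterministic (tornado) and probabilistic sensitivity analysis.

One-way analysis re-runs the pipeline at each parameter's published low and
high with everything else at base and records both ICERs.  Probabilistic
analysis draws every non-constant parameter from a distribution moment-
matched to its one-way range (the range is read as a 95% interval, so
sd = range/3.92), re-runs the pipeline per iteration, and summarises the
CG-minus-erlotinib incremental pairs as a cost-effectiveness plane and
acceptability curves.  Parameters are sampled independently; survival and
post-progression mortality are structural (calibrated once, not sampled)
unless extra specs are supplied explicitly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .economics import IncrementalResult
from .params import ParameterSpec, WtpConfig, default_parameter_specs, reference_base_case
from .economics import econ_from_occupancy, icer as _icer

__all__ = [
    "TornadoEntry",
    "one_way",
    "tornado",
    "fit_distribution",
    "run_psa",
    "PSAResults",
    "ceac",
    "quadrant_proportions",
    "reference_icer",
]

_Z95_WIDTH = 2.0 * 1.96  # range read as a 95% interval


@dataclass(frozen=True)
class TornadoEntry:
    """ICERs at a parameter's low and high, and the resulting spread."""

    name: str
    role: str
    base: float
    low: float
    high: float
    icer_at_low: float
    icer_at_high: float
    unstable: bool

    @property
    def spread(self) -> float:
        if self.unstable:
            return math.inf
        return abs(self.icer_at_high - self.icer_at_low)


def _icer_under(results, role: str, value: float) -> tuple[float, bool]:
    """(ICER per QALY, unstable flag) with one input overridden."""
    bundle = results.bundle.with_value(role, value)
    out = results.reevaluate(bundle)
    inc: IncrementalResult = out["incremental"]
    if inc.dominance != "none" or not math.isfinite(inc.icer_per_qaly):
        # incremental QALYs crossed zero: ratio meaningless, report a
        # signed sentinel and flag the entry
        sentinel = math.copysign(math.inf, inc.delta_cost)
        return sentinel, True
    return inc.icer_per_qaly, False


def one_way(spec: ParameterSpec, results) -> TornadoEntry:
    """Re-run the deterministic pipeline at the spec's low and high."""
    icer_low, bad_low = _icer_under(results, spec.role, spec.low)
    icer_high, bad_high = _icer_under(results, spec.role, spec.high)
    return TornadoEntry(
        name=spec.name,
        role=spec.role,
        base=spec.base,
        low=spec.low,
        high=spec.high,
        icer_at_low=icer_low,
        icer_at_high=icer_high,
        unstable=bad_low or bad_high,
    )


def tornado(results, specs=None) -> pd.DataFrame:
    """One-way entries for every spec, sorted widest spread first."""
    specs = specs or default_parameter_specs()
    entries = [one_way(s, results) for s in specs]
    df = pd.DataFrame(
        {
            "parameter": [e.name for e in entries],
            "role": [e.role for e in entries],
            "low": [e.low for e in entries],
            "high": [e.high for e in entries],
            "icer_low": [e.icer_at_low for e in entries],
            "icer_high": [e.icer_at_high for e in entries],
            "spread": [e.spread for e in entries],
            "unstable": [e.unstable for e in entries],
        }
    )
    df = df.sort_values("spread", ascending=False, kind="mergesort")
    df["rank"] = np.arange(1, len(df) + 1)
    return df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# distributions

class _PointMass:
    """Degenerate distribution for constant-family parameters."""

    def __init__(self, value: float):
        self.value = value

    def rvs(self, size=None, random_state=None):
        if size is None:
            return self.value
        return np.full(size, self.value)

    def mean(self) -> float:
        return self.value


def fit_distribution(spec: ParameterSpec):
    """Moment-matched sampling distribution for one parameter.

    Mean equals the base value; the sd comes from reading [low, high] as a
    95% interval, sd = (high - low)/3.92.  Gamma and beta are matched by
    their standard mean/variance identities; the lognormal is matched so the
    distribution itself (not the underlying normal) has the target mean and
    sd.  The constant family returns a point mass.
    """
    if spec.family == "constant":
        return _PointMass(spec.base)
    mean = spec.base
    sd = (spec.high - spec.low) / _Z95_WIDTH
    if sd <= 0:
        raise ValueError(f"{spec.name}: degenerate range gives sd <= 0")
    if spec.family == "gamma":
        shape = (mean / sd) ** 2
        scale = sd**2 / mean
        return stats.gamma(a=shape, scale=scale)
    if spec.family == "lognormal":
        sigma2 = math.log(1.0 + (sd / mean) ** 2)
        mu = math.log(mean) - sigma2 / 2.0
        return stats.lognorm(s=math.sqrt(sigma2), scale=math.exp(mu))
    if spec.family == "beta":
        nu = mean * (1.0 - mean) / sd**2 - 1.0
        if nu <= 0:
            raise ValueError(
                f"{spec.name}: range too wide for a beta with mean {mean}")
        return stats.beta(a=mean * nu, b=(1.0 - mean) * nu)
    raise ValueError(f"{spec.name}: unknown family {spec.family!r}")


_UNIT_INTERVAL_ROLES = {
    "rate_neutropenia", "rate_thrombocytopenia", "rate_anaemia",
    "u_pfs_erlotinib", "u_pfs_cg", "u_dp",
}


def _domain_ok(role: str, values: np.ndarray) -> np.ndarray:
    if role in _UNIT_INTERVAL_ROLES:
        return (values >= 0.0) & (values <= 1.0)
    return values >= 0.0


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis

def run_psa(results, n_iter: int = 1000, seed: int = 0, specs=None,
            recalibrate: bool = False) -> "PSAResults":
    """Monte-Carlo uncertainty propagation through the fitted model.

    Draws every non-constant spec independently per iteration, re-runs the
    economic pipeline, and records the CG-minus-erlotinib incremental pair
    with its cost-effectiveness-plane quadrant.  Fully reproducible for a
    given seed.  ``recalibrate`` forces a full survival recalibration per
    iteration (needed only when user-supplied specs touch survival inputs).
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    specs = tuple(specs if specs is not None else default_parameter_specs())
    sampled = [s for s in specs if s.family != "constant"]
    rng = np.random.default_rng(seed)

    draws: dict[str, np.ndarray] = {}
    n_resampled = 0
    for s in sampled:
        dist = fit_distribution(s)
        vals = np.asarray(dist.rvs(size=n_iter, random_state=rng), dtype=float)
        bad = ~_domain_ok(s.role, vals)
        while bad.any():  # resample out-of-domain draws, keep count
            n_resampled += int(bad.sum())
            vals[bad] = dist.rvs(size=int(bad.sum()), random_state=rng)
            bad = ~_domain_ok(s.role, vals)
        draws[s.role] = vals

    rows = []
    for i in range(n_iter):
        overrides = {role: float(v[i]) for role, v in draws.items()}
        bundle = results.bundle.with_values(overrides)
        out = results.reevaluate(bundle, recalibrate=recalibrate)
        inc = out["incremental"]
        row = {"iteration": i, **overrides,
               "delta_cost": inc.delta_cost, "delta_qaly": inc.delta_qaly}
        row["quadrant"] = _quadrant(inc.delta_cost, inc.delta_qaly)
        rows.append(row)
    samples = pd.DataFrame(rows)
    return PSAResults(samples=samples, seed=seed, wtp=results.bundle.wtp,
                      n_resampled=n_resampled)


def _quadrant(delta_cost: float, delta_qaly: float) -> str:
    # ties (exact zeros) go to the positive side
    ns = "N" if delta_cost >= 0 else "S"
    ew = "E" if delta_qaly >= 0 else "W"
    return ns + ew


def quadrant_proportions(samples: pd.DataFrame) -> dict[str, float]:
    """Fractions of the CE plane's four quadrants (sum to 1)."""
    if len(samples) == 0:
        raise ValueError("need at least one sample")
    counts = samples["quadrant"].value_counts()
    n = len(samples)
    return {q: float(counts.get(q, 0)) / n for q in ("NE", "NW", "SE", "SW")}


def ceac(samples: pd.DataFrame, wtp: WtpConfig | None = None) -> pd.DataFrame:
    """Cost-effectiveness acceptability curves over a WTP grid.

    At each threshold, CG's probability is the fraction of iterations in
    which its incremental net monetary benefit over erlotinib is positive;
    erlotinib's is the complement.
    """
    if len(samples) == 0:
        raise ValueError("need at least one sample")
    wtp = wtp or WtpConfig()
    grid = np.asarray(wtp.wtp_grid, dtype=float)
    dq = samples["delta_qaly"].to_numpy()
    dc = samples["delta_cost"].to_numpy()
    inb = grid[:, None] * dq[None, :] - dc[None, :]
    p_cg = (inb > 0).mean(axis=1)
    return pd.DataFrame({"wtp": grid, "p_cg": p_cg, "p_erlotinib": 1.0 - p_cg})


@dataclass
class PSAResults:
    """Probabilistic sensitivity analysis output (CG minus erlotinib)."""

    samples: pd.DataFrame
    seed: int
    wtp: WtpConfig
    n_resampled: int = 0

    def quadrant_proportions(self) -> dict[str, float]:
        return quadrant_proportions(self.samples)

    def ceac(self, wtp: WtpConfig | None = None) -> pd.DataFrame:
        return ceac(self.samples, wtp or self.wtp)

    def prob_cg_cost_effective(self, wtp_threshold: float | None = None) -> float:
        """P(CG's NMB beats erlotinib's) at one threshold."""
        wtp = self.wtp.wtp_threshold if wtp_threshold is None else wtp_threshold
        inb = wtp * self.samples["delta_qaly"] - self.samples["delta_cost"]
        return float((inb > 0).mean())

    def ceac_crossing(self, level: float = 0.5) -> float:
        """Smallest grid WTP at which CG's probability reaches ``level``."""
        curve = self.ceac()
        hit = curve[curve["p_cg"] >= level]
        return float(hit["wtp"].iloc[0]) if len(hit) else math.inf

    def plot_ce_plane(self, ax=None):
        from . import plots

        return plots.plot_ce_plane(self, ax=ax)

    def plot_ceac(self, ax=None):
        from . import plots

        return plots.plot_ceac(self, ax=ax)


# ---------------------------------------------------------------------------
# published-occupancy reanalysis

def reference_icer(
    u_pfs_erlotinib: float = 0.65,
    u_pfs_cg: float = 0.56,
    u_dp: float = 0.47,
    ref: dict | None = None,
) -> float:
    """ICER (USD/QALY, CG minus erlotinib) from the published occupancies.

    Holds state person-years and lifetime costs at their published base-case
    values and recomposes QALYs under the given utilities — the utility rows
    of the one-way analysis, anchored to the printed table rather than to a
    recalibrated trace.
    """
    from .params import UtilitySet

    ref = ref or reference_base_case()
    utilities = UtilitySet(
        u_pfs_erlotinib=u_pfs_erlotinib, u_pfs_cg=u_pfs_cg, u_dp=u_dp)
    erl = econ_from_occupancy(
        "erlotinib", ref["ly_pfs_erlotinib"], ref["ly_dp_erlotinib"],
        utilities, cost_pfs=ref["cost_total_erlotinib"])
    cg = econ_from_occupancy(
        "cg", ref["ly_pfs_cg"], ref["ly_dp_cg"],
        utilities, cost_pfs=ref["cost_total_cg"])
    return _icer(erl, cg).icer_per_qaly
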