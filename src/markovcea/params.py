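"""Model inputs: structural constants, costs, utilities, adverse-event
profiles, survival anchors and uncertainty specifications.

Every default in this module is a published input of the source evaluation
(unit costs and per-cycle aggregates in 2010 US dollars, state utilities,
adverse-event rates, trial survival medians, the willingness-to-pay
threshold).  A flat YAML config file can override any field; unknown keys
and out-of-bound values are hard errors so a typo can never silently run
the base case.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import yaml

__all__ = [
    "ConfigError",
    "ValidationError",
    "ModelStructure",
    "UtilitySet",
    "CostParams",
    "AdverseEvent",
    "AdverseEventProfile",
    "SurvivalInputs",
    "ParameterSpec",
    "WtpConfig",
    "ParameterBundle",
    "default_bundle",
    "default_parameter_specs",
    "load_config",
    "write_config",
    "reference_base_case",
]

DAYS_PER_MONTH = 30.4375
DAYS_PER_YEAR = 365.25


class ConfigError(ValueError):
    """Malformed or unknown configuration content."""


class ValidationError(ValueError):
    """A parameter violates its documented bounds."""


def _check(cond: bool, field_name: str, message: str) -> None:
    if not cond:
        raise ValidationError(f"{field_name}: {message}")


@dataclass(frozen=True)
class ModelStructure:
    """Cycle length, horizon and discounting of the cohort model.

    The model steps in 3-week (21-day) cycles over a 10-year horizon and
    discounts costs and effects at 3% per year.  Months are 30.4375 days and
    years 365.25 days everywhere, so unit conversions are calendar-free.
    """

    cycle_length_days: float = 21.0
    horizon_years: float = 10.0
    discount_rate_annual: float = 0.03

    def __post_init__(self) -> None:
        _check(self.cycle_length_days > 0, "cycle_length_days", "must be > 0")
        _check(self.horizon_years > 0, "horizon_years", "must be > 0")
        _check(
            0.0 <= self.discount_rate_annual <= 1.0,
            "discount_rate_annual",
            "must lie in [0, 1]",
        )

    @property
    def n_cycles(self) -> int:
        """Number of cycles covering the horizon (ceil; 174 at defaults)."""
        return math.ceil(self.horizon_years * DAYS_PER_YEAR / self.cycle_length_days)

    @property
    def cycle_length_months(self) -> float:
        return self.cycle_length_days / DAYS_PER_MONTH

    @property
    def cycle_length_years(self) -> float:
        return self.cycle_length_days / DAYS_PER_YEAR


@dataclass(frozen=True)
class UtilitySet:
    """Health-state preference weights (1 = perfect health, 0 = death).

    PFS on erlotinib keeps the no-toxicity utility 0.65; PFS on chemotherapy
    is adjusted down to 0.56 for treatment toxicity; progressed disease is
    0.47 for both arms.
    """

    u_pfs_erlotinib: float = 0.65
    u_pfs_cg: float = 0.56
    u_dp: float = 0.47

    u_death: float = dataclasses.field(default=0.0, init=False)

    def __post_init__(self) -> None:
        for name in ("u_pfs_erlotinib", "u_pfs_cg", "u_dp"):
            _check(0.0 <= getattr(self, name) <= 1.0, name, "utility must lie in [0, 1]")

    def u_pfs(self, strategy: str) -> float:
        if strategy == "erlotinib":
            return self.u_pfs_erlotinib
        if strategy == "cg":
            return self.u_pfs_cg
        raise ValueError(f"unknown strategy {strategy!r}")


@dataclass(frozen=True)
class CostParams:
    """Per-cycle cost aggregates (2010 USD).

    Chemotherapy (carboplatin-gemcitabine, CG) costs 1599.41 per cycle for
    cycles 1-4, after which progression-free patients move to best supportive
    care at 1415.4 per cycle.  Erlotinib costs 1971.1 per cycle for cycles
    1-7; from cycle 8 the drug is donated (manufacturer programme) and drug
    cost drops to zero.  Differential blood-test costs are charged per PFS
    cycle on treatment.  Progressed disease costs 1209.96 per cycle in both
    arms.
    """

    cg_tt_per_cycle: float = 1599.41
    cg_bsc_per_cycle: float = 1415.4
    erl_tt_per_cycle: float = 1971.1
    erl_after_donation_per_cycle: float = 0.0
    admin_chemo_per_cycle: float = 54.74
    blood_test_cg_per_cycle: float = 10.59
    blood_test_erl_per_cycle: float = 3.53
    dp_cost_per_cycle: float = 1209.96
    erl_unit_price_per_week: float = 657.05  # one 150 mg x 7 pack

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            _check(getattr(self, f.name) >= 0, f.name, "cost must be >= 0")


@dataclass(frozen=True)
class AdverseEvent:
    name: str
    rate: float
    unit_cost: float

    def __post_init__(self) -> None:
        _check(0.0 <= self.rate <= 1.0, f"{self.name}.rate", "must lie in [0, 1]")
        _check(self.unit_cost >= 0, f"{self.name}.unit_cost", "must be >= 0")


@dataclass(frozen=True)
class AdverseEventProfile:
    """Grade-relevant adverse events with per-episode management costs.

    The chemotherapy arm carries neutropenia, thrombocytopenia and anaemia;
    the erlotinib arm reported none of these, so its profile is all-zero.
    The anaemia rate defaults to 0.13 (the uncertainty-table value, which
    reproduces the published expected management cost of 1620.951 exactly);
    the alternative 9% figure is reachable via the ``rate_anaemia`` override.
    """

    events: tuple[AdverseEvent, ...] = (
        AdverseEvent("neutropenia", 0.42, 461.5),
        AdverseEvent("thrombocytopenia", 0.40, 3395.0),
        AdverseEvent("anaemia", 0.13, 531.7),
    )

    @classmethod
    def none(cls) -> "AdverseEventProfile":
        return cls(
            events=tuple(
                AdverseEvent(e.name, 0.0, e.unit_cost)
                for e in cls().events
            )
        )

    def rate(self, name: str) -> float:
        return self._get(name).rate

    def unit_cost(self, name: str) -> float:
        return self._get(name).unit_cost

    def _get(self, name: str) -> AdverseEvent:
        for e in self.events:
            if e.name == name:
                return e
        raise KeyError(name)

    def replace_event(self, name: str, *, rate: float | None = None,
                      unit_cost: float | None = None) -> "AdverseEventProfile":
        new = []
        for e in self.events:
            if e.name == name:
                e = AdverseEvent(
                    e.name,
                    e.rate if rate is None else rate,
                    e.unit_cost if unit_cost is None else unit_cost,
                )
            new.append(e)
        return AdverseEventProfile(events=tuple(new))


@dataclass(frozen=True)
class SurvivalInputs:
    """Trial survival anchors and calibration targets.

    ``median_pfs_*`` are the trial-reported progression-free survival
    medians (months).  ``hazard_ratio_erl_vs_cg`` is the trial hazard ratio
    (0.16, 95% CI 0.10-0.26); it is available for scenario analysis but the
    default calibration fits each arm to its own median.
    ``target_dp_ly_*`` are the published discounted person-years spent in
    progressed disease, the only anchor available for post-progression
    mortality.
    """

    median_pfs_erl: float = 13.1
    median_pfs_cg: float = 4.6
    hazard_ratio_erl_vs_cg: float = 0.16
    weibull_shape_default: float = 1.0
    target_dp_ly_erl: float = 1.23
    target_dp_ly_cg: float = 3.65

    def __post_init__(self) -> None:
        _check(self.median_pfs_erl > 0, "median_pfs_erl", "must be > 0")
        _check(self.median_pfs_cg > 0, "median_pfs_cg", "must be > 0")
        _check(self.hazard_ratio_erl_vs_cg > 0, "hazard_ratio_erl_vs_cg", "must be > 0")
        _check(self.weibull_shape_default > 0, "weibull_shape_default", "must be > 0")
        _check(self.target_dp_ly_erl > 0, "target_dp_ly_erl", "must be > 0")
        _check(self.target_dp_ly_cg > 0, "target_dp_ly_cg", "must be > 0")


_FAMILIES = ("gamma", "lognormal", "beta", "constant")


@dataclass(frozen=True)
class ParameterSpec:
    """One uncertain parameter: base value, one-way range, PSA family.

    ``role`` names the model input the spec binds to (a config key), so the
    same object drives both the tornado analysis and probabilistic sampling.
    """

    name: str
    base: float
    low: float
    high: float
    family: str
    role: str

    def __post_init__(self) -> None:
        _check(self.family in _FAMILIES, f"{self.name}.family",
               f"must be one of {_FAMILIES}")
        _check(self.low <= self.base <= self.high, f"{self.name}",
               f"requires low <= base <= high (got {self.low}, {self.base}, {self.high})")
        if self.family == "beta":
            _check(0.0 <= self.low and self.high <= 1.0, f"{self.name}",
                   "beta family requires the range inside [0, 1]")


@dataclass(frozen=True)
class WtpConfig:
    """Willingness-to-pay threshold and the CEAC evaluation grid (USD/QALY).

    The decision threshold is $13,527/QALY (three times China's 2010 per
    capita GDP).  The default grid spans 0-500k so the acceptability curves
    cover their upper crossing.
    """

    wtp_threshold: float = 13527.0
    wtp_grid: tuple[float, ...] = tuple(float(x) for x in range(0, 500001, 5000))

    def __post_init__(self) -> None:
        _check(self.wtp_threshold >= 0, "wtp_threshold", "must be >= 0")
        grid = self.wtp_grid
        _check(len(grid) > 0, "wtp_grid", "must be non-empty")
        _check(all(g >= 0 for g in grid), "wtp_grid", "all values must be >= 0")
        _check(all(b > a for a, b in zip(grid, grid[1:])), "wtp_grid",
               "must be strictly ascending")


@dataclass(frozen=True)
class ParameterBundle:
    """The complete, validated input set for one model run."""

    structure: ModelStructure = field(default_factory=ModelStructure)
    utilities: UtilitySet = field(default_factory=UtilitySet)
    costs: CostParams = field(default_factory=CostParams)
    cg_adverse_events: AdverseEventProfile = field(default_factory=AdverseEventProfile)
    erl_adverse_events: AdverseEventProfile = field(
        default_factory=AdverseEventProfile.none)
    survival: SurvivalInputs = field(default_factory=SurvivalInputs)
    wtp: WtpConfig = field(default_factory=WtpConfig)
    # accounting switches (see methods note)
    dp_cost_basis: str = "cycle"        # {"cycle", "month"}
    include_blood_tests: bool = True
    blood_tests_stop_at_bsc: bool = True

    def __post_init__(self) -> None:
        _check(self.dp_cost_basis in ("cycle", "month"), "dp_cost_basis",
               "must be 'cycle' or 'month'")

    # -- overrides ---------------------------------------------------------

    def with_value(self, role: str, value: float) -> "ParameterBundle":
        """Return a copy of the bundle with one named input replaced.

        ``role`` is any config key (see ``_ROLE_MAP``); this is the binding
        used by one-way sensitivity analysis and probabilistic sampling.
        """
        return _apply_overrides(self, {role: value})

    def with_values(self, overrides: dict[str, float]) -> "ParameterBundle":
        return _apply_overrides(self, overrides)

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        d: dict = {}
        for attr in ("structure", "utilities", "costs", "survival"):
            d.update(dataclasses.asdict(getattr(self, attr)))
        d.pop("u_death", None)
        for e in self.cg_adverse_events.events:
            d[f"rate_{e.name}"] = e.rate
            d[f"cost_{e.name}"] = e.unit_cost
        d["wtp_threshold"] = self.wtp.wtp_threshold
        d["wtp_grid"] = list(self.wtp.wtp_grid)
        d["dp_cost_basis"] = self.dp_cost_basis
        d["include_blood_tests"] = self.include_blood_tests
        d["blood_tests_stop_at_bsc"] = self.blood_tests_stop_at_bsc
        return d

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


# ---------------------------------------------------------------------------
# role/key dispatch

_STRUCTURE_KEYS = {"cycle_length_days", "horizon_years", "discount_rate_annual"}
_UTILITY_KEYS = {"u_pfs_erlotinib", "u_pfs_cg", "u_dp"}
_COST_KEYS = {f.name for f in dataclasses.fields(CostParams)}
_SURVIVAL_KEYS = {f.name for f in dataclasses.fields(SurvivalInputs)}
_AE_RATE_KEYS = {"rate_neutropenia", "rate_thrombocytopenia", "rate_anaemia"}
_AE_COST_KEYS = {"cost_neutropenia", "cost_thrombocytopenia", "cost_anaemia"}
_SWITCH_KEYS = {"dp_cost_basis", "include_blood_tests", "blood_tests_stop_at_bsc"}
_WTP_KEYS = {"wtp_threshold", "wtp_grid"}

KNOWN_KEYS = (
    _STRUCTURE_KEYS | _UTILITY_KEYS | _COST_KEYS | _SURVIVAL_KEYS
    | _AE_RATE_KEYS | _AE_COST_KEYS | _SWITCH_KEYS | _WTP_KEYS
)


def _apply_overrides(bundle: ParameterBundle, overrides: dict) -> ParameterBundle:
    unknown = set(overrides) - KNOWN_KEYS
    if unknown:
        raise ConfigError(
            "unknown configuration key(s): " + ", ".join(sorted(unknown)))

    structure = bundle.structure
    utilities = bundle.utilities
    costs = bundle.costs
    survival = bundle.survival
    cg_ae = bundle.cg_adverse_events
    wtp = bundle.wtp
    switches = {
        "dp_cost_basis": bundle.dp_cost_basis,
        "include_blood_tests": bundle.include_blood_tests,
        "blood_tests_stop_at_bsc": bundle.blood_tests_stop_at_bsc,
    }

    for key, value in overrides.items():
        if key in _STRUCTURE_KEYS:
            structure = dataclasses.replace(structure, **{key: float(value)})
        elif key in _UTILITY_KEYS:
            utilities = dataclasses.replace(utilities, **{key: float(value)})
        elif key in _COST_KEYS:
            costs = dataclasses.replace(costs, **{key: float(value)})
        elif key in _SURVIVAL_KEYS:
            survival = dataclasses.replace(survival, **{key: float(value)})
        elif key in _AE_RATE_KEYS:
            cg_ae = cg_ae.replace_event(key.removeprefix("rate_"), rate=float(value))
        elif key in _AE_COST_KEYS:
            cg_ae = cg_ae.replace_event(key.removeprefix("cost_"),
                                        unit_cost=float(value))
        elif key == "wtp_threshold":
            wtp = dataclasses.replace(wtp, wtp_threshold=float(value))
        elif key == "wtp_grid":
            wtp = dataclasses.replace(wtp, wtp_grid=tuple(float(v) for v in value))
        elif key in _SWITCH_KEYS:
            switches[key] = value
    return ParameterBundle(
        structure=structure,
        utilities=utilities,
        costs=costs,
        cg_adverse_events=cg_ae,
        erl_adverse_events=bundle.erl_adverse_events,
        survival=survival,
        wtp=wtp,
        **switches,
    )


def default_bundle() -> ParameterBundle:
    """The base case: every input at its published default."""
    return ParameterBundle()


def load_config(path: str | Path) -> ParameterBundle:
    """Read a flat YAML config file and return a validated bundle.

    Missing keys fall back to the published defaults; unknown keys raise
    :class:`ConfigError`; bound violations raise :class:`ValidationError`
    naming the field.  An empty file yields the default bundle.
    """
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"could not parse {path}: {exc}") from exc
    if raw is None:
        return default_bundle()
    if not isinstance(raw, dict):
        raise ConfigError(
            f"{path}: expected a flat key/value mapping, got {type(raw).__name__}")
    return _apply_overrides(default_bundle(), raw)


def write_config(bundle: ParameterBundle, path: str | Path) -> None:
    """Write a bundle as a flat YAML file that ``load_config`` round-trips."""
    Path(path).write_text(yaml.safe_dump(bundle.to_dict(), sort_keys=True))


# ---------------------------------------------------------------------------
# uncertainty table

def default_parameter_specs() -> tuple[ParameterSpec, ...]:
    """The published uncertainty table: 17 rows of (base, low, high, family).

    Ranges are the one-way sensitivity ranges; families are the PSA sampling
    distributions.  The discount rate is varied one-way but held constant in
    the PSA.
    """
    rows = [
        ("cost of CG in the PFS per cycle(<5 cycle)",
         1599.41, 1279.53, 1919.29, "gamma", "cg_tt_per_cycle"),
        ("cost of CG in the PFS per cycle(>=5 cycle)",
         1415.4, 1022.8, 2021.5, "lognormal", "cg_bsc_per_cycle"),
        ("cost of erlotinib in the PFS per cycle(<8 cycle)",
         1971.1, 1576.9, 2365.4, "lognormal", "erl_tt_per_cycle"),
        ("Administration cost chemo per cycle",
         54.74, 43.09, 64.63, "gamma", "admin_chemo_per_cycle"),
        ("Cost of neutropenia",
         461.5, 415.4, 507.7, "lognormal", "cost_neutropenia"),
        ("Cost of thrombocytopenia",
         3395.0, 3017.5, 3804.6, "lognormal", "cost_thrombocytopenia"),
        ("Cost of anaemia",
         531.7, 478.5, 584.9, "lognormal", "cost_anaemia"),
        ("Blood tests CG group",
         10.59, 8.47, 12.71, "lognormal", "blood_test_cg_per_cycle"),
        ("Blood tests Erl group",
         3.53, 2.82, 4.24, "lognormal", "blood_test_erl_per_cycle"),
        ("cost of DP for both groups per cycle",
         1209.96, 967.97, 1451.95, "gamma", "dp_cost_per_cycle"),
        ("Neutropenia in CG", 0.42, 0.34, 0.50, "beta", "rate_neutropenia"),
        ("Thrombocytopenia in CG", 0.40, 0.32, 0.48, "beta", "rate_thrombocytopenia"),
        ("Anaemia in CG", 0.13, 0.10, 0.156, "beta", "rate_anaemia"),
        ("PFS of erlotinib", 0.65, 0.26, 0.87, "beta", "u_pfs_erlotinib"),
        ("PFS of CG", 0.56, 0.224, 0.75, "beta", "u_pfs_cg"),
        ("DP", 0.47, 0.30, 0.58, "beta", "u_dp"),
        ("Discount rate", 0.03, 0.0, 0.08, "constant", "discount_rate_annual"),
    ]
    return tuple(ParameterSpec(*row) for row in rows)


def reference_base_case() -> dict[str, float]:
    """Published base-case results (discounted at 3%/year), used as inputs.

    These are the validation anchors of the analysis: discounted state
    person-years, QALYs and lifetime costs per strategy, and the headline
    incremental ratios.  The DP person-years double as calibration targets
    for post-progression mortality.
    """
    return {
        "ly_total_erlotinib": 2.5,
        "ly_total_cg": 4.08,
        "ly_pfs_erlotinib": 1.27,
        "ly_pfs_cg": 0.43,
        "ly_dp_erlotinib": 1.23,
        "ly_dp_cg": 3.65,
        "qaly_total_erlotinib": 1.4,
        "qaly_total_cg": 1.96,
        "qaly_pfs_erlotinib": 0.82,
        "qaly_pfs_cg": 0.24,
        "qaly_dp_erlotinib": 0.58,
        "qaly_dp_cg": 1.72,
        "cost_mae_cg": 1620.951,
        "cost_pfs_erlotinib": 14772.04,
        "cost_pfs_cg": 13060.35,
        "cost_dp_erlotinib": 25335.91,
        "cost_dp_cg": 75166.95,
        "cost_total_erlotinib": 40107.95,
        "cost_total_cg": 88227.3,
        "icer_per_qaly": 85927.41,
        "icer_per_ly": 30455.28,
        "model_median_pfs_erlotinib": 13.2,
        "model_median_pfs_cg": 4.64,
    }
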