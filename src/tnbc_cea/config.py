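"""Analysis configuration: schema, validation, YAML IO, and the bundled
CPS>=10 base case.

A configuration holds exactly two strategies (intervention and comparator),
their extrapolated survival curves and regimens, the cost/utility/AE
tables, and global settings (3-week cycles, 174-cycle horizon, 5% annual
discounting, WTP threshold $38,224/QALY).

Uncertain quantities are addressed by dotted paths into the config tree
(e.g. ``costs.drug_prices_per_100mg.pembrolizumab`` or ``utilities.pfs``);
the sensitivity-analysis machinery reads and writes through these paths.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass
import yaml

from .economics import (
    AEProfile,
    DrugComponent,
    PatientProfile,
    RecurringCost,
    RegimenSpec,
    UnitCosts,
    UtilitySet,
)
from .survival import ParametricSurvival

__all__ = [
    "ConfigError",
    "Settings",
    "PSASettings",
    "StrategyConfig",
    "AnalysisConfig",
    "default_cps10_config",
    "validate_and_load",
    "load_config",
    "save_config",
    "get_by_path",
    "set_by_path",
]

logger = logging.getLogger(__name__)

DEFAULT_PSA_SEED = 12345


class ConfigError(ValueError):
    """Configuration schema or value error."""


@dataclass
class Settings:
    cycle_days: float = 21.0
    horizon_cycles: int = 174
    discount_rate: float = 0.05
    wtp: float = 38224.0
    background_mortality_annual: float = 0.002
    half_cycle_correction: bool = False

    def __post_init__(self):
        if self.cycle_days <= 0:
            raise ConfigError("settings.cycle_days must be positive")
        if self.horizon_cycles < 1:
            raise ConfigError("settings.horizon_cycles must be >= 1")
        if self.discount_rate < 0:
            raise ConfigError(
                f"settings.discount_rate must be >= 0, got {self.discount_rate}"
            )
        if self.wtp <= 0:
            raise ConfigError("settings.wtp must be positive")
        if not 0 <= self.background_mortality_annual <= 1:
            raise ConfigError("settings.background_mortality_annual outside [0, 1]")


@dataclass
class PSASettings:
    n_iterations: int = 1000
    seed: int = DEFAULT_PSA_SEED

    def __post_init__(self):
        if self.n_iterations < 1:
            raise ConfigError("psa.n_iterations must be >= 1")


@dataclass
class StrategyConfig:
    """One arm: its survival curves, regimen, and adverse-event profile."""

    name: str
    pfs_curve: ParametricSurvival
    os_curve: ParametricSurvival
    regimen: RegimenSpec
    ae: AEProfile


@dataclass
class AnalysisConfig:
    settings: Settings
    patient: PatientProfile
    costs: UnitCosts
    utilities: UtilitySet
    intervention: StrategyConfig
    comparator: StrategyConfig
    psa: PSASettings

    def strategy(self, which: str) -> StrategyConfig:
        if which not in ("intervention", "comparator"):
            raise ConfigError(f"unknown strategy {which!r}")
        return getattr(self, which)


# -- bundled CPS>=10 base case ----------------------------------------------

#: KEYNOTE-355-style chemotherapy backbone mixture (cohort shares) with a
#: 6-cycle treated cap; carboplatin uses a fixed 625 mg-equivalent per
#: administration (AUC 5 with an assumed GFR of 100 mL/min).
def _chemo_backbone() -> tuple:
    return (
        DrugComponent("gemcitabine", "per_m2", 1000.0, admins_per_cycle=2,
                      weight=0.55, max_cycles=6),
        DrugComponent("carboplatin", "flat", 625.0, admins_per_cycle=1,
                      weight=0.55, max_cycles=6),
        DrugComponent("nab_paclitaxel", "per_m2", 100.0, admins_per_cycle=3,
                      weight=0.31, max_cycles=6),
        DrugComponent("paclitaxel", "per_m2", 90.0, admins_per_cycle=3,
                      weight=0.14, max_cycles=6),
    )


def default_cps10_config() -> AnalysisConfig:
    """The bundled base case for the PD-L1 CPS>=10 subgroup.

    Curves, prices, utilities and adverse-event inputs follow the published
    model inputs for this population; the costing conventions (35-cycle
    pembrolizumab cap, treatment-gated chemotherapy/supportive care,
    post-progression follow-up) are documented in docs/methods.md.
    """
    pembro = DrugComponent("pembrolizumab", "flat", 200.0, admins_per_cycle=1,
                           weight=1.0, max_cycles=35)
    costs = UnitCosts(
        drug_prices_per_100mg={
            "pembrolizumab": 2451.60,
            "gemcitabine": 18.64,
            "carboplatin": 7.06,
            "nab_paclitaxel": 20.25,
            "paclitaxel": 24.75,
        },
        supportive=RecurringCost(359.0, state="pfs", max_cycles=6),
        followup=RecurringCost(170.0, state="pd", max_cycles=None),
        terminal_care=2325.75,
        ae_event_costs={
            "anemia": 607.06,
            "neutropenia": 547.5,
            "neutrophil_count_decreased": 104.95,
        },
    )
    utilities = UtilitySet(
        pfs=0.76, pd=0.55,
        ae_disutilities={
            "anemia": 0.029,
            "neutropenia": 0.012,
            "neutrophil_count_decreased": 0.2,
        },
    )
    intervention = StrategyConfig(
        name="pembrolizumab_chemotherapy",
        pfs_curve=ParametricSurvival("lognormal", (2.3487, 1.2258)),
        os_curve=ParametricSurvival("lognormal", (3.1454, 1.1058)),
        regimen=RegimenSpec((pembro,) + _chemo_backbone()),
        ae=AEProfile({
            "anemia": 0.165,
            "neutropenia": 0.297,
            "neutrophil_count_decreased": 0.174,
        }),
    )
    comparator = StrategyConfig(
        name="placebo_chemotherapy",
        pfs_curve=ParametricSurvival("loglogistic", (1.763, 6.618)),
        os_curve=ParametricSurvival("loglogistic", (1.702, 16.631)),
        regimen=RegimenSpec(_chemo_backbone()),
        ae=AEProfile({
            "anemia": 0.146,
            "neutropenia": 0.299,
            "neutrophil_count_decreased": 0.203,
        }),
    )
    return AnalysisConfig(
        settings=Settings(),
        patient=PatientProfile(),
        costs=costs,
        utilities=utilities,
        intervention=intervention,
        comparator=comparator,
        psa=PSASettings(),
    )


# -- serialization ------------------------------------------------------------


def _require(d: dict, key: str, where: str):
    if key not in d:
        raise ConfigError(f"missing required key '{where}.{key}'" if where else
                          f"missing required key '{key}'")
    return d[key]


def _curve_from_dict(d: dict, where: str) -> ParametricSurvival:
    family = _require(d, "family", where)
    params = _require(d, "params", where)
    try:
        return ParametricSurvival(family, tuple(params))
    except ValueError as exc:
        raise ConfigError(f"{where}: {exc}") from exc


def _strategy_from_dict(d: dict, where: str) -> StrategyConfig:
    comps = []
    for i, c in enumerate(_require(d, "regimen", where)):
        try:
            comps.append(DrugComponent(
                name=_require(c, "name", f"{where}.regimen[{i}]"),
                dose_rule=_require(c, "dose_rule", f"{where}.regimen[{i}]"),
                dose_mg=_require(c, "dose_mg", f"{where}.regimen[{i}]"),
                admins_per_cycle=c.get("admins_per_cycle", 1),
                weight=c.get("weight", 1.0),
                max_cycles=c.get("max_cycles"),
            ))
        except ValueError as exc:
            raise ConfigError(f"{where}.regimen[{i}]: {exc}") from exc
    try:
        ae = AEProfile(dict(_require(d, "ae_incidence", where)))
    except ValueError as exc:
        raise ConfigError(f"{where}.ae_incidence: {exc}") from exc
    return StrategyConfig(
        name=_require(d, "name", where),
        pfs_curve=_curve_from_dict(_require(d, "pfs_curve", where), f"{where}.pfs_curve"),
        os_curve=_curve_from_dict(_require(d, "os_curve", where), f"{where}.os_curve"),
        regimen=RegimenSpec(tuple(comps)),
        ae=ae,
    )


def _recurring_from_dict(d: dict, where: str) -> RecurringCost:
    try:
        return RecurringCost(
            amount=_require(d, "amount", where),
            state=d.get("state", "pfs"),
            max_cycles=d.get("max_cycles"),
        )
    except ValueError as exc:
        raise ConfigError(f"{where}: {exc}") from exc


def from_dict(data: dict) -> AnalysisConfig:
    """Build and validate an AnalysisConfig from a plain nested dict."""
    if not isinstance(data, dict):
        raise ConfigError("top-level config must be a mapping")
    try:
        settings = Settings(**data.get("settings", {}))
    except TypeError as exc:
        raise ConfigError(f"settings: {exc}") from exc
    patient = PatientProfile(**data.get("patient", {}))
    cd = _require(data, "costs", "")
    try:
        costs = UnitCosts(
            drug_prices_per_100mg=dict(_require(cd, "drug_prices_per_100mg", "costs")),
            supportive=_recurring_from_dict(_require(cd, "supportive", "costs"),
                                            "costs.supportive"),
            followup=_recurring_from_dict(_require(cd, "followup", "costs"),
                                          "costs.followup"),
            terminal_care=_require(cd, "terminal_care", "costs"),
            ae_event_costs=dict(cd.get("ae_event_costs", {})),
        )
    except ValueError as exc:
        raise ConfigError(f"costs: {exc}") from exc
    ud = _require(data, "utilities", "")
    try:
        utilities = UtilitySet(
            pfs=_require(ud, "pfs", "utilities"),
            pd=_require(ud, "pd", "utilities"),
            ae_disutilities=dict(ud.get("ae_disutilities", {})),
        )
    except ValueError as exc:
        raise ConfigError(f"utilities: {exc}") from exc
    psa_d = dict(data.get("psa", {}))
    if "seed" not in psa_d:
        logger.warning("psa.seed not set; using default seed %d", DEFAULT_PSA_SEED)
    try:
        psa = PSASettings(**psa_d)
    except TypeError as exc:
        raise ConfigError(f"psa: {exc}") from exc
    return AnalysisConfig(
        settings=settings,
        patient=patient,
        costs=costs,
        utilities=utilities,
        intervention=_strategy_from_dict(_require(data, "intervention", ""),
                                         "intervention"),
        comparator=_strategy_from_dict(_require(data, "comparator", ""),
                                       "comparator"),
        psa=psa,
    )


def to_dict(config: AnalysisConfig) -> dict:
    def curve(c: ParametricSurvival) -> dict:
        return {"family": c.family, "params": list(c.params)}

    def strategy(s: StrategyConfig) -> dict:
        return {
            "name": s.name,
            "pfs_curve": curve(s.pfs_curve),
            "os_curve": curve(s.os_curve),
            "regimen": [
                {k: v for k, v in dataclasses.asdict(comp).items() if v is not None}
                for comp in s.regimen.components
            ],
            "ae_incidence": dict(s.ae.incidence),
        }

    def recurring(r: RecurringCost) -> dict:
        d = {"amount": r.amount, "state": r.state}
        if r.max_cycles is not None:
            d["max_cycles"] = r.max_cycles
        return d

    return {
        "settings": dataclasses.asdict(config.settings),
        "patient": dataclasses.asdict(config.patient),
        "costs": {
            "drug_prices_per_100mg": dict(config.costs.drug_prices_per_100mg),
            "supportive": recurring(config.costs.supportive),
            "followup": recurring(config.costs.followup),
            "terminal_care": config.costs.terminal_care,
            "ae_event_costs": dict(config.costs.ae_event_costs),
        },
        "utilities": {
            "pfs": config.utilities.pfs,
            "pd": config.utilities.pd,
            "ae_disutilities": dict(config.utilities.ae_disutilities),
        },
        "intervention": strategy(config.intervention),
        "comparator": strategy(config.comparator),
        "psa": dataclasses.asdict(config.psa),
    }


def validate_and_load(path) -> AnalysisConfig:
    """Load a YAML/JSON config file, validating schema and value ranges."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return from_dict(data)


#: Alias kept for symmetry with :func:`save_config`.
load_config = validate_and_load


def save_config(config: AnalysisConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(to_dict(config), fh, sort_keys=False)


def config_digest(config: AnalysisConfig) -> str:
    """Stable short hash of the config contents, for output provenance."""
    blob = yaml.safe_dump(to_dict(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


# -- dotted-path access -------------------------------------------------------


def _walk(obj, parts):
    for p in parts:
        if isinstance(obj, dict):
            if p not in obj:
                raise ConfigError(f"unknown config path element {p!r}")
            obj = obj[p]
        elif dataclasses.is_dataclass(obj) and hasattr(obj, p):
            obj = getattr(obj, p)
        else:
            raise ConfigError(f"unknown config path element {p!r}")
    return obj


def get_by_path(config: AnalysisConfig, path: str):
    """Read a value at a dotted path like ``utilities.pfs``."""
    return _walk(config, path.split("."))


def set_by_path(config: AnalysisConfig, path: str, value) -> None:
    """Write a value at a dotted path (in place; use on a deep copy)."""
    parts = path.split(".")
    parent = _walk(config, parts[:-1])
    leaf = parts[-1]
    if isinstance(parent, dict):
        if leaf not in parent:
            raise ConfigError(f"unknown config path element {leaf!r}")
        parent[leaf] = value
    elif dataclasses.is_dataclass(parent) and hasattr(parent, leaf):
        object.__setattr__(parent, leaf, value)  # tolerates frozen dataclasses
    else:
        raise ConfigError(f"unknown config path element {leaf!r}")
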