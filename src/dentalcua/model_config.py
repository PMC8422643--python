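"""Domain types and configuration for the two-arm prosthetic decision model.

The whole study is a parameter set, so the configuration file IS the study
record: a single versioned YAML document encodes the health states and
failure-destination rules of each treatment arm, the cost tables (initial
costs per treatment variant, banded annual maintenance costs, entry costs),
the utility weights on a 0–100 scale, the survival parameters of each
prosthesis, and the economic settings (discount rate, horizon, conventions).

`load_config` parses and validates a document; `make_reference_config`
returns the packaged base-case parameterization (Czech single-molar
replacement, implant-supported single crown vs. three-unit fixed dental
prosthesis, 30-year horizon, 3% discount rate).
"""

from __future__ import annotations

import copy
import importlib.resources
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Any, Mapping, Optional, Sequence

import yaml

from .survival import Family, SurvivalModel

SCHEMA_VERSION = 1


class ConfigError(ValueError):
    """A configuration document violates the schema or a model invariant."""


class DiscountConvention(str, Enum):
    """When discounting starts relative to the first model cycle.

    FROM_CYCLE_1 leaves the first year undiscounted (costs and utilities are
    discounted "beyond one year"); FROM_CYCLE_0 discounts every cycle
    including the first; CYCLE0_REWARD_PLUS_FROM_CYCLE_1 additionally grants
    an undiscounted state reward at cycle 0 (the convention of some decision
    -tree packages).
    """

    FROM_CYCLE_1 = "from_cycle_1"
    FROM_CYCLE_0 = "from_cycle_0"
    CYCLE0_REWARD_PLUS_FROM_CYCLE_1 = "cycle0_reward_plus_from_cycle_1"


class CostBandKeying(str, Enum):
    """Whether annual cost bands follow prosthesis age or model time."""

    RESIDENCE = "residence"
    MODEL_TIME = "model_time"


@dataclass(frozen=True)
class CostSchedule:
    """Banded annual costs: ordered (year_from, year_to, annual CZK) bands.

    Bands are contiguous, start at year 1 and the last band is open-ended
    (``year_to is None``).
    """

    bands: tuple[tuple[int, Optional[int], float], ...]

    def __post_init__(self) -> None:
        if not self.bands:
            raise ConfigError("cost schedule needs at least one band")
        expected_start = 1
        for i, (lo, hi, cost) in enumerate(self.bands):
            last = i == len(self.bands) - 1
            if lo != expected_start:
                raise ConfigError(
                    f"cost bands must be contiguous from year 1; band {i} "
                    f"starts at {lo}, expected {expected_start}"
                )
            if last:
                if hi is not None:
                    raise ConfigError("last cost band must be open-ended")
            else:
                if hi is None or hi < lo:
                    raise ConfigError(f"band {i} has invalid upper year {hi}")
                expected_start = hi + 1
            if cost < 0:
                raise ConfigError(f"band {i} has negative annual cost {cost}")

    def annual_cost(self, year: int) -> float:
        """Annual cost applying in the given year (1-based)."""
        if year < 1:
            raise ValueError(f"year must be >= 1, got {year}")
        for lo, hi, cost in self.bands:
            if year >= lo and (hi is None or year <= hi):
                return cost
        raise AssertionError("unreachable: last band is open-ended")


@dataclass(frozen=True)
class HealthState:
    """A model health state: a prosthesis in place, or the absorbing gap."""

    name: str
    utility: float  # quality weight, 0-100 scale
    absorbing: bool
    annual_cost_bands: CostSchedule
    survival_ref: Optional[str] = None  # key into the survival-model set

    def __post_init__(self) -> None:
        if not 0.0 <= self.utility <= 100.0:
            raise ConfigError(
                f"state {self.name!r}: utility {self.utility} outside [0, 100]"
            )
        if self.absorbing and self.survival_ref is not None:
            raise ConfigError(
                f"absorbing state {self.name!r} must not have a survival model"
            )
        if not self.absorbing and self.survival_ref is None:
            raise ConfigError(
                f"non-absorbing state {self.name!r} needs a survival model"
            )


@dataclass(frozen=True)
class FailureRule:
    """Where a failed prosthesis goes: destination states and probabilities."""

    from_state: str
    destinations: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        if not self.destinations:
            raise ConfigError(f"rule for {self.from_state!r} has no destinations")
        for to, p in self.destinations:
            if not 0.0 <= p <= 1.0:
                raise ConfigError(
                    f"rule {self.from_state!r}→{to!r}: probability {p} outside [0, 1]"
                )
        total = sum(p for _, p in self.destinations)
        if abs(total - 1.0) > 1e-12:
            raise ConfigError(
                f"rule for {self.from_state!r}: destination probabilities sum "
                f"to {total!r}, expected 1"
            )


@dataclass(frozen=True)
class EntryCostTable:
    """One-off cost charged on entering a state, optionally by source state."""

    defaults: Mapping[str, float]  # to_state -> CZK
    overrides: Mapping[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for to, c in self.defaults.items():
            if c < 0:
                raise ConfigError(f"entry cost for {to!r} is negative: {c}")
        for (to, frm), c in self.overrides.items():
            if c < 0:
                raise ConfigError(
                    f"entry cost for {to!r} from {frm!r} is negative: {c}"
                )

    def cost(self, to_state: str, from_state: str) -> float:
        key = (to_state, from_state)
        if key in self.overrides:
            return self.overrides[key]
        return self.defaults.get(to_state, 0.0)


@dataclass(frozen=True)
class ArmModel:
    """One treatment strategy: its states, failure rules and costs."""

    name: str
    initial_state: str
    states: Mapping[str, HealthState]
    rules: Mapping[str, FailureRule]
    entry_costs: EntryCostTable
    initial_cost: float

    def __post_init__(self) -> None:
        if self.initial_state not in self.states:
            raise ConfigError(
                f"arm {self.name!r}: initial state {self.initial_state!r} "
                "is not a declared state"
            )
        if self.states[self.initial_state].absorbing:
            raise ConfigError(
                f"arm {self.name!r}: initial state {self.initial_state!r} "
                "must be non-absorbing"
            )
        if self.initial_cost < 0:
            raise ConfigError(f"arm {self.name!r}: negative initial cost")
        absorbing = [s for s in self.states.values() if s.absorbing]
        if len(absorbing) != 1:
            raise ConfigError(
                f"arm {self.name!r}: exactly one absorbing state required, "
                f"found {len(absorbing)}"
            )
        for state in self.states.values():
            if state.absorbing:
                if state.name in self.rules:
                    raise ConfigError(
                        f"arm {self.name!r}: absorbing state {state.name!r} "
                        "must not have a failure rule"
                    )
                continue
            if state.name not in self.rules:
                raise ConfigError(
                    f"arm {self.name!r}: non-absorbing state {state.name!r} "
                    "has no failure rule"
                )
        for rule in self.rules.values():
            if rule.from_state not in self.states:
                raise ConfigError(
                    f"arm {self.name!r}: rule references undeclared state "
                    f"{rule.from_state!r}"
                )
            for to, _ in rule.destinations:
                if to not in self.states:
                    raise ConfigError(
                        f"arm {self.name!r}: rule {rule.from_state!r} targets "
                        f"undeclared state {to!r}"
                    )
        self._check_terminal_reachability(absorbing[0].name)

    def _check_terminal_reachability(self, terminal: str) -> None:
        # every state must be able to reach the absorbing terminal
        for start in self.states:
            if start == terminal:
                continue
            seen, frontier = {start}, [start]
            while frontier:
                s = frontier.pop()
                rule = self.rules.get(s)
                if rule is None:
                    continue
                for to, p in rule.destinations:
                    if p > 0 and to not in seen:
                        seen.add(to)
                        frontier.append(to)
            if terminal not in seen:
                raise ConfigError(
                    f"arm {self.name!r}: terminal {terminal!r} unreachable "
                    f"from {start!r}"
                )

    @property
    def absorbing_state(self) -> str:
        return next(s.name for s in self.states.values() if s.absorbing)


@dataclass(frozen=True)
class EconSettings:
    """Discounting and horizon settings of the evaluation."""

    discount_rate: float = 0.03
    horizon: int = 30
    discount_convention: DiscountConvention = DiscountConvention.FROM_CYCLE_1
    half_cycle_correction: bool = False
    utility_scale: float = 100.0
    cost_band_keying: CostBandKeying = CostBandKeying.RESIDENCE

    def __post_init__(self) -> None:
        if self.discount_rate < 0:
            raise ConfigError(f"discount rate must be >= 0, got {self.discount_rate}")
        if self.horizon < 1:
            raise ConfigError(f"horizon must be >= 1 year, got {self.horizon}")
        if self.utility_scale <= 0:
            raise ConfigError("utility scale must be positive")


@dataclass(frozen=True)
class EconomicEnvironment:
    """National-economy constants feeding the indirect-cost formulas."""

    monthly_wage: float = 36144.0  # CZK, gross monthly nominal wage
    weekly_hours: float = 40.0
    weeks_per_month: float = 4.348
    unemployment_rate: float = 0.031
    base_fare: float = 32.0  # CZK, single public-transport fare
    czk_to_usd: float = 0.048  # display-only conversion constant

    def __post_init__(self) -> None:
        for name in ("monthly_wage", "weekly_hours", "weeks_per_month",
                     "base_fare", "czk_to_usd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if not 0.0 <= self.unemployment_rate <= 1.0:
            raise ConfigError("unemployment_rate must lie in [0, 1]")


@dataclass(frozen=True)
class DecisionModel:
    """Fully resolved two-arm decision model plus its economic settings."""

    evaluated: ArmModel
    comparator: ArmModel
    econ: EconSettings
    environment: EconomicEnvironment
    survival_models: Mapping[str, SurvivalModel]
    config: Mapping[str, Any] = field(compare=False, default_factory=dict)

    @property
    def arms(self) -> tuple[ArmModel, ArmModel]:
        return (self.evaluated, self.comparator)


# --------------------------------------------------------------------------
# schema parsing

_TOP_KEYS = {"schema_version", "comparison", "economics", "environment",
             "utilities", "costs", "survival", "arms"}
_ECON_KEYS = {"discount_rate", "horizon_years", "discount_convention",
              "half_cycle_correction", "utility_scale", "cost_band_keying"}
_ENV_KEYS = {"monthly_wage_czk", "weekly_hours", "weeks_per_month",
             "unemployment_rate", "base_fare_czk", "czk_to_usd"}
_COST_KEYS = {"variants", "initial", "annual_bands", "entry"}
_ARM_KEYS = {"initial_state", "states", "rules"}
_STATE_KEYS = {"prosthesis", "absorbing"}
_SURV_KEYS = {"family", "shape", "scale", "rate", "mu", "sigma", "note"}


def _reject_unknown(section: Mapping[str, Any], allowed: set[str], where: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ConfigError(
            f"unknown key(s) {sorted(unknown)} in {where}; allowed: {sorted(allowed)}"
        )


def _require(section: Mapping[str, Any], key: str, where: str) -> Any:
    if key not in section:
        raise ConfigError(f"missing required key {key!r} in {where}")
    return section[key]


def _parse_bands(raw: Sequence[Any], where: str) -> CostSchedule:
    bands = []
    for row in raw:
        if not isinstance(row, (list, tuple)) or len(row) != 3:
            raise ConfigError(f"{where}: each band must be [year_from, year_to, cost]")
        lo, hi, cost = row
        bands.append((int(lo), None if hi is None else int(hi), float(cost)))
    return CostSchedule(tuple(bands))


def _parse_survival(raw: Mapping[str, Any], where: str) -> SurvivalModel:
    _reject_unknown(raw, _SURV_KEYS, where)
    family = Family(str(_require(raw, "family", where)).lower())
    params: dict[str, float] = {}
    for key in ("shape", "scale", "rate", "mu", "sigma"):
        if key in raw:
            params[key] = float(raw[key])
    return SurvivalModel(family=family, parameters=params)


def _initial_cost(spec: Mapping[str, Any], where: str) -> Optional[float]:
    """Resolve a cost table's initial cost; 'mean' averages the variants."""
    if "initial" not in spec:
        return None
    initial = spec["initial"]
    if initial == "mean":
        variants = _require(spec, "variants", where)
        if not variants:
            raise ConfigError(f"{where}: 'mean' initial cost needs variants")
        values = [float(v) for v in variants.values()]
        # the base case uses the whole-CZK rounded mean of the variant costs
        return float(round(sum(values) / len(values)))
    return float(initial)


def build_model(config: Mapping[str, Any]) -> DecisionModel:
    """Resolve a parsed configuration mapping into a validated model."""
    if not isinstance(config, Mapping):
        raise ConfigError("configuration root must be a mapping")
    _reject_unknown(config, _TOP_KEYS, "document root")
    version = _require(config, "schema_version", "document root")
    if version != SCHEMA_VERSION:
        raise ConfigError(
            f"unsupported schema_version {version!r}; this reader supports "
            f"{SCHEMA_VERSION}"
        )

    econ_raw = dict(config.get("economics", {}))
    _reject_unknown(econ_raw, _ECON_KEYS, "economics")
    econ = EconSettings(
        discount_rate=float(econ_raw.get("discount_rate", 0.03)),
        horizon=int(econ_raw.get("horizon_years", 30)),
        discount_convention=DiscountConvention(
            econ_raw.get("discount_convention", "from_cycle_1")
        ),
        half_cycle_correction=bool(econ_raw.get("half_cycle_correction", False)),
        utility_scale=float(econ_raw.get("utility_scale", 100.0)),
        cost_band_keying=CostBandKeying(
            econ_raw.get("cost_band_keying", "residence")
        ),
    )

    env_raw = dict(config.get("environment", {}))
    _reject_unknown(env_raw, _ENV_KEYS, "environment")
    environment = EconomicEnvironment(
        monthly_wage=float(env_raw.get("monthly_wage_czk", 36144.0)),
        weekly_hours=float(env_raw.get("weekly_hours", 40.0)),
        weeks_per_month=float(env_raw.get("weeks_per_month", 4.348)),
        unemployment_rate=float(env_raw.get("unemployment_rate", 0.031)),
        base_fare=float(env_raw.get("base_fare_czk", 32.0)),
        czk_to_usd=float(env_raw.get("czk_to_usd", 0.048)),
    )

    utilities = {str(k): float(v) for k, v in _require(config, "utilities",
                                                       "document root").items()}

    costs_raw = _require(config, "costs", "document root")
    bands: dict[str, CostSchedule] = {}
    initial_costs: dict[str, float] = {}
    entry_defaults: dict[str, float] = {}
    entry_overrides: dict[tuple[str, str], float] = {}  # keyed by prosthesis
    for pros, spec in costs_raw.items():
        where = f"costs.{pros}"
        _reject_unknown(spec, _COST_KEYS, where)
        bands[pros] = _parse_bands(_require(spec, "annual_bands", where), where)
        init = _initial_cost(spec, where)
        if init is not None:
            initial_costs[pros] = init
        if "entry" in spec:
            for key, value in spec["entry"].items():
                if key == "default":
                    entry_defaults[pros] = float(value)
                elif key.startswith("from_"):
                    entry_overrides[(pros, key[len("from_"):])] = float(value)
                else:
                    raise ConfigError(
                        f"{where}.entry: keys must be 'default' or 'from_<prosthesis>'"
                    )
        elif init is not None:
            # entering a prosthesis state costs that prosthesis's initial cost
            entry_defaults[pros] = init

    survival_raw = _require(config, "survival", "document root")
    survival_models = {
        str(name): _parse_survival(spec, f"survival.{name}")
        for name, spec in survival_raw.items()
    }

    arms_raw = _require(config, "arms", "document root")
    comparison = dict(config.get("comparison", {}))
    _reject_unknown(comparison, {"evaluated", "comparator"}, "comparison")
    arm_names = list(arms_raw)
    if len(arm_names) != 2:
        raise ConfigError(f"exactly two arms required, found {len(arm_names)}")
    evaluated_name = str(comparison.get("evaluated", arm_names[0]))
    comparator_name = str(comparison.get("comparator", arm_names[1]))
    for name in (evaluated_name, comparator_name):
        if name not in arms_raw:
            raise ConfigError(f"comparison references unknown arm {name!r}")
    if evaluated_name == comparator_name:
        raise ConfigError("evaluated and comparator arms must differ")

    def build_arm(name: str) -> ArmModel:
        raw = arms_raw[name]
        where = f"arms.{name}"
        _reject_unknown(raw, _ARM_KEYS, where)
        states: dict[str, HealthState] = {}
        prosthesis_of: dict[str, str] = {}
        for sname, sraw in _require(raw, "states", where).items():
            _reject_unknown(sraw, _STATE_KEYS, f"{where}.states.{sname}")
            pros = str(_require(sraw, "prosthesis", f"{where}.states.{sname}"))
            if pros not in utilities:
                raise ConfigError(
                    f"{where}.states.{sname}: no utility declared for "
                    f"prosthesis {pros!r}"
                )
            if pros not in bands:
                raise ConfigError(
                    f"{where}.states.{sname}: no cost table for prosthesis {pros!r}"
                )
            absorbing = bool(sraw.get("absorbing", False))
            if not absorbing and pros not in survival_models:
                raise ConfigError(
                    f"{where}.states.{sname}: no survival model for "
                    f"prosthesis {pros!r}"
                )
            prosthesis_of[sname] = pros
            states[sname] = HealthState(
                name=sname,
                utility=utilities[pros],
                absorbing=absorbing,
                annual_cost_bands=bands[pros],
                survival_ref=None if absorbing else pros,
            )
        rules: dict[str, FailureRule] = {}
        for fname, dests in _require(raw, "rules", where).items():
            if fname not in states:
                raise ConfigError(
                    f"{where}.rules: rule for undeclared state {fname!r}"
                )
            rules[fname] = FailureRule(
                from_state=fname,
                destinations=tuple((str(t), float(p)) for t, p in dests.items()),
            )
        # expand prosthesis-keyed entry costs onto this arm's state names
        defaults = {
            sname: entry_defaults[prosthesis_of[sname]]
            for sname in states if prosthesis_of[sname] in entry_defaults
        }
        overrides = {
            (to, frm): cost
            for (to_pros, frm_pros), cost in entry_overrides.items()
            for to in states if prosthesis_of[to] == to_pros
            for frm in states if prosthesis_of[frm] == frm_pros
        }
        initial_state = str(_require(raw, "initial_state", where))
        if initial_state not in prosthesis_of:
            raise ConfigError(
                f"{where}: initial state {initial_state!r} is not a declared state"
            )
        if states[initial_state].absorbing:
            raise ConfigError(
                f"{where}: initial state {initial_state!r} must be non-absorbing"
            )
        init_pros = prosthesis_of[initial_state]
        if init_pros not in initial_costs:
            raise ConfigError(
                f"{where}: prosthesis {init_pros!r} of the initial state has "
                "no initial cost"
            )
        return ArmModel(
            name=name,
            initial_state=initial_state,
            states=states,
            rules=rules,
            entry_costs=EntryCostTable(defaults=defaults, overrides=overrides),
            initial_cost=initial_costs[init_pros],
        )

    return DecisionModel(
        evaluated=build_arm(evaluated_name),
        comparator=build_arm(comparator_name),
        econ=econ,
        environment=environment,
        survival_models=survival_models,
        config=copy.deepcopy(dict(config)),
    )


def load_config(path: str | Path) -> DecisionModel:
    """Read and validate a YAML model configuration."""
    text = Path(path).read_text()
    raw = yaml.safe_load(text)
    return build_model(raw)


def serialize(model: DecisionModel) -> str:
    """YAML text that parses back (via load) to an equal model."""
    return yaml.safe_dump(dict(model.config), sort_keys=True)


def reference_config_dict() -> dict[str, Any]:
    """The packaged base-case configuration as a plain mapping."""
    ref = importlib.resources.files("dentalcua.data") / "reference_config.yaml"
    return yaml.safe_load(ref.read_text())


def make_reference_config() -> DecisionModel:
    """The base-case parameterization of the published comparison."""
    return build_model(reference_config_dict())


def materialize_initial_costs(config: Mapping[str, Any]) -> dict[str, Any]:
    """Replace 'mean' initial costs with their computed numeric values.

    Useful before sensitivity analysis, whose parameter paths must point at
    numeric leaves (e.g. ``costs.FDP.initial``).
    """
    out = copy.deepcopy(dict(config))
    for pros, spec in out.get("costs", {}).items():
        if spec.get("initial") == "mean":
            spec["initial"] = _initial_cost(spec, f"costs.{pros}")
    return out
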