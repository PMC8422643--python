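"""Deterministic sensitivity analysis over configuration parameters.

All analyses here perturb numeric leaves of the configuration document by
dotted path (e.g. ``costs.FDP.initial`` or ``utilities.ISC``), rebuild the
model and re-run the full cost-utility comparison. One-way sweeps vary one
parameter over a relative interval (±30% by default, 13 grid points so the
base case sits on the grid); the tornado evaluates every parameter at the
interval ends and orders them by the swing they induce in the incremental
cost-utility ratio; the threshold search bisects on the dominance-determining
quantity to locate break-even parameter values; scenario and horizon sweeps
re-run the comparison under alternative discount rates and time horizons.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass
from numbers import Number
from typing import Any, Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .economics import CEAResult
from .model_config import ConfigError, materialize_initial_costs
from .pipeline import evaluate_config

__all__ = [
    "ParamRef",
    "TornadoEntry",
    "make_param_ref",
    "numeric_leaf_paths",
    "one_way_sweep",
    "tornado",
    "threshold_search",
    "scenario_discounts",
    "horizon_sweep",
    "sweep_frame",
    "tornado_frame",
    "scenario_frame",
]


@dataclass(frozen=True)
class ParamRef:
    """A dotted path to one numeric leaf of the configuration document."""

    path: str
    base_value: float


@dataclass(frozen=True)
class TornadoEntry:
    param: ParamRef
    value_low: float
    value_high: float
    icur_low: float
    icur_high: float

    @property
    def span(self) -> float:
        return abs(self.icur_high - self.icur_low)


def _walk(config: Mapping[str, Any], path: str) -> tuple[Any, str]:
    parts = path.split(".")
    node: Any = config
    for key in parts[:-1]:
        if isinstance(node, Mapping) and key in node:
            node = node[key]
        elif isinstance(node, list) and key.lstrip("-").isdigit():
            node = node[int(key)]
        else:
            raise ConfigError(f"parameter path {path!r}: segment {key!r} not found")
    return node, parts[-1]


def get_param(config: Mapping[str, Any], path: str) -> float:
    node, leaf = _walk(config, path)
    try:
        value = node[int(leaf)] if isinstance(node, list) else node[leaf]
    except (KeyError, IndexError, ValueError):
        raise ConfigError(f"parameter path {path!r}: leaf {leaf!r} not found")
    if isinstance(value, bool) or not isinstance(value, Number):
        raise ConfigError(
            f"parameter path {path!r} does not resolve to a numeric leaf "
            f"(found {type(value).__name__})"
        )
    return float(value)


def set_param(config: dict[str, Any], path: str, value: float) -> None:
    node, leaf = _walk(config, path)
    if isinstance(node, list):
        node[int(leaf)] = value
    else:
        if leaf not in node:
            raise ConfigError(f"parameter path {path!r}: leaf {leaf!r} not found")
        node[leaf] = value


def make_param_ref(config: Mapping[str, Any], path: str) -> ParamRef:
    return ParamRef(path=path, base_value=get_param(config, path))


def numeric_leaf_paths(config: Mapping[str, Any], prefix: str = "") -> list[str]:
    """All dotted paths in the document that point at numeric leaves."""
    paths: list[str] = []
    if isinstance(config, Mapping):
        items: Iterable[tuple[str, Any]] = ((str(k), v) for k, v in config.items())
    elif isinstance(config, list):
        items = ((str(i), v) for i, v in enumerate(config))
    else:
        return paths
    for key, value in items:
        dotted = f"{prefix}{key}"
        if isinstance(value, bool):
            continue
        if isinstance(value, Number):
            paths.append(dotted)
        elif isinstance(value, (Mapping, list)):
            paths.extend(numeric_leaf_paths(value, prefix=f"{dotted}."))
    return paths


def _evaluate_at(config: Mapping[str, Any], path: str, value: float) -> CEAResult:
    perturbed = copy.deepcopy(dict(config))
    set_param(perturbed, path, value)
    return evaluate_config(perturbed)


def _prepared(config: Mapping[str, Any]) -> dict[str, Any]:
    return materialize_initial_costs(config)


def one_way_sweep(config: Mapping[str, Any], param: ParamRef | str,
                  rel_low: float = -0.30, rel_high: float = 0.30,
                  n_points: int = 13) -> list[tuple[float, CEAResult]]:
    """Re-evaluate the comparison over an evenly spaced multiplier grid.

    Values are ``base × m`` for multipliers m from 1+rel_low to 1+rel_high;
    with the default 13 points over ±30% the base case lies on the grid.
    """
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    cfg = _prepared(config)
    ref = param if isinstance(param, ParamRef) else make_param_ref(cfg, param)
    if n_points == 1:
        multipliers = np.array([1.0 + rel_low])
    else:
        multipliers = np.linspace(1.0 + rel_low, 1.0 + rel_high, n_points)
    out = []
    for m in multipliers:
        value = ref.base_value * float(m)
        out.append((value, _evaluate_at(cfg, ref.path, value)))
    return out


def tornado(config: Mapping[str, Any], params: Sequence[ParamRef | str],
            rel: float = 0.30) -> list[TornadoEntry]:
    """Evaluate each parameter at ±rel and sort by descending ICUR span."""
    if not params:
        raise ValueError("tornado needs at least one parameter")
    cfg = _prepared(config)
    entries = []
    for p in params:
        ref = p if isinstance(p, ParamRef) else make_param_ref(cfg, p)
        lo_val = ref.base_value * (1.0 - rel)
        hi_val = ref.base_value * (1.0 + rel)
        lo = _evaluate_at(cfg, ref.path, lo_val)
        hi = _evaluate_at(cfg, ref.path, hi_val)
        entries.append(TornadoEntry(
            param=ref, value_low=lo_val, value_high=hi_val,
            icur_low=lo.icur if lo.icur is not None else math.nan,
            icur_high=hi.icur if hi.icur is not None else math.nan,
        ))
    return sorted(entries, key=lambda e: -e.span)


def _dominance_margin(result: CEAResult) -> float:
    """Signed distance to the dominance boundary.

    Positive iff the evaluated arm dominates (cheaper and at least as
    effective); crosses zero where either the incremental cost or the
    incremental outcome changes sign, which is exactly where the verdict (and
    the sign of the ICUR) flips.
    """
    return min(-result.incremental_cost, result.incremental_utility)


def threshold_search(config: Mapping[str, Any], param: ParamRef | str,
                     bracket: tuple[float, float], tol: float = 1e-6,
                     ) -> Optional[float]:
    """Bisection for the parameter value where the dominance verdict flips.

    Returns None when the verdict is the same at both bracket ends; otherwise
    the crossing located to within ``tol`` (on the parameter axis).
    """
    if tol <= 0:
        raise ValueError("tolerance must be positive")
    lo, hi = bracket
    if not lo < hi:
        raise ValueError("bracket must satisfy low < high")
    cfg = _prepared(config)
    ref = param if isinstance(param, ParamRef) else make_param_ref(cfg, param)

    def margin(v: float) -> float:
        return _dominance_margin(_evaluate_at(cfg, ref.path, v))

    m_lo, m_hi = margin(lo), margin(hi)
    if m_lo == 0.0:
        return lo
    if m_hi == 0.0:
        return hi
    if (m_lo > 0) == (m_hi > 0):
        return None
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        m_mid = margin(mid)
        if m_mid == 0.0:
            return mid
        if (m_mid > 0) == (m_lo > 0):
            lo, m_lo = mid, m_mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def scenario_discounts(config: Mapping[str, Any],
                       rates: Sequence[float] = (0.0, 0.03, 0.05),
                       ) -> dict[float, CEAResult]:
    """Full comparison at each discount rate, everything else fixed."""
    cfg = _prepared(config)
    out = {}
    for rate in rates:
        if rate < 0:
            raise ValueError("discount rates must be >= 0")
        scenario = copy.deepcopy(cfg)
        scenario.setdefault("economics", {})["discount_rate"] = float(rate)
        out[float(rate)] = evaluate_config(scenario)
    return out


def horizon_sweep(config: Mapping[str, Any],
                  horizons: Sequence[int] = tuple(range(5, 56, 5)),
                  ) -> dict[int, CEAResult]:
    """Full comparison at each time horizon, everything else fixed."""
    cfg = _prepared(config)
    out = {}
    for horizon in horizons:
        if horizon < 1:
            raise ValueError("horizons must be >= 1")
        scenario = copy.deepcopy(cfg)
        scenario.setdefault("economics", {})["horizon_years"] = int(horizon)
        out[int(horizon)] = evaluate_config(scenario)
    return out


# --------------------------------------------------------------------------
# tabular views

def _cea_row(result: CEAResult) -> dict[str, Any]:
    return {
        "evaluated_cost_czk": result.evaluated_cost,
        "comparator_cost_czk": result.comparator_cost,
        "evaluated_outcome_qapy": result.evaluated_utility,
        "comparator_outcome_qapy": result.comparator_utility,
        "incremental_cost_czk": result.incremental_cost,
        "incremental_outcome_qapy": result.incremental_utility,
        "icur_czk_per_qapy": result.icur,
        "dominance": result.dominance.value,
        "plane_quadrant": result.plane_quadrant.value,
    }


def sweep_frame(series: Sequence[tuple[float, CEAResult]],
                param_path: str) -> pd.DataFrame:
    rows = [{"parameter": param_path, "value": v, **_cea_row(r)}
            for v, r in series]
    return pd.DataFrame(rows)


def tornado_frame(entries: Sequence[TornadoEntry]) -> pd.DataFrame:
    rows = [{
        "parameter": e.param.path,
        "base_value": e.param.base_value,
        "value_low": e.value_low,
        "value_high": e.value_high,
        "icur_low_czk_per_qapy": e.icur_low,
        "icur_high_czk_per_qapy": e.icur_high,
        "span_czk_per_qapy": e.span,
    } for e in entries]
    return pd.DataFrame(rows)


def scenario_frame(results: Mapping[Any, CEAResult], key_name: str) -> pd.DataFrame:
    rows = [{key_name: k, **_cea_row(r)} for k, r in results.items()]
    return pd.DataFrame(rows)
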