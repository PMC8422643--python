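"""Tunnel-state Markov cohort engine with residence-age-dependent failure.

The cohort is tracked as fractions over (state, residence age) strata so
that the per-cycle failure probability of a prosthesis depends on how long
*that* prosthesis has been in place, not on model time (the classic tunnel
-state construction). Tunnel depth equals the horizon, which is exact and
cheap at yearly cycles. Each cycle accrues discounted annual costs (banded
by prosthesis age, resetting on replacement) and discounted utility; a
replacement's entry cost and first annual-band cost are charged in its entry
cycle. The cohort is deterministic — no Monte Carlo, no randomness.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .model_config import (ArmModel, CostBandKeying, DiscountConvention,
                           EconSettings)
from .survival import SurvivalModel, conditional_failure_prob

__all__ = [
    "CohortTrace",
    "ArmResult",
    "discount_factor",
    "run_cohort",
    "in_place_survival",
    "trace_frame",
]

Stratum = tuple[str, int]  # (state name, residence age in years, >= 1)


@dataclass(frozen=True)
class CohortTrace:
    """Per-cycle occupancy fractions resolved by (state, residence age).

    ``occupancy[t]`` is the composition at the start of cycle t+1 (index 0 is
    the initial cohort; index ``horizon`` is the composition after the final
    cycle).
    """

    occupancy: tuple[Mapping[Stratum, float], ...]
    state_names: tuple[str, ...]

    def per_state_totals(self) -> pd.DataFrame:
        """cycle × state table of occupancy fractions."""
        rows = []
        for occ in self.occupancy:
            row = {s: 0.0 for s in self.state_names}
            for (state, _age), frac in occ.items():
                row[state] += frac
            rows.append(row)
        df = pd.DataFrame(rows)
        df.index.name = "cycle"
        return df

    def state_total(self, cycle: int, state: str) -> float:
        return sum(f for (s, _a), f in self.occupancy[cycle].items() if s == state)


@dataclass(frozen=True)
class ArmResult:
    """Discounted per-cycle and cumulative costs (CZK) and utilities (QAPY)."""

    arm_name: str
    trace: CohortTrace
    cost_per_cycle: np.ndarray      # index 0..horizon; [0] holds initial cost
    utility_per_cycle: np.ndarray
    econ: EconSettings
    absorbing_states: tuple[str, ...] = ()

    @property
    def cumulative_cost_series(self) -> np.ndarray:
        return np.cumsum(self.cost_per_cycle)

    @property
    def cumulative_utility_series(self) -> np.ndarray:
        return np.cumsum(self.utility_per_cycle)

    @property
    def cumulative_cost(self) -> float:
        return float(self.cost_per_cycle.sum())

    @property
    def cumulative_utility(self) -> float:
        return float(self.utility_per_cycle.sum())


def discount_factor(cycle: int, rate: float,
                    convention: DiscountConvention = DiscountConvention.FROM_CYCLE_1,
                    ) -> float:
    """Discount factor applied to rewards accrued during a given cycle.

    Cycle numbering is 1-based; cycle 0 is only meaningful under the
    convention that grants an undiscounted cycle-0 state reward.
    """
    if cycle < 0:
        raise ValueError(f"cycle must be >= 0, got {cycle}")
    convention = DiscountConvention(convention)
    if cycle == 0:
        if convention is DiscountConvention.CYCLE0_REWARD_PLUS_FROM_CYCLE_1:
            return 1.0
        raise ValueError("cycle 0 is only defined under the cycle-0 reward convention")
    if convention is DiscountConvention.FROM_CYCLE_0:
        return float((1.0 + rate) ** (-cycle))
    # FROM_CYCLE_1 and the cycle-0-reward variant: first year undiscounted
    return float((1.0 + rate) ** (-(cycle - 1)))


def _band_year(age: int, cycle: int, keying: CostBandKeying) -> int:
    return age if keying is CostBandKeying.RESIDENCE else cycle


def run_cohort(arm: ArmModel, survivals: Mapping[str, SurvivalModel],
               econ: EconSettings) -> ArmResult:
    """Simulate the full-horizon cohort for one treatment arm.

    Each cycle, every non-absorbing (state, age) stratum fails with the
    survival model's conditional failure probability at that age and is
    redistributed according to the arm's failure rules (entering replacements
    at residence age 1); survivors advance one year of residence. Absorbing
    fractions stay put. Accrual per cycle: occupancy × utility/scale ×
    discount and occupancy × banded annual cost × discount; entry costs are
    charged, discounted, in the cycle a fraction first occupies its new state.
    """
    if econ.horizon < 1:
        raise ValueError("horizon must be at least one cycle")
    for state in arm.states.values():
        if not state.absorbing and state.survival_ref not in survivals:
            raise ValueError(
                f"no survival model supplied for state {state.name!r} "
                f"(reference {state.survival_ref!r})"
            )

    horizon = econ.horizon
    # pre-compute conditional failure probabilities per state and age
    fail_p: dict[str, np.ndarray] = {}
    for state in arm.states.values():
        if state.absorbing:
            continue
        model = survivals[state.survival_ref]
        fail_p[state.name] = np.array(
            [conditional_failure_prob(model, a) for a in range(1, horizon + 1)]
        )

    occ: dict[Stratum, float] = {(arm.initial_state, 1): 1.0}
    trace: list[dict[Stratum, float]] = [dict(occ)]
    cost = np.zeros(horizon + 1)
    utility = np.zeros(horizon + 1)
    cost[0] = arm.initial_cost

    def state_reward(stratum_occ: Mapping[Stratum, float], cycle: int,
                     ) -> tuple[float, float]:
        """(cost, utility) accrued by one cycle's occupancy, undiscounted."""
        c = u = 0.0
        for (sname, age), frac in stratum_occ.items():
            if frac == 0.0:
                continue
            state = arm.states[sname]
            year = _band_year(age, cycle, econ.cost_band_keying)
            c += frac * state.annual_cost_bands.annual_cost(year)
            u += frac * state.utility / econ.utility_scale
        return c, u

    if econ.discount_convention is DiscountConvention.CYCLE0_REWARD_PLUS_FROM_CYCLE_1:
        c0, u0 = state_reward(occ, 1)
        cost[0] += c0 * discount_factor(0, econ.discount_rate,
                                        econ.discount_convention)
        utility[0] += u0 * discount_factor(0, econ.discount_rate,
                                           econ.discount_convention)

    for t in range(1, horizon + 1):
        df_t = discount_factor(t, econ.discount_rate, econ.discount_convention)

        # resolve failures at the end of the cycle
        nxt: dict[Stratum, float] = {}
        entry_cost_next = 0.0  # entrants are charged in their entry cycle t+1
        for (sname, age), frac in occ.items():
            state = arm.states[sname]
            if state.absorbing:
                nxt[(sname, age + 1)] = nxt.get((sname, age + 1), 0.0) + frac
                continue
            q = fail_p[sname][age - 1]
            failing = frac * q
            surviving = frac - failing
            if surviving > 0.0:
                key = (sname, age + 1)
                nxt[key] = nxt.get(key, 0.0) + surviving
            if failing > 0.0:
                for to, p in arm.rules[sname].destinations:
                    if p == 0.0:
                        continue
                    key = (to, 1)
                    nxt[key] = nxt.get(key, 0.0) + failing * p
                    entry_cost_next += failing * p * arm.entry_costs.cost(to, sname)

        # accrue this cycle's state rewards
        if econ.half_cycle_correction:
            keys = set(occ) | set(nxt)
            avg = {k: 0.5 * (occ.get(k, 0.0) + nxt.get(k, 0.0)) for k in keys}
            c_t, u_t = state_reward(avg, t)
        else:
            c_t, u_t = state_reward(occ, t)
        cost[t] += c_t * df_t
        utility[t] += u_t * df_t

        # entry costs belong to the entrants' first cycle in place
        if t < horizon and entry_cost_next > 0.0:
            cost[t + 1] += entry_cost_next * discount_factor(
                t + 1, econ.discount_rate, econ.discount_convention
            )

        occ = nxt
        trace.append(dict(occ))

    return ArmResult(
        arm_name=arm.name,
        trace=CohortTrace(occupancy=tuple(trace),
                          state_names=tuple(arm.states)),
        cost_per_cycle=cost,
        utility_per_cycle=utility,
        econ=econ,
        absorbing_states=tuple(s.name for s in arm.states.values() if s.absorbing),
    )


def in_place_survival(result: ArmResult) -> np.ndarray:
    """Per-cycle fraction of the cohort with a prosthesis in place.

    The complement of occupancy of the absorbing missing-tooth state; index 0
    is the initial cohort (1.0 by construction).
    """
    absorbing = set(result.absorbing_states)
    series = np.zeros(len(result.trace.occupancy))
    for i, occ in enumerate(result.trace.occupancy):
        series[i] = sum(frac for (sname, _a), frac in occ.items()
                        if sname not in absorbing)
    return series


def trace_frame(result: ArmResult) -> pd.DataFrame:
    """Long-format cohort trace: cycle, state, residence_age, fraction."""
    rows = []
    for cycle, occ in enumerate(result.trace.occupancy):
        for (state, age), frac in sorted(occ.items()):
            rows.append((cycle, state, age, frac))
    return pd.DataFrame(rows, columns=["cycle", "state", "residence_age",
                                       "fraction"])
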