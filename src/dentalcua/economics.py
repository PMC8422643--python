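"""Cost formulas and the two-arm cost-utility comparison.

Indirect costs follow the lost-earnings approach: the value of a patient's
time at the clinic is (1 − unemployment rate) × average hourly earnings ×
hours, with hourly earnings derived from the gross monthly wage, statutory
weekly hours and the mean number of weeks per month; transport is a return
journey at the basic public-transport fare per visit. The comparison itself
reports per-arm cost-effectiveness ratios (CZK per quality-adjusted
prosthesis year), the incremental cost and outcome, the incremental
cost-utility ratio ΔC/ΔE, and a dominance verdict located on the
cost-utility plane.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Optional

import pandas as pd

from .markov import ArmResult

__all__ = [
    "Dominance",
    "Quadrant",
    "CEAResult",
    "hourly_earnings",
    "patient_time_cost",
    "transport_cost",
    "mean_initial_cost",
    "dib_cost_rule",
    "cea_summary",
    "cea_from_totals",
    "cea_report_frame",
]


class Dominance(str, Enum):
    EVALUATED_DOMINANT = "evaluated_dominant"
    COMPARATOR_DOMINANT = "comparator_dominant"
    TRADEOFF_NE = "tradeoff_ne"    # dearer and more effective
    TRADEOFF_SW = "tradeoff_sw"    # cheaper and less effective
    INDIFFERENT = "indifferent"


class Quadrant(str, Enum):
    """Location of (Δeffect, Δcost) on the cost-utility plane."""

    NE = "ne"
    SE = "se"    # more effect, less cost: clearly cost-effective
    SW = "sw"
    NW = "nw"
    ORIGIN = "origin"
    AXIS = "axis"


@dataclass(frozen=True)
class CEAResult:
    evaluated_name: str
    comparator_name: str
    evaluated_cost: float
    comparator_cost: float
    evaluated_utility: float
    comparator_utility: float
    evaluated_ce: Optional[float]
    comparator_ce: Optional[float]
    incremental_cost: float
    incremental_utility: float
    icur: Optional[float]          # undefined when ΔE == 0
    dominance: Dominance
    plane_quadrant: Quadrant


def hourly_earnings(monthly_wage: float, weekly_hours: float,
                    weeks_per_month: float) -> float:
    """Average hourly earnings: monthly wage / (weekly hours × weeks/month).

    A zero wage is allowed (yields zero earnings); the divisor inputs must be
    strictly positive.
    """
    if monthly_wage < 0:
        raise ValueError("monthly wage must be >= 0")
    if weekly_hours <= 0 or weeks_per_month <= 0:
        raise ValueError("weekly hours and weeks per month must be positive")
    return monthly_wage / (weekly_hours * weeks_per_month)


def patient_time_cost(hours: float, hourly: float, unemployment: float) -> float:
    """Value of the patient's time at the clinic (lost earnings).

    (1 − unemployment rate) × hourly earnings × hours.
    """
    if hours < 0:
        raise ValueError("hours must be >= 0")
    if not 0.0 <= unemployment <= 1.0:
        raise ValueError("unemployment rate must lie in [0, 1]")
    return (1.0 - unemployment) * hourly * hours


def transport_cost(base_fare: float, visits: int) -> float:
    """Transport cost: a return journey at the base fare per clinic visit."""
    if visits < 0:
        raise ValueError("visit count must be >= 0")
    if base_fare < 0:
        raise ValueError("base fare must be >= 0")
    return 2.0 * base_fare * visits


def mean_initial_cost(variant_costs) -> float:
    """Arithmetic mean of the treatment-variant initial costs."""
    costs = list(variant_costs)
    if not costs:
        raise ValueError("at least one variant cost required")
    if any(c < 0 for c in costs):
        raise ValueError("variant costs must be >= 0")
    return sum(costs) / len(costs)


def dib_cost_rule(fdp_variant_a: float, isc_variant_b: float) -> float:
    """Composite cost of the double implant-supported bridge.

    One third of the bridge cost (variant A) plus twice the single-crown cost
    (variant B).
    """
    if fdp_variant_a < 0 or isc_variant_b < 0:
        raise ValueError("costs must be >= 0")
    return fdp_variant_a / 3.0 + 2.0 * isc_variant_b


def _classify(d_cost: float, d_util: float) -> tuple[Dominance, Quadrant]:
    if d_cost == 0.0 and d_util == 0.0:
        return Dominance.INDIFFERENT, Quadrant.ORIGIN
    if d_util > 0 and d_cost < 0:
        quadrant = Quadrant.SE
    elif d_util > 0 and d_cost > 0:
        quadrant = Quadrant.NE
    elif d_util < 0 and d_cost > 0:
        quadrant = Quadrant.NW
    elif d_util < 0 and d_cost < 0:
        quadrant = Quadrant.SW
    else:
        quadrant = Quadrant.AXIS
    if d_cost <= 0 and d_util >= 0:
        return Dominance.EVALUATED_DOMINANT, quadrant
    if d_cost >= 0 and d_util <= 0:
        return Dominance.COMPARATOR_DOMINANT, quadrant
    if d_cost > 0:  # and d_util > 0
        return Dominance.TRADEOFF_NE, quadrant
    return Dominance.TRADEOFF_SW, quadrant


def cea_from_totals(evaluated_cost: float, evaluated_utility: float,
                    comparator_cost: float, comparator_utility: float,
                    evaluated_name: str = "evaluated",
                    comparator_name: str = "comparator") -> CEAResult:
    """Cost-utility comparison from cumulative totals.

    Increments are evaluated − comparator; the incremental cost-utility
    ratio is reported as undefined (None) when the incremental outcome is
    zero, and the verdict then rests on cost alone.
    """
    d_cost = evaluated_cost - comparator_cost
    d_util = evaluated_utility - comparator_utility
    icur = d_cost / d_util if d_util != 0.0 else None
    dominance, quadrant = _classify(d_cost, d_util)

    def ce(cost: float, util: float) -> Optional[float]:
        if util == 0.0:
            return None
        return cost / util

    return CEAResult(
        evaluated_name=evaluated_name,
        comparator_name=comparator_name,
        evaluated_cost=evaluated_cost,
        comparator_cost=comparator_cost,
        evaluated_utility=evaluated_utility,
        comparator_utility=comparator_utility,
        evaluated_ce=ce(evaluated_cost, evaluated_utility),
        comparator_ce=ce(comparator_cost, comparator_utility),
        incremental_cost=d_cost,
        incremental_utility=d_util,
        icur=icur,
        dominance=dominance,
        plane_quadrant=quadrant,
    )


def cea_summary(evaluated: ArmResult, comparator: ArmResult) -> CEAResult:
    """Compare two simulated arms computed under identical settings."""
    if evaluated.econ != comparator.econ:
        raise ValueError("arms must be simulated under identical settings")
    return cea_from_totals(
        evaluated.cumulative_cost, evaluated.cumulative_utility,
        comparator.cumulative_cost, comparator.cumulative_utility,
        evaluated_name=evaluated.arm_name, comparator_name=comparator.arm_name,
    )


def cea_report_frame(result: CEAResult, czk_to_usd: float) -> pd.DataFrame:
    """Tabular report with CZK and display-USD columns."""
    def usd(x: Optional[float]) -> Optional[float]:
        return None if x is None else x * czk_to_usd

    rows = [
        {"intervention": result.evaluated_name,
         "cost_czk": result.evaluated_cost,
         "cost_usd": usd(result.evaluated_cost),
         "outcome_qapy": result.evaluated_utility,
         "ce_czk_per_qapy": result.evaluated_ce,
         "ce_usd_per_qapy": usd(result.evaluated_ce),
         "incremental_cost_czk": 0.0,
         "incremental_outcome_qapy": 0.0,
         "icur_czk_per_qapy": None,
         "icur_usd_per_qapy": None},
        {"intervention": result.comparator_name,
         "cost_czk": result.comparator_cost,
         "cost_usd": usd(result.comparator_cost),
         "outcome_qapy": result.comparator_utility,
         "ce_czk_per_qapy": result.comparator_ce,
         "ce_usd_per_qapy": usd(result.comparator_ce),
         "incremental_cost_czk": result.incremental_cost,
         "incremental_outcome_qapy": result.incremental_utility,
         "icur_czk_per_qapy": result.icur,
         "icur_usd_per_qapy": usd(result.icur)},
    ]
    df = pd.DataFrame(rows)
    df.attrs["dominance"] = result.dominance.value
    df.attrs["plane_quadrant"] = result.plane_quadrant.value
    return df
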