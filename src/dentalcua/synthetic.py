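"""Seed-deterministic synthetic inputs for the whole pipeline.

Emulates the statistical structure the survival workflow assumes: event
times drawn from a parametric family (Weibull by default), independent
exponential censoring whose rate is solved numerically so the expected
censored fraction matches a requested rate, plus administrative censoring at
the end of follow-up. Also provides a two-state constant-hazard toy decision
model whose occupancy, costs and utilities have closed forms (the engine's
oracle), and a fixture bundle writer that regenerates every file the
pipeline consumes from a single seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from scipy import integrate, optimize

from .model_config import (ArmModel, CostSchedule, DecisionModel, EntryCostTable,
                           FailureRule, HealthState, reference_config_dict)
from .survival import Family, SurvivalModel, _scipy_dist

__all__ = [
    "SimSpec",
    "simulate_survival_data",
    "make_toy_geometric_model",
    "reference_fixture_bundle",
    "censoring_rate_for",
]


@dataclass(frozen=True)
class SimSpec:
    """Specification of one simulated prosthesis-survival dataset."""

    n: int
    model: SurvivalModel
    censor_rate: float = 0.0
    max_followup: float = math.inf
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not 0.0 <= self.censor_rate < 1.0:
            raise ValueError("censor_rate must lie in [0, 1)")
        if self.max_followup <= 0:
            raise ValueError("max_followup must be positive")


def censoring_rate_for(model: SurvivalModel, censor_rate: float) -> float:
    """Exponential censoring rate c with P(C < T) = censor_rate, C ~ Exp(c).

    P(C < T) = 1 − E[exp(−cT)], solved by bracketed root finding with the
    Laplace transform of the event distribution evaluated by quadrature.
    """
    if censor_rate == 0.0:
        return 0.0
    dist = _scipy_dist(model)

    def censored_fraction(c: float) -> float:
        laplace, _err = integrate.quad(
            lambda t: math.exp(-c * t) * dist.pdf(t), 0, math.inf, limit=200
        )
        return 1.0 - laplace

    lo, hi = 1e-12, 1.0
    while censored_fraction(hi) < censor_rate:
        hi *= 10.0
        if hi > 1e9:  # pragma: no cover
            raise RuntimeError("failed to bracket the censoring rate")
    return float(optimize.brentq(
        lambda c: censored_fraction(c) - censor_rate, lo, hi, xtol=1e-12
    ))


def simulate_survival_data(spec: SimSpec) -> tuple[np.ndarray, np.ndarray]:
    """Draw (event_times, event_observed) under the spec's censoring scheme.

    Identical specs (including seed) return identical arrays.
    """
    rng = np.random.default_rng(spec.seed)
    dist = _scipy_dist(spec.model)
    event = dist.rvs(size=spec.n, random_state=rng)
    if spec.censor_rate > 0.0:
        rate = censoring_rate_for(spec.model, spec.censor_rate)
        censor = rng.exponential(1.0 / rate, size=spec.n)
    else:
        censor = np.full(spec.n, math.inf)
    censor = np.minimum(censor, spec.max_followup)
    observed = event <= censor
    times = np.minimum(event, censor)
    return times, observed


def make_toy_geometric_model(p: float, utility: float = 100.0,
                             annual_cost: float = 0.0,
                             initial_cost: float = 0.0,
                             entry_cost: float = 0.0,
                             mt_annual_cost: float = 0.0,
                             ) -> tuple[ArmModel, Mapping[str, SurvivalModel]]:
    """Two-state constant-hazard arm (prosthesis → missing tooth).

    The exponential rate is −ln(1−p), so the per-cycle conditional failure
    probability is exactly ``p`` at every residence age. Occupancy of the
    prosthesis state after t cycles is (1−p)^t; with discounting, cumulative
    cost and utility are geometric partial sums — the closed-form oracle for
    the cohort engine.
    """
    if not 0.0 < p < 1.0:
        raise ValueError("p must lie strictly between 0 and 1")
    flat = lambda c: CostSchedule(bands=((1, None, c),))
    states = {
        "ALIVE": HealthState(name="ALIVE", utility=utility, absorbing=False,
                             annual_cost_bands=flat(annual_cost),
                             survival_ref="toy"),
        "MT": HealthState(name="MT", utility=0.0, absorbing=True,
                          annual_cost_bands=flat(mt_annual_cost)),
    }
    arm = ArmModel(
        name="toy",
        initial_state="ALIVE",
        states=states,
        rules={"ALIVE": FailureRule("ALIVE", (("MT", 1.0),))},
        entry_costs=EntryCostTable(defaults={"MT": entry_cost}),
        initial_cost=initial_cost,
    )
    survivals = {"toy": SurvivalModel(Family.EXPONENTIAL,
                                      {"rate": -math.log1p(-p)})}
    return arm, survivals


def reference_fixture_bundle(seed: int, dest: str | Path,
                         n: int = 500, censor_rate: float = 0.2,
                         max_followup: float = 40.0) -> Path:
    """Write a fully regenerable fixture directory.

    Contents: the reference configuration, one simulated Kaplan–Meier-style
    dataset per prosthesis type (drawn from the calibrated survival
    parameters), and a JSON stub of the generating parameters. Two bundles
    written from the same seed are byte-identical.
    """
    dest = Path(dest)
    dest.mkdir(parents=True, exist_ok=True)
    config = reference_config_dict()
    (dest / "reference_config.yaml").write_text(
        yaml.safe_dump(config, sort_keys=True)
    )

    children = np.random.SeedSequence(seed).spawn(len(config["survival"]))
    stub: dict[str, dict] = {"seed": seed, "n": n, "censor_rate": censor_rate,
                             "max_followup": max_followup, "prostheses": {}}
    for child, (name, surv) in zip(children, sorted(config["survival"].items())):
        params = {k: float(v) for k, v in surv.items()
                  if k not in ("family", "note")}
        model = SurvivalModel(Family(surv["family"]), params)
        spec = SimSpec(n=n, model=model, censor_rate=censor_rate,
                       max_followup=max_followup,
                       seed=int(child.generate_state(1)[0] % (2**31)))
        times, observed = simulate_survival_data(spec)
        df = pd.DataFrame({
            "time_years": times,
            "event_observed": observed.astype(int),
        })
        df.to_csv(dest / f"survival_times_{name}.csv", index=False,
                  float_format="%.6f")
        stub["prostheses"][name] = {"family": surv["family"], **params,
                                    "sim_seed": spec.seed}
    (dest / "generating_parameters.json").write_text(
        json.dumps(stub, indent=2, sort_keys=True) + "\n"
    )
    return dest
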