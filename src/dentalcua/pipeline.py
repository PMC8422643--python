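"""Thin driver: run both arms of a decision model and compare them."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Mapping

from .economics import CEAResult, cea_summary
from .markov import ArmResult, run_cohort
from .model_config import DecisionModel, build_model

__all__ = ["CUAOutcome", "run_cua", "evaluate_config"]


@dataclass(frozen=True)
class CUAOutcome:
    evaluated: ArmResult
    comparator: ArmResult
    cea: CEAResult


def run_cua(model: DecisionModel) -> CUAOutcome:
    """Simulate both arms under the model's settings and compare them."""
    evaluated = run_cohort(model.evaluated, model.survival_models, model.econ)
    comparator = run_cohort(model.comparator, model.survival_models, model.econ)
    return CUAOutcome(evaluated=evaluated, comparator=comparator,
                      cea=cea_summary(evaluated, comparator))


def evaluate_config(config: Mapping[str, Any]) -> CEAResult:
    """Build, run and compare a configuration mapping in one call."""
    return run_cua(build_model(config)).cea
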