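"""Survival estimation and per-cycle failure probabilities.

Prosthesis longevity enters the decision model as a parametric survival
function S(t). Published curves are available only as digitized
Kaplan–Meier points, so the workflow is: estimate (or read) a product-limit
curve, reconstruct pseudo-individual event data from its steps, fit
candidate parametric families by maximum likelihood, select the family with
the highest log-likelihood, and convert the fitted S(t) into the per-cycle
conditional failure probability 1 − S(t)/S(t−1) that drives the Markov
engine. Extrapolation beyond the last observed point uses the parametric
curve, which is what makes 30-year horizons possible from shorter follow-up.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Family",
    "SurvivalModel",
    "KMCurve",
    "FitError",
    "km_estimator",
    "fit_parametric",
    "select_distribution",
    "survival_at",
    "conditional_failure_prob",
    "read_km_csv",
    "failure_probability_table",
]


class FitError(RuntimeError):
    """Parametric fitting failed (degenerate input or non-convergence)."""


class Family(str, Enum):
    EXPONENTIAL = "exponential"
    WEIBULL = "weibull"
    LOGNORMAL = "lognormal"
    LOGLOGISTIC = "loglogistic"


#: number of free parameters, used for tie-breaking in model selection
N_PARAMS = {
    Family.EXPONENTIAL: 1,
    Family.WEIBULL: 2,
    Family.LOGNORMAL: 2,
    Family.LOGLOGISTIC: 2,
}

_REQUIRED_PARAMS = {
    Family.EXPONENTIAL: ("rate",),
    Family.WEIBULL: ("shape", "scale"),
    Family.LOGNORMAL: ("mu", "sigma"),
    Family.LOGLOGISTIC: ("shape", "scale"),
}


@dataclass(frozen=True)
class SurvivalModel:
    """A parametric survivor function for one prosthesis type.

    Parameters by family (all times in years):

    - exponential: ``rate`` λ, S(t) = exp(−λt)
    - weibull: ``shape`` k, ``scale`` λ, S(t) = exp(−(t/λ)^k)
    - lognormal: ``mu``, ``sigma`` of log-time
    - loglogistic: ``shape`` β, ``scale`` α, S(t) = 1 / (1 + (t/α)^β)
    """

    family: Family
    parameters: Mapping[str, float]
    fitted_loglik: Optional[float] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        required = _REQUIRED_PARAMS[self.family]
        missing = [k for k in required if k not in self.parameters]
        if missing:
            raise ValueError(
                f"{self.family.value} model missing parameter(s) {missing}"
            )
        for k in required:
            v = self.parameters[k]
            if k == "mu":
                continue  # log-time location may be any real
            if v <= 0:
                raise ValueError(
                    f"{self.family.value} parameter {k!r} must be positive, got {v}"
                )

    def survival(self, t):
        return survival_at(self, t)


@dataclass(frozen=True)
class KMCurve:
    """Product-limit survival estimates at strictly increasing times."""

    times: np.ndarray
    survival: np.ndarray
    n_initial: Optional[int] = None

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        surv = np.asarray(self.survival, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "survival", surv)
        if times.ndim != 1 or surv.shape != times.shape:
            raise ValueError("times and survival must be equal-length 1-D arrays")
        if times.size == 0:
            raise ValueError("empty curve")
        if np.any(times <= 0):
            raise ValueError("curve times must be positive")
        if np.any(np.diff(times) <= 0):
            raise ValueError("curve times must be strictly increasing")
        if surv[0] > 1.0 + 1e-12 or np.any(surv < -1e-12):
            raise ValueError("survival values must lie in [0, 1]")
        if np.any(np.diff(surv) > 1e-12):
            raise ValueError("survival values must be nonincreasing")


def km_estimator(event_times: Sequence[float], event_observed: Sequence[bool],
                 ) -> KMCurve:
    """Kaplan–Meier product-limit estimate from (possibly censored) times.

    Censored subjects leave the risk set without producing a drop in the
    curve. Raises if every observation is censored (no events to estimate
    from).
    """
    from lifelines import KaplanMeierFitter

    times = np.asarray(event_times, dtype=float)
    observed = np.asarray(event_observed, dtype=bool)
    if times.shape != observed.shape or times.ndim != 1:
        raise ValueError("event_times and event_observed must match in shape")
    if np.any(times < 0):
        raise ValueError("event times must be >= 0")
    if not observed.any():
        raise ValueError("all observations censored: no events to estimate from")

    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=observed)
    sf = kmf.survival_function_
    grid = np.asarray(sf.index, dtype=float)
    surv = np.asarray(sf.iloc[:, 0], dtype=float)
    keep = grid > 0
    return KMCurve(times=grid[keep], survival=surv[keep], n_initial=times.size)


def _pseudo_individuals(curve: KMCurve) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Weighted pseudo event data reconstructed from curve steps.

    Each drop in S becomes an event with weight equal to the drop, placed at
    the midpoint of the interval over which the drop occurred (events are
    only known to lie between successive curve points; midpoint placement
    makes the fit unbiased on noiseless gridded curves). Residual survival at
    the last point becomes a censored observation. At-risk counts are
    unavailable from a digitized curve, so weights are the unconditional drop
    fractions (uniform weighting).
    """
    prev = np.concatenate([[1.0], curve.survival[:-1]])
    prev_t = np.concatenate([[0.0], curve.times[:-1]])
    drops = prev - curve.survival
    keep = drops > 1e-15
    durations = 0.5 * (prev_t[keep] + curve.times[keep])
    weights = drops[keep]
    observed = np.ones(durations.size, dtype=bool)
    tail = curve.survival[-1]
    if tail > 1e-15:
        durations = np.append(durations, curve.times[-1])
        weights = np.append(weights, tail)
        observed = np.append(observed, False)
    if durations.size == 0:
        raise FitError("curve has no drops and no residual mass")
    return durations, observed, weights


def _weibull_lsq(curve: KMCurve) -> SurvivalModel:
    """Least-squares fit of log(−log S) on log t (Weibull fallback)."""
    mask = (curve.survival > 0) & (curve.survival < 1)
    if mask.sum() < 2:
        raise FitError("too few interior points for the log(−log) regression")
    x = np.log(curve.times[mask])
    y = np.log(-np.log(curve.survival[mask]))
    slope, intercept = np.polyfit(x, y, 1)
    shape = float(slope)
    scale = float(np.exp(-intercept / slope))
    if shape <= 0 or scale <= 0:
        raise FitError("log(−log) regression produced non-positive parameters")
    return SurvivalModel(Family.WEIBULL, {"shape": shape, "scale": scale})


def _lifelines_fit(family: Family, durations, observed, weights):
    from lifelines import (ExponentialFitter, LogLogisticFitter,
                           LogNormalFitter, WeibullFitter)

    fitters = {
        Family.EXPONENTIAL: ExponentialFitter,
        Family.WEIBULL: WeibullFitter,
        Family.LOGNORMAL: LogNormalFitter,
        Family.LOGLOGISTIC: LogLogisticFitter,
    }
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fitter = fitters[family]().fit(
            durations, event_observed=observed, weights=weights
        )
    if family is Family.EXPONENTIAL:
        params = {"rate": 1.0 / float(fitter.lambda_)}
    elif family is Family.WEIBULL:
        params = {"shape": float(fitter.rho_), "scale": float(fitter.lambda_)}
    elif family is Family.LOGNORMAL:
        params = {"mu": float(fitter.mu_), "sigma": float(fitter.sigma_)}
    else:
        params = {"shape": float(fitter.beta_), "scale": float(fitter.alpha_)}
    loglik = float(fitter.log_likelihood_)
    if not np.isfinite(loglik):
        raise FitError(f"{family.value} fit did not converge (loglik not finite)")
    return SurvivalModel(family, params, fitted_loglik=loglik)


def _loglik(model: SurvivalModel, durations, observed, weights) -> float:
    """Weighted censored log-likelihood of a model on pseudo data."""
    dist = _scipy_dist(model)
    ll = np.where(observed, dist.logpdf(durations), dist.logsf(durations))
    return float(np.sum(weights * ll))


def _scipy_dist(model: SurvivalModel):
    p = model.parameters
    if model.family is Family.EXPONENTIAL:
        return stats.expon(scale=1.0 / p["rate"])
    if model.family is Family.WEIBULL:
        return stats.weibull_min(c=p["shape"], scale=p["scale"])
    if model.family is Family.LOGNORMAL:
        return stats.lognorm(s=p["sigma"], scale=np.exp(p["mu"]))
    return stats.fisk(c=p["shape"], scale=p["scale"])


def fit_parametric(curve: KMCurve, family: Family) -> SurvivalModel:
    """Maximum-likelihood fit of a parametric family to a KM curve.

    The likelihood is over pseudo-individual event data reconstructed from
    the curve's steps. Falls back to a least-squares fit on the log(−log S)
    scale for Weibull-family degenerate inputs.
    """
    family = Family(family)
    if curve.times.size < 3:
        raise ValueError("need at least 3 curve points to fit")
    durations, observed, weights = _pseudo_individuals(curve)
    try:
        return _lifelines_fit(family, durations, observed, weights)
    except FitError:
        raise
    except Exception as exc:  # lifelines convergence failure
        if family is Family.WEIBULL:
            model = _weibull_lsq(curve)
            loglik = _loglik(model, durations, observed, weights)
            return SurvivalModel(family, dict(model.parameters),
                                 fitted_loglik=loglik)
        raise FitError(f"{family.value} fit failed: {exc}") from exc


def select_distribution(curve: KMCurve, candidates: Sequence[Family],
                        tol: float = 1e-6) -> SurvivalModel:
    """Fit every candidate family and keep the best by log-likelihood.

    Candidates whose log-likelihood is within ``tol`` of the maximum are
    tied; ties go to the family with fewer parameters.
    """
    candidates = [Family(c) for c in candidates]
    if not candidates:
        raise ValueError("at least one candidate family required")
    fits: list[SurvivalModel] = []
    errors: dict[str, str] = {}
    for fam in candidates:
        try:
            fits.append(fit_parametric(curve, fam))
        except Exception as exc:
            errors[fam.value] = str(exc)
    if not fits:
        raise FitError(f"every candidate family failed to fit: {errors}")
    best_ll = max(f.fitted_loglik for f in fits)
    tied = [f for f in fits if f.fitted_loglik >= best_ll - tol]
    return min(tied, key=lambda f: (N_PARAMS[f.family], -f.fitted_loglik))


def survival_at(model: SurvivalModel, t):
    """Closed-form survivor function S(t); t may be a scalar or array."""
    arr = np.asarray(t, dtype=float)
    scalar = arr.ndim == 0
    tt = np.atleast_1d(arr)
    if np.any(tt < 0):
        raise ValueError("survival time must be >= 0")
    p = model.parameters
    if model.family is Family.EXPONENTIAL:
        out = np.exp(-p["rate"] * tt)
    elif model.family is Family.WEIBULL:
        out = np.exp(-((tt / p["scale"]) ** p["shape"]))
    elif model.family is Family.LOGNORMAL:
        out = np.ones_like(tt)
        pos = tt > 0
        z = (np.log(tt, where=pos, out=np.zeros_like(tt)) - p["mu"]) / p["sigma"]
        out[pos] = stats.norm.sf(z[pos])
    elif model.family is Family.LOGLOGISTIC:
        out = 1.0 / (1.0 + (tt / p["scale"]) ** p["shape"])
    else:  # pragma: no cover
        raise ValueError(f"unknown family {model.family}")
    return float(out[0]) if scalar else out


def conditional_failure_prob(model: SurvivalModel, age: int) -> float:
    """Probability a prosthesis alive at the start of its age-th year fails
    during that year: 1 − S(age)/S(age−1)."""
    if age < 1:
        raise ValueError(f"age must be >= 1, got {age}")
    s_prev = survival_at(model, age - 1)
    if s_prev <= 0.0:
        raise ValueError(
            f"cohort already extinct at age {age - 1} (S = 0); conditional "
            "failure probability undefined"
        )
    return 1.0 - survival_at(model, age) / s_prev


# --------------------------------------------------------------------------
# tabular IO

def read_km_csv(path: str | Path) -> KMCurve:
    """Digitized survival points: columns time_years, survival_probability."""
    df = pd.read_csv(path, comment="#")
    missing = {"time_years", "survival_probability"} - set(df.columns)
    if missing:
        raise ValueError(f"KM CSV missing column(s) {sorted(missing)}")
    df = df.sort_values("time_years")
    return KMCurve(
        times=df["time_years"].to_numpy(float),
        survival=df["survival_probability"].to_numpy(float),
    )


def failure_probability_table(model: SurvivalModel, horizon: int) -> pd.DataFrame:
    """Per-age survival and conditional failure probabilities, ages 1..horizon."""
    ages = np.arange(1, horizon + 1)
    surv = survival_at(model, ages)
    rows = [conditional_failure_prob(model, int(a)) for a in ages]
    return pd.DataFrame({
        "age_years": ages,
        "survival": surv,
        "conditional_failure_probability": rows,
    })
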