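"""Parametric survival families, maximum-likelihood fitting, and per-cycle
event probabilities.

Five families are supported: exponential, Weibull, log-logistic, lognormal,
and Gompertz.  Time is measured in model cycles (one cycle = 21 days).  The
log-logistic law uses the scale-rate form

    S(t) = 1 / (1 + lam * t**gam)

with ``lam`` a scale-rate (> 0) and ``gam`` a shape (> 0).  The Weibull and
Gompertz families likewise use rate-style parameterizations so that every
parameter is strictly positive (lognormal allows any real log-scale mu).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "FAMILIES",
    "ParametricSurvival",
    "KMCurve",
    "FitResult",
    "survival_at",
    "median_time",
    "per_cycle_event_prob",
    "fit_km",
    "select_model",
]

logger = logging.getLogger(__name__)

#: Canonical family order; also the final tie-break rank in model selection.
FAMILIES = ("exponential", "weibull", "loglogistic", "lognormal", "gompertz")

_N_PARAMS = {
    "exponential": 1,
    "weibull": 2,
    "loglogistic": 2,
    "lognormal": 2,
    "gompertz": 2,
}

#: Survival floor applied before forming ratios of survival values.
S_FLOOR = 1e-12


@dataclass(frozen=True)
class ParametricSurvival:
    """A parametric survival law: family name plus ordered parameters.

    Parameter order per family (all times in cycles):

    - exponential: (rate,)                   S(t) = exp(-rate*t)
    - weibull:     (lam, gam)                S(t) = exp(-lam*t**gam)
    - loglogistic: (lam, gam)                S(t) = 1/(1 + lam*t**gam)
    - lognormal:   (mu, sigma)               S(t) = 1 - Phi((ln t - mu)/sigma)
    - gompertz:    (rate, shape)             S(t) = exp(-rate/shape*(exp(shape*t)-1))
    """

    family: str
    params: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown survival family {self.family!r}")
        object.__setattr__(self, "params", tuple(float(p) for p in self.params))
        if len(self.params) != _N_PARAMS[self.family]:
            raise ValueError(
                f"{self.family} expects {_N_PARAMS[self.family]} parameters, "
                f"got {len(self.params)}"
            )
        positives = self.params
        if self.family == "lognormal":
            positives = self.params[1:]  # mu may be any real
        if any(not math.isfinite(p) for p in self.params) or any(
            p <= 0 for p in positives
        ):
            raise ValueError(
                f"invalid parameters {self.params} for family {self.family}"
            )

    # -- evaluation ------------------------------------------------------

    def survival(self, t):
        """Vectorized S(t); raises on negative times."""
        t_arr = np.asarray(t, dtype=float)
        if np.any(t_arr < 0):
            raise ValueError("survival time must be non-negative")
        if self.family == "exponential":
            (rate,) = self.params
            s = np.exp(-rate * t_arr)
        elif self.family == "weibull":
            lam, gam = self.params
            s = np.exp(-lam * np.power(t_arr, gam))
        elif self.family == "loglogistic":
            lam, gam = self.params
            s = 1.0 / (1.0 + lam * np.power(t_arr, gam))
        elif self.family == "lognormal":
            mu, sigma = self.params
            with np.errstate(divide="ignore"):
                z = (np.log(np.where(t_arr > 0, t_arr, 1.0)) - mu) / sigma
            s = np.where(t_arr > 0, stats.norm.sf(z), 1.0)
        else:  # gompertz
            rate, shape = self.params
            s = np.exp(-rate / shape * np.expm1(shape * t_arr))
        return s if s.ndim else float(s)

    def log_hazard(self, t_arr: np.ndarray) -> np.ndarray:
        """log h(t) on strictly positive times (used by the fitter)."""
        if self.family == "exponential":
            (rate,) = self.params
            return np.full_like(t_arr, math.log(rate))
        if self.family == "weibull":
            lam, gam = self.params
            return math.log(lam * gam) + (gam - 1.0) * np.log(t_arr)
        if self.family == "loglogistic":
            lam, gam = self.params
            # h = lam*gam*t^(g-1) / (1 + lam*t^g)
            return (
                math.log(lam * gam)
                + (gam - 1.0) * np.log(t_arr)
                - np.log1p(lam * np.power(t_arr, gam))
            )
        if self.family == "lognormal":
            mu, sigma = self.params
            z = (np.log(t_arr) - mu) / sigma
            return (
                stats.norm.logpdf(z)
                - math.log(sigma)
                - np.log(t_arr)
                - stats.norm.logsf(z)
            )
        rate, shape = self.params  # gompertz
        return math.log(rate) + shape * t_arr

    def cumulative_hazard(self, t_arr: np.ndarray) -> np.ndarray:
        if self.family == "exponential":
            (rate,) = self.params
            return rate * t_arr
        if self.family == "weibull":
            lam, gam = self.params
            return lam * np.power(t_arr, gam)
        if self.family == "loglogistic":
            lam, gam = self.params
            return np.log1p(lam * np.power(t_arr, gam))
        if self.family == "lognormal":
            mu, sigma = self.params
            with np.errstate(divide="ignore"):
                z = (np.log(np.where(t_arr > 0, t_arr, 1.0)) - mu) / sigma
            return np.where(t_arr > 0, -stats.norm.logsf(z), 0.0)
        rate, shape = self.params
        return rate / shape * np.expm1(shape * t_arr)


@dataclass(frozen=True)
class KMCurve:
    """A product-limit (or digitized) survival curve on cycle time."""

    times: tuple[float, ...]
    surv: tuple[float, ...]
    n_at_risk: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        times = tuple(float(t) for t in self.times)
        surv = tuple(float(s) for s in self.surv)
        if len(times) != len(surv) or not times:
            raise ValueError("times and surv must be equal-length and non-empty")
        if any(t < 0 for t in times) or any(np.diff(times) < 0):
            raise ValueError("times must be non-negative and non-decreasing")
        if any(s < 0 or s > 1 for s in surv) or any(np.diff(surv) > 1e-12):
            raise ValueError("surv must be non-increasing within [0, 1]")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "surv", surv)

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame({"time_cycles": self.times, "survival": self.surv}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path) -> "KMCurve":
        import pandas as pd

        df = pd.read_csv(path)
        return cls(tuple(df["time_cycles"]), tuple(df["survival"]))


@dataclass(frozen=True)
class FitResult:
    """A fitted model with its goodness-of-fit summary."""

    model: ParametricSurvival
    loglik: float
    aic: float
    bic: float
    n_obs: int = 0
    converged: bool = True

    @property
    def k(self) -> int:
        return _N_PARAMS[self.model.family]


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def survival_at(model: ParametricSurvival, t) -> float:
    """Evaluate S(t) for a valid model at time ``t`` (cycles)."""
    return model.survival(t)


def median_time(model: ParametricSurvival) -> float:
    """Time t with S(t) = 0.5.

    Closed forms where available; Gompertz uses its analytic inverse and
    raises :class:`ValueError` when the survival plateau lies above 0.5.
    """
    p = model.params
    if model.family == "exponential":
        return math.log(2.0) / p[0]
    if model.family == "weibull":
        return (math.log(2.0) / p[0]) ** (1.0 / p[1])
    if model.family == "loglogistic":
        return (1.0 / p[0]) ** (1.0 / p[1])
    if model.family == "lognormal":
        return math.exp(p[0])
    rate, shape = p  # gompertz: H(t) = rate/shape*(e^{shape t}-1) = ln 2
    arg = 1.0 + shape * math.log(2.0) / rate
    if arg <= 0:
        raise ValueError("survival never reaches 0.5 for these parameters")
    return math.log(arg) / shape


def per_cycle_event_prob(model: ParametricSurvival, cycle_index: int) -> float:
    """Probability of the event during cycle ``cycle_index`` given survival
    to its start: 1 - S(c+1)/S(c).  Degenerate S(c)=0 returns 1 with a
    warning."""
    if cycle_index < 0:
        raise ValueError("cycle_index must be >= 0")
    s0 = survival_at(model, float(cycle_index))
    s1 = survival_at(model, float(cycle_index + 1))
    if s0 <= S_FLOOR:
        logger.warning(
            "survival already ~0 at cycle %d; event probability set to 1",
            cycle_index,
        )
        return 1.0
    return min(max(1.0 - s1 / max(s0, S_FLOOR), 0.0), 1.0)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


def _init_params(times: np.ndarray, events: np.ndarray, family: str) -> np.ndarray:
    """Moment-style starting values on the log scale."""
    t_pos = np.maximum(times, 1e-6)
    rate0 = max(events.sum(), 1.0) / t_pos.sum()
    if family == "exponential":
        return np.log([rate0])
    if family in ("weibull", "loglogistic"):
        return np.log([rate0, 1.0])
    if family == "lognormal":
        mu0 = float(np.mean(np.log(t_pos)))
        sigma0 = max(float(np.std(np.log(t_pos))), 0.1)
        return np.array([mu0, math.log(sigma0)])
    # gompertz: keep shape*t_max small enough that exp(shape*t) is finite
    shape0 = min(0.05, 10.0 / max(float(times.max()), 1.0))
    return np.log([rate0, shape0])


def _from_log(theta: np.ndarray, family: str) -> tuple[float, ...]:
    if family == "lognormal":
        return (float(theta[0]), float(math.exp(theta[1])))
    return tuple(float(math.exp(x)) for x in theta)


def neg_loglik(
    theta: np.ndarray, times: np.ndarray, events: np.ndarray, family: str
) -> float:
    """Right-censored negative log-likelihood on log-scale parameters."""
    try:
        model = ParametricSurvival(family, _from_log(theta, family))
    except (ValueError, OverflowError):
        return 1e12
    t_pos = np.maximum(times, 1e-9)
    with np.errstate(over="ignore", invalid="ignore"):
        ll = float(
            np.sum(events * model.log_hazard(t_pos))
            - np.sum(model.cumulative_hazard(t_pos))
        )
    if not math.isfinite(ll):
        return 1e12
    return -ll


def fit_km(
    data: Sequence[tuple[float, int]],
    family: str,
) -> FitResult:
    """Maximum-likelihood fit of one family to right-censored (time, event)
    pairs.

    Requires at least 10 observations with at least one event.  AIC and BIC
    use k parameters and n = number of observations.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown survival family {family!r}")
    arr = np.asarray(list(data), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("data must be (time, event) pairs")
    times, events = arr[:, 0], arr[:, 1]
    n = len(times)
    if n < 10:
        raise ValueError(f"need at least 10 observations, got {n}")
    if events.sum() < 1:
        raise ValueError("all observations censored; cannot fit")
    if np.any(times < 0) or not set(np.unique(events)) <= {0.0, 1.0}:
        raise ValueError("times must be >= 0 and events in {0, 1}")

    theta0 = _init_params(times, events, family)
    res = optimize.minimize(
        neg_loglik,
        theta0,
        args=(times, events, family),
        method="Nelder-Mead",
        options={"maxiter": 4000, "xatol": 1e-9, "fatol": 1e-10},
    )
    if not res.success:
        # one polish attempt from the best point so far
        res = optimize.minimize(
            neg_loglik,
            res.x,
            args=(times, events, family),
            method="Nelder-Mead",
            options={"maxiter": 4000},
        )
    if not math.isfinite(res.fun) or res.fun >= 1e12:
        raise RuntimeError(
            f"fit of family {family} failed to converge: {res.message}"
        )
    model = ParametricSurvival(family, _from_log(res.x, family))
    loglik = -float(res.fun)
    k = _N_PARAMS[family]
    return FitResult(
        model=model,
        loglik=loglik,
        aic=-2.0 * loglik + 2.0 * k,
        bic=-2.0 * loglik + k * math.log(n),
        n_obs=n,
        converged=bool(res.success),
    )


def fit_all_families(data: Sequence[tuple[float, int]]) -> list[FitResult]:
    """Fit every supported family; failed fits are skipped with a log entry."""
    fits = []
    for family in FAMILIES:
        try:
            fits.append(fit_km(data, family))
        except RuntimeError as exc:  # pragma: no cover - rare
            logger.warning("family %s dropped: %s", family, exc)
    return fits


def select_model(fits: Sequence[FitResult]) -> FitResult:
    """Pick the fit with minimal AIC; ties broken by BIC, then family order."""
    if not fits:
        raise ValueError("no fits to select from")
    ranked = sorted(
        fits, key=lambda f: (f.aic, f.bic, FAMILIES.index(f.model.family))
    )
    for i, f in enumerate(ranked, 1):
        logger.info(
            "model rank %d: %s aic=%.3f bic=%.3f", i, f.model.family, f.aic, f.bic
        )
    return ranked[0]
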