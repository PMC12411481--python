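"""Parametric survival curves, right-censored MLE fitting, and pseudo-IPD tools.

Time is measured in months throughout this module.  Six families are
supported: exponential, Weibull, two-parameter gamma, log-normal,
log-logistic and Gompertz.  Parameterizations:

========== ========================= =====================================
family     params                    survival function
========== ========================= =====================================
exponential (rate,)                  S(t) = exp(-rate*t)
weibull     (shape, scale)           S(t) = exp(-(t/scale)**shape)
gamma       (shape, scale)           S(t) = 1 - GammaCDF(t; shape, scale)
lognormal   (meanlog, sdlog)         S(t) = 1 - Phi((ln t - meanlog)/sdlog)
loglogistic (shape, scale)           S(t) = 1 / (1 + (t/scale)**shape)
gompertz    (shape, rate)            S(t) = exp(-(rate/shape)*(e**(shape*t)-1))
========== ========================= =====================================

The log-logistic form is equivalent to S(t) = 1/(1 + lambda*t**gamma) with
lambda = scale**(-shape) and gamma = shape; with this mapping the median
equals the scale parameter.  The Gompertz shape may be negative, in which
case the survival function plateaus at exp(rate/shape) > 0 instead of
decaying to zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "FAMILIES",
    "ParametricSurvival",
    "PseudoIPD",
    "KMCurvePoints",
    "FitResult",
    "survival_at",
    "fit_mle",
    "fit_all_families",
    "select_model",
    "km_estimator",
    "reconstruct_pseudo_ipd",
    "fit_report",
]

#: Fixed family order, also the documented tie-break order in model selection.
FAMILIES = ("exponential", "weibull", "gamma", "lognormal", "loglogistic", "gompertz")

_N_PARAMS = {
    "exponential": 1,
    "weibull": 2,
    "gamma": 2,
    "lognormal": 2,
    "loglogistic": 2,
    "gompertz": 2,
}


class SurvivalValidationError(ValueError):
    """Invalid parameters or malformed survival inputs."""


def _as_1d(t) -> np.ndarray:
    arr = np.atleast_1d(np.asarray(t, dtype=float))
    if arr.ndim != 1:
        raise SurvivalValidationError("time input must be scalar or 1-d")
    return arr


@dataclass(frozen=True)
class ParametricSurvival:
    """A parametric survival curve: a family name plus its parameter vector."""

    family: str
    params: tuple

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise SurvivalValidationError(
                f"unknown family {self.family!r}; expected one of {FAMILIES}"
            )
        object.__setattr__(self, "params", tuple(float(p) for p in self.params))
        if len(self.params) != _N_PARAMS[self.family]:
            raise SurvivalValidationError(
                f"{self.family} expects {_N_PARAMS[self.family]} parameters, "
                f"got {len(self.params)}"
            )
        self._validate()

    def _validate(self):
        p = self.params
        if any(not math.isfinite(v) for v in p):
            raise SurvivalValidationError(f"non-finite parameters {p}")
        if self.family == "exponential" and p[0] <= 0:
            raise SurvivalValidationError("exponential rate must be > 0")
        elif self.family in ("weibull", "gamma", "loglogistic"):
            if p[0] <= 0 or p[1] <= 0:
                raise SurvivalValidationError(f"{self.family} shape/scale must be > 0")
        elif self.family == "lognormal" and p[1] <= 0:
            raise SurvivalValidationError("lognormal sdlog must be > 0")
        elif self.family == "gompertz":
            if p[0] == 0:
                raise SurvivalValidationError("gompertz shape must be nonzero")
            if p[1] <= 0:
                raise SurvivalValidationError("gompertz rate must be > 0")

    # -- distribution functions ------------------------------------------
    def _frozen(self):
        p = self.params
        if self.family == "exponential":
            return stats.expon(scale=1.0 / p[0])
        if self.family == "weibull":
            return stats.weibull_min(c=p[0], scale=p[1])
        if self.family == "gamma":
            return stats.gamma(a=p[0], scale=p[1])
        if self.family == "lognormal":
            return stats.lognorm(s=p[1], scale=math.exp(p[0]))
        if self.family == "loglogistic":
            return stats.fisk(c=p[0], scale=p[1])
        return None  # gompertz handled explicitly

    def sf(self, t) -> np.ndarray:
        """Survival probability S(t); vectorized over t (months)."""
        t = _as_1d(t)
        if np.any(t < 0):
            raise SurvivalValidationError("negative time in survival evaluation")
        if self.family == "gompertz":
            a, b = self.params
            out = np.exp(-(b / a) * np.expm1(a * t))
        else:
            out = self._frozen().sf(t)
        return np.clip(out, 0.0, 1.0)

    def logsf(self, t) -> np.ndarray:
        t = _as_1d(t)
        if self.family == "gompertz":
            a, b = self.params
            return -(b / a) * np.expm1(a * t)
        return self._frozen().logsf(t)

    def logpdf(self, t) -> np.ndarray:
        t = _as_1d(t)
        if self.family == "gompertz":
            a, b = self.params
            return np.log(b) + a * t - (b / a) * np.expm1(a * t)
        return self._frozen().logpdf(t)

    def median(self) -> float:
        if self.family == "gompertz":
            a, b = self.params
            arg = 1.0 + (a / b) * math.log(2.0)
            if arg <= 0:  # plateau above 0.5: median undefined
                return math.inf
            return math.log(arg) / a
        return float(self._frozen().median())


def survival_at(model: ParametricSurvival, t) -> np.ndarray | float:
    """Evaluate S(t) for scalar or vector t >= 0 (months)."""
    scalar = np.isscalar(t)
    out = model.sf(t)
    return float(out[0]) if scalar else out


# -- individual patient data -------------------------------------------------


@dataclass
class PseudoIPD:
    """Individual (time, event) records; event 1 = event observed, 0 = censored."""

    time: np.ndarray
    event: np.ndarray

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        if self.time.shape != self.event.shape or self.time.ndim != 1:
            raise SurvivalValidationError("time and event must be equal-length 1-d arrays")
        if len(self.time) == 0:
            raise SurvivalValidationError("pseudo-IPD must contain at least one record")
        if np.any(self.time < 0):
            raise SurvivalValidationError("negative times in pseudo-IPD")
        if not np.isin(self.event, (0, 1)).all():
            raise SurvivalValidationError("event indicator must be 0 or 1")

    def __len__(self):
        return len(self.time)

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_months": self.time, "event": self.event})

    def to_csv(self, path):
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "PseudoIPD":
        df = pd.read_csv(path, comment="#")
        return cls(df["time_months"].to_numpy(), df["event"].to_numpy())


@dataclass
class KMCurvePoints:
    """Digitized or estimated Kaplan-Meier coordinates: (time, survival) pairs."""

    time: np.ndarray
    survival: np.ndarray

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.survival = np.asarray(self.survival, dtype=float)
        if self.time.shape != self.survival.shape or self.time.ndim != 1:
            raise SurvivalValidationError("time/survival must be equal-length 1-d arrays")
        if len(self.time) == 0:
            raise SurvivalValidationError("empty KM curve")
        if np.any(np.diff(self.time) <= 0):
            raise SurvivalValidationError("KM times must be strictly increasing")
        if np.any((self.survival < 0) | (self.survival > 1)):
            raise SurvivalValidationError("KM survival must lie in [0, 1]")
        if np.any(np.diff(self.survival) > 1e-12):
            raise SurvivalValidationError("KM survival must be non-increasing")
        if np.any(self.time < 0):
            raise SurvivalValidationError("negative KM times")

    def __len__(self):
        return len(self.time)

    def step_interp(self, t) -> np.ndarray:
        """Right-continuous step interpolation, S(t)=1 before the first point."""
        t = _as_1d(t)
        idx = np.searchsorted(self.time, t, side="right") - 1
        out = np.where(idx >= 0, self.survival[np.clip(idx, 0, None)], 1.0)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_months": self.time, "survival": self.survival})

    def to_csv(self, path):
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "KMCurvePoints":
        df = pd.read_csv(path, comment="#")
        return cls(df["time_months"].to_numpy(), df["survival"].to_numpy())


# -- maximum likelihood fitting ----------------------------------------------


@dataclass
class FitResult:
    model: ParametricSurvival
    loglik: float
    aic: float
    bic: float
    n: int
    converged: bool

    @property
    def k(self) -> int:
        return len(self.model.params)


def _loglik(model: ParametricSurvival, time: np.ndarray, event: np.ndarray) -> float:
    ev = event == 1
    ll = 0.0
    if ev.any():
        ll += float(model.logpdf(time[ev]).sum())
    if (~ev).any():
        ll += float(model.logsf(time[~ev]).sum())
    return ll


def _starting_points(family: str, time: np.ndarray, event: np.ndarray) -> list:
    """Three documented moment-style starting points per family.

    Base start uses the mean observed time (rough scale) and log-time
    moments; the other two perturb the shape up/down to escape flat regions.
    """
    tpos = np.maximum(time, 1e-8)
    mean_t = float(tpos.mean())
    mlog = float(np.log(tpos).mean())
    slog = float(np.log(tpos).std(ddof=0)) or 1.0
    if family == "exponential":
        r = max(event.mean() / mean_t, 1e-8)
        return [[r], [r * 2], [r / 2]]
    if family == "lognormal":
        return [[mlog, slog], [mlog, slog * 2], [mlog, slog / 2]]
    if family == "gompertz":
        r = max(event.mean() / mean_t, 1e-8)
        return [[0.05, r], [0.2, r], [-0.05, r]]
    # weibull / gamma / loglogistic: (shape, scale)
    return [[1.0, mean_t], [1.5, mean_t], [0.7, mean_t]]


def _to_unconstrained(family: str, p: Sequence[float]) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if family == "lognormal":
        return np.array([p[0], math.log(p[1])])
    if family == "gompertz":
        return np.array([p[0], math.log(p[1])])  # shape free, rate > 0
    return np.log(p)


def _from_unconstrained(family: str, x: np.ndarray) -> tuple:
    if family == "lognormal":
        return (x[0], math.exp(x[1]))
    if family == "gompertz":
        return (x[0], math.exp(x[1]))
    return tuple(np.exp(x))


def fit_mle(ipd: PseudoIPD, family: str) -> FitResult:
    """Fit one parametric family to right-censored data by maximum likelihood.

    The likelihood is sum_events log f(t) + sum_censored log S(t).  Positive
    parameters are optimized on the log scale; three starting points are
    tried and the best optimum kept (tolerance 1e-8 on the log-likelihood).
    The exponential rate uses its closed form events/total-time.
    """
    if family not in FAMILIES:
        raise SurvivalValidationError(f"unknown family {family!r}")
    if len(ipd) < 2:
        raise SurvivalValidationError("need at least two records to fit")
    if ipd.n_events < 1:
        raise SurvivalValidationError("cannot fit survival model with zero events")

    time = np.maximum(ipd.time, 1e-8)  # guard log(0) for exact-zero times
    event = ipd.event
    n = len(ipd)

    if family == "exponential":
        rate = ipd.n_events / float(time.sum())
        model = ParametricSurvival("exponential", (rate,))
        ll = _loglik(model, time, event)
        return FitResult(model, ll, -2 * ll + 2 * 1, -2 * ll + 1 * math.log(n), n, True)

    _PENALTY = 1e15  # finite so gradient-based steps stay defined

    def nll(x):
        try:
            model = ParametricSurvival(family, _from_unconstrained(family, x))
        except (SurvivalValidationError, OverflowError):
            return _PENALTY
        val = _loglik(model, time, event)
        return _PENALTY if not np.isfinite(val) else -val

    coarse = None
    for start in _starting_points(family, time, event):
        x0 = _to_unconstrained(family, start)
        res = optimize.minimize(nll, x0, method="L-BFGS-B")
        if coarse is None or res.fun < coarse.fun:
            coarse = res
    # derivative-free polish at tight tolerance from the best coarse optimum
    best = optimize.minimize(
        nll, coarse.x, method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": 1e-8, "maxiter": 4000},
    )
    if coarse.fun < best.fun:
        best = coarse
    params = _from_unconstrained(family, best.x)
    model = ParametricSurvival(family, params)
    ll = -float(best.fun)
    converged = bool(best.success and np.isfinite(ll))
    k = _N_PARAMS[family]
    return FitResult(model, ll, -2 * ll + 2 * k, -2 * ll + k * math.log(n), n, converged)


def fit_all_families(ipd: PseudoIPD, families: Iterable[str] = FAMILIES) -> list:
    return [fit_mle(ipd, fam) for fam in families]


def select_model(fits: Sequence[FitResult]) -> FitResult:
    """Pick the best fit: smallest AIC, ties broken by BIC, then family order."""
    fits = list(fits)
    if not fits:
        raise SurvivalValidationError("select_model requires a non-empty list of fits")
    return min(fits, key=lambda f: (f.aic, f.bic, FAMILIES.index(f.model.family)))


def fit_report(fits: Sequence[FitResult]) -> pd.DataFrame:
    """Tabular fit summary (family, params, loglik, AIC, BIC, converged)."""
    rows = []
    for f in sorted(fits, key=lambda f: f.aic):
        rows.append({
            "family": f.model.family,
            "params": ";".join(f"{p:.6g}" for p in f.model.params),
            "loglik": f.loglik,
            "aic": f.aic,
            "bic": f.bic,
            "n": f.n,
            "converged": f.converged,
        })
    return pd.DataFrame(rows)


# -- Kaplan-Meier and reconstruction -----------------------------------------


def km_estimator(ipd: PseudoIPD) -> KMCurvePoints:
    """Product-limit estimate evaluated at each distinct event time.

    Returns a curve anchored at (0, 1).  Uses lifelines' KaplanMeierFitter.
    """
    from lifelines import KaplanMeierFitter

    kmf = KaplanMeierFitter()
    kmf.fit(ipd.time, ipd.event)
    event_times = np.unique(ipd.time[ipd.event == 1])
    if len(event_times) == 0:
        return KMCurvePoints(np.array([0.0]), np.array([1.0]))
    surv = kmf.survival_function_at_times(event_times).to_numpy()
    times = np.concatenate([[0.0], event_times])
    surv = np.concatenate([[1.0], surv])
    if times[1] == 0.0:  # events at t=0 collapse into the anchor
        times, surv = times[1:], surv[1:]
    return KMCurvePoints(times, surv)


def reconstruct_pseudo_ipd(
    curve: KMCurvePoints,
    n_total: int,
    at_risk: Sequence[int] | None = None,
) -> PseudoIPD:
    """Reconstruct individual records from digitized KM coordinates.

    Events are assigned at each step time so that the product-limit
    estimate of the output reproduces the input curve within rounding
    (1/(2*n_total)).  Without number-at-risk information, interior
    censoring is unidentifiable: all remaining subjects are
    administratively censored at the final curve time.  When ``at_risk``
    (count just before each curve time) is supplied, the implied censored
    subjects are spread uniformly within each interval.
    """
    if n_total < 1:
        raise SurvivalValidationError("n_total must be >= 1")
    times = curve.time
    surv = curve.survival
    if at_risk is not None and len(at_risk) != len(times):
        raise SurvivalValidationError("at_risk must align with curve times")

    rec_t: list = []
    rec_e: list = []
    n_risk = int(n_total)
    s_model = 1.0  # achieved KM level of the reconstruction
    start = 0
    if times[0] == 0.0:
        # anchor point; any drop at exactly t=0 is treated as a first step
        if surv[0] < 1.0:
            d0 = round(n_risk * (1 - surv[0]))
            rec_t += [0.0] * d0
            rec_e += [1] * d0
            s_model *= 1 - d0 / n_risk
            n_risk -= d0
        start = 1
    for i in range(start, len(times)):
        if n_risk <= 0 or s_model <= 0:
            break
        target = surv[i]
        d = round(n_risk * (1 - target / s_model)) if s_model > 0 else 0
        d = min(max(d, 0), n_risk)
        rec_t += [times[i]] * d
        rec_e += [1] * d
        s_model *= 1 - d / n_risk
        n_risk -= d
        if at_risk is not None and i + 1 < len(times):
            c = max(0, n_risk - int(at_risk[i + 1]))
            if c > 0:
                gaps = np.linspace(times[i], times[i + 1], c + 2)[1:-1]
                rec_t += list(gaps)
                rec_e += [0] * c
                n_risk -= c
    if n_risk > 0:  # administrative censoring at the end of the digitized curve
        rec_t += [times[-1]] * n_risk
        rec_e += [0] * n_risk
    return PseudoIPD(np.array(rec_t), np.array(rec_e))
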