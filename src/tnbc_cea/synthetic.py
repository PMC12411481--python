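"""Trial-like synthetic time-to-event data with known ground truth.

Emulates the inputs of the extrapolation pipeline — individual event
times drawn from a chosen parametric family, thinned by random
(exponential) censoring and an administrative cutoff — plus digitized-KM
style curve exports, so fitting, model selection and pseudo-IPD
reconstruction are testable end to end without any external data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .survival import KMCurvePoints, ParametricSurvival, PseudoIPD, km_estimator

__all__ = [
    "SimulationSpec",
    "simulate_ipd",
    "export_km_curve",
    "table_ground_truth_curves",
]


def table_ground_truth_curves() -> dict:
    """The four fitted base-case curves (CPS>=10), as simulation ground truth."""
    return {
        "pembrolizumab_pfs": ParametricSurvival("lognormal", (2.3487, 1.2258)),
        "pembrolizumab_os": ParametricSurvival("lognormal", (3.1454, 1.1058)),
        "placebo_pfs": ParametricSurvival("loglogistic", (1.763, 6.618)),
        "placebo_os": ParametricSurvival("loglogistic", (1.702, 16.631)),
    }


@dataclass(frozen=True)
class SimulationSpec:
    """Ground-truth family/params, cohort size, censoring, cutoff, seed."""

    model: ParametricSurvival
    n: int
    censor_rate: float = 0.0  # exponential censoring hazard per month
    admin_cutoff: float = math.inf  # months
    seed: int = 0

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.censor_rate < 0:
            raise ValueError("censoring rate must be >= 0")
        if self.admin_cutoff <= 0:
            raise ValueError("administrative cutoff must be positive")


def _sample_event_times(model: ParametricSurvival, n: int,
                        rng: np.random.Generator) -> np.ndarray:
    if model.family == "gompertz":
        a, b = model.params
        u = rng.uniform(size=n)
        arg = 1.0 - (a / b) * np.log(u)
        t = np.full(n, np.inf)
        ok = arg > 0
        t[ok] = np.log(arg[ok]) / a  # inverse of S(t)=u; inf = never-event plateau
        return t
    return model._frozen().rvs(size=n, random_state=rng)


def simulate_ipd(spec: SimulationSpec) -> PseudoIPD:
    """Draw (time, event) records: observed = min(event, censor, cutoff)."""
    rng = np.random.default_rng(spec.seed)
    t_event = _sample_event_times(spec.model, spec.n, rng)
    t_obs = np.minimum(t_event, spec.admin_cutoff)
    if spec.censor_rate > 0:
        t_cens = rng.exponential(1.0 / spec.censor_rate, size=spec.n)
        t_obs = np.minimum(t_obs, t_cens)
    event = (t_event <= t_obs).astype(int)
    return PseudoIPD(t_obs, event)


def export_km_curve(ipd: PseudoIPD, grid: Sequence[float]) -> KMCurvePoints:
    """Kaplan-Meier estimate sampled on a time grid (digitized-curve dialect)."""
    grid = np.asarray(list(grid), dtype=float)
    if grid.size == 0:
        raise ValueError("empty time grid")
    km = km_estimator(ipd)
    surv = km.step_interp(grid)
    return KMCurvePoints(grid, surv)
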