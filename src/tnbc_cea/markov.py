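"""Three-state Markov cohort engine (progression-free / progressed / dead).

Transition probabilities are rebuilt every cycle from the two extrapolated
survival curves:

* ``pFTF = S_pfs(t) / S_pfs(t-1)`` — stay progression-free,
* ``pFTD`` — progression-free to death, set to the general-population
  per-cycle mortality,
* ``pFTP = 1 - pFTD - pFTF`` — progress,
* ``pSTS = S_os(t) / S_os(t-1)`` — overall-survival ratio,
* ``pPTP = [(nPFS + nPD)*pSTS - nPFS*pFTF - nPFS*pFTP] / nPD`` and
  ``pPTD = 1 - pPTP``.

The ``pPTP`` construction forces the alive fraction to track the OS curve
and the PFS compartment to track the PFS curve exactly (a partitioned
survival equivalence) whenever no probability clamping triggers and
``pFTD`` is zero.  All probabilities are clamped to [0, 1]; clamp events
are counted on the returned trace.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

__all__ = [
    "BackgroundMortality",
    "TransitionRow",
    "CohortTrace",
    "per_cycle_probability",
    "transition_row",
    "run_cohort",
]

logger = logging.getLogger(__name__)

DAYS_PER_YEAR = 365.25
DAYS_PER_MONTH = 30.4375


class MarkovError(ValueError):
    """Invalid Markov engine input."""


def per_cycle_probability(annual_p: float, cycle_days: float) -> float:
    """Convert an annual probability to a per-cycle probability.

    Uses the constant-rate identity 1 - (1 - p)**(cycle_days/365.25).
    """
    if not 0.0 <= annual_p <= 1.0:
        raise MarkovError(f"annual probability {annual_p} outside [0, 1]")
    if cycle_days <= 0:
        raise MarkovError("cycle length must be positive")
    return 1.0 - (1.0 - annual_p) ** (cycle_days / DAYS_PER_YEAR)


@dataclass(frozen=True)
class BackgroundMortality:
    """General-population mortality, a constant annual death probability."""

    annual_probability: float = 0.002

    def __post_init__(self):
        if not 0.0 <= self.annual_probability <= 1.0:
            raise MarkovError("annual mortality outside [0, 1]")

    def per_cycle(self, cycle_days: float) -> float:
        return per_cycle_probability(self.annual_probability, cycle_days)


@dataclass(frozen=True)
class TransitionRow:
    cycle: int
    pFTD: float
    pFTF: float
    pFTP: float
    pPTP: float
    pPTD: float
    pSTS: float
    clamped: int = 0  # number of probabilities that required clamping


def _clamp(p: float) -> tuple:
    c = min(1.0, max(0.0, p))
    return c, int(c != p)


def transition_row(
    t: int, S_pfs, S_os, prev, pFTD: float, cycle_days: float = 21.0
) -> TransitionRow:
    """Build the cycle-``t`` transition probabilities from the two curves.

    ``prev`` is the occupancy (nPFS, nPD) at the end of cycle t-1; curves
    are evaluated at t and t-1 cycles converted to months.  ``S(t-1)=0``
    is treated as an absorbed compartment (ratio 0), not a division error;
    an empty PD compartment (nPD below 1e-12) pins pPTP to 0 since its
    flow is zero anyway.
    """
    t = int(t)
    if t < 1:
        raise MarkovError("transition cycles start at 1")
    months = cycle_days / DAYS_PER_MONTH
    tm, tm1 = t * months, (t - 1) * months
    nPFS, nPD = float(prev[0]), float(prev[1])
    sp1 = float(S_pfs.sf(tm1)[0])
    sp = float(S_pfs.sf(tm)[0])
    so1 = float(S_os.sf(tm1)[0])
    so = float(S_os.sf(tm)[0])

    clamped = 0
    pFTF = sp / sp1 if sp1 > 0 else 0.0
    pFTF, c = _clamp(pFTF)
    clamped += c
    pSTS = so / so1 if so1 > 0 else 0.0
    pSTS, c = _clamp(pSTS)
    clamped += c
    if nPD > 1e-12:
        pPTP_raw = ((nPFS + nPD) * pSTS - nPFS * (1.0 - pFTD)) / nPD
        pPTP, c = _clamp(pPTP_raw)
        clamped += c
    else:
        # empty PD compartment: no flow from PD, and the whole OS decrement
        # must leave through the PFS death channel to keep alive == S_os
        pPTP = 0.0
        pFTD = max(pFTD, 1.0 - pSTS)
    if pFTF > 1.0 - pFTD:  # keep the PFS row on the simplex
        pFTF = 1.0 - pFTD
        clamped += 1
    pFTP = 1.0 - pFTD - pFTF
    return TransitionRow(t, pFTD, pFTF, pFTP, pPTP, 1.0 - pPTP, pSTS, clamped)


@dataclass
class CohortTrace:
    """Per-cycle state occupancy; row k is the state after k transitions."""

    n_pfs: np.ndarray
    n_pd: np.ndarray
    n_dead: np.ndarray
    new_dead: np.ndarray  # deaths during the transition into row k
    cycle_days: float
    clamp_events: int = 0

    def __post_init__(self):
        for arr in (self.n_pfs, self.n_pd, self.n_dead, self.new_dead):
            if np.any(arr < -1e-12) or np.any(arr > 1 + 1e-12):
                raise MarkovError("occupancy outside [0, 1]")
        total = self.n_pfs + self.n_pd + self.n_dead
        if not np.allclose(total, 1.0, atol=1e-9):
            raise MarkovError("occupancies do not sum to 1")
        if np.any(np.diff(self.n_dead) < -1e-12):
            raise MarkovError("death state must be absorbing")

    @property
    def n_cycles(self) -> int:
        return len(self.n_pfs) - 1

    @property
    def months_per_cycle(self) -> float:
        return self.cycle_days / DAYS_PER_MONTH

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "cycle": np.arange(len(self.n_pfs)),
            "n_pfs": self.n_pfs,
            "n_pd": self.n_pd,
            "n_dead": self.n_dead,
            "new_dead": self.new_dead,
        })


def run_cohort(
    S_pfs,
    S_os,
    mortality: BackgroundMortality,
    horizon: int,
    cycle_days: float = 21.0,
) -> CohortTrace:
    """Run the cohort for ``horizon`` cycles starting fully progression-free."""
    if horizon < 1:
        raise MarkovError("horizon must be at least one cycle")
    pFTD = mortality.per_cycle(cycle_days)

    n_pfs = np.empty(horizon + 1)
    n_pd = np.empty(horizon + 1)
    n_dead = np.empty(horizon + 1)
    new_dead = np.zeros(horizon + 1)
    n_pfs[0], n_pd[0], n_dead[0] = 1.0, 0.0, 0.0
    clamp_events = 0

    for t in range(1, horizon + 1):
        row = transition_row(
            t, S_pfs, S_os, (n_pfs[t - 1], n_pd[t - 1]), pFTD, cycle_days
        )
        clamp_events += row.clamped
        died = n_pfs[t - 1] * row.pFTD + n_pd[t - 1] * row.pPTD
        n_pfs[t] = n_pfs[t - 1] * row.pFTF
        n_pd[t] = n_pfs[t - 1] * row.pFTP + n_pd[t - 1] * row.pPTP
        n_dead[t] = n_dead[t - 1] + died
        new_dead[t] = died
    if clamp_events:
        logger.warning("cohort trace required %d probability clamp(s)", clamp_events)
    return CohortTrace(n_pfs, n_pd, n_dead, new_dead, cycle_days, clamp_events)
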