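"""Costing, discounted accumulation of costs/life-years/QALYs, and ICERs.

Accrual convention: cycles are indexed k = 0..H-1; during cycle k the
cohort occupies the state reached after k transitions (trace row k) and
all per-cycle quantities are discounted by (1+r)^(-k*cycle_days/365.25).
Terminal care attaches to the deaths occurring during the transition into
row t (discounted at cycle t).  Adverse-event costs and QALY decrements
are incidence-weighted one-off amounts applied at cycle 1.

No half-cycle correction is applied by default; ``half_cycle=True``
switches to the life-table convention (average of start- and end-of-cycle
occupancy).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .markov import DAYS_PER_YEAR, CohortTrace

__all__ = [
    "DrugComponent",
    "RegimenSpec",
    "RecurringCost",
    "UnitCosts",
    "UtilitySet",
    "AEProfile",
    "PatientProfile",
    "EconResult",
    "ICERResult",
    "drug_cost_per_cycle",
    "discount_factor",
    "accumulate_outcomes",
    "icer",
    "apply_price_discount",
]


class EconomicsError(ValueError):
    """Invalid costing configuration."""


@dataclass(frozen=True)
class PatientProfile:
    """Reference patient used for dose calculations."""

    bsa_m2: float = 1.72
    weight_kg: float = 65.0


@dataclass(frozen=True)
class DrugComponent:
    """One drug in a regimen.

    ``dose_rule`` is one of ``flat`` (mg per administration), ``per_m2``
    (mg/m2, scaled by body surface area) or ``per_kg`` (mg/kg).  ``weight``
    supports regimen mixtures (cohort fraction receiving this backbone).
    ``max_cycles`` caps the number of treated cycles (None = unlimited).
    """

    name: str
    dose_rule: str
    dose_mg: float
    admins_per_cycle: int = 1
    weight: float = 1.0
    max_cycles: Optional[int] = None

    def __post_init__(self):
        if self.dose_rule not in ("flat", "per_m2", "per_kg"):
            raise EconomicsError(f"unknown dose rule {self.dose_rule!r}")
        if self.dose_mg <= 0 or self.admins_per_cycle < 1:
            raise EconomicsError("doses and administrations must be positive")
        if not 0.0 <= self.weight <= 1.0:
            raise EconomicsError("component weight must lie in [0, 1]")
        if self.max_cycles is not None and self.max_cycles < 1:
            raise EconomicsError("max_cycles must be >= 1 or None")

    def mg_per_cycle(self, patient: PatientProfile) -> float:
        per_admin = self.dose_mg
        if self.dose_rule == "per_m2":
            per_admin *= patient.bsa_m2
        elif self.dose_rule == "per_kg":
            per_admin *= patient.weight_kg
        return per_admin * self.admins_per_cycle


@dataclass(frozen=True)
class RegimenSpec:
    """An arm's drug components; treatment is gated to the PFS state."""

    components: tuple

    def __post_init__(self):
        object.__setattr__(self, "components", tuple(self.components))


@dataclass(frozen=True)
class RecurringCost:
    """A per-cycle cost tied to a health state.

    ``state`` is one of ``pfs``, ``pd`` or ``alive``; ``max_cycles``
    optionally restricts accrual to the first cycles (e.g. supportive care
    given only during active chemotherapy).
    """

    amount: float
    state: str = "pfs"
    max_cycles: Optional[int] = None

    def __post_init__(self):
        if self.amount < 0:
            raise EconomicsError("recurring cost must be non-negative")
        if self.state not in ("pfs", "pd", "alive"):
            raise EconomicsError(f"unknown cost state {self.state!r}")


@dataclass
class UnitCosts:
    """Unit prices in 2024 US$."""

    drug_prices_per_100mg: dict
    supportive: RecurringCost
    followup: RecurringCost
    terminal_care: float
    ae_event_costs: dict

    def __post_init__(self):
        for name, price in self.drug_prices_per_100mg.items():
            if price < 0:
                raise EconomicsError(f"negative price for {name}")
        if self.terminal_care < 0:
            raise EconomicsError("negative terminal care cost")
        for name, c in self.ae_event_costs.items():
            if c < 0:
                raise EconomicsError(f"negative AE cost for {name}")


@dataclass
class UtilitySet:
    """Health-state utilities and adverse-event disutilities.

    Disutilities are stored as absolute one-off decrements (per event).
    """

    pfs: float = 0.76
    pd: float = 0.55
    death: float = 0.0
    ae_disutilities: dict = field(default_factory=dict)

    def __post_init__(self):
        for u in (self.pfs, self.pd):
            if not 0.0 <= u <= 1.0:
                raise EconomicsError("state utilities must lie in [0, 1]")
        if self.death != 0.0:
            raise EconomicsError("death utility must be 0")
        self.ae_disutilities = {k: abs(v) for k, v in self.ae_disutilities.items()}


@dataclass(frozen=True)
class AEProfile:
    """Grade>=3 adverse-event incidences for one arm."""

    incidence: dict

    def __post_init__(self):
        for name, p in self.incidence.items():
            if not 0.0 <= p <= 1.0:
                raise EconomicsError(f"AE incidence for {name} outside [0, 1]")


@dataclass(frozen=True)
class EconResult:
    cost: float
    life_years: float
    qalys: float

    def __post_init__(self):
        if self.cost < 0 or self.life_years < 0:
            raise EconomicsError("negative accumulated totals")


def discount_factor(cycle, annual_rate: float, cycle_days: float = 21.0):
    """Discount factor (1+r)^(-cycle*cycle_days/365.25); vectorized."""
    if annual_rate < 0:
        raise EconomicsError("discount rate must be non-negative")
    cycle = np.asarray(cycle, dtype=float)
    return (1.0 + annual_rate) ** (-cycle * cycle_days / DAYS_PER_YEAR)


def drug_cost_per_cycle(
    regimen: RegimenSpec,
    costs: UnitCosts,
    cycle: int,
    state: str,
    patient: PatientProfile = PatientProfile(),
) -> float:
    """Per-person drug cost for one cycle in a given state.

    Returns 0 outside the PFS treatment gate or beyond a component's
    treated-cycle cap.  Pricing is linear in mg (no vial rounding).
    """
    if state != "pfs":
        return 0.0
    total = 0.0
    for comp in regimen.components:
        if comp.max_cycles is not None and cycle >= comp.max_cycles:
            continue
        if comp.name not in costs.drug_prices_per_100mg:
            raise EconomicsError(f"no unit price configured for drug {comp.name!r}")
        price = costs.drug_prices_per_100mg[comp.name]
        total += comp.weight * comp.mg_per_cycle(patient) / 100.0 * price
    return total


def _state_occ(trace_slice, state: str):
    n_pfs, n_pd = trace_slice
    if state == "pfs":
        return n_pfs
    if state == "pd":
        return n_pd
    return n_pfs + n_pd


def accumulate_outcomes(
    trace: CohortTrace,
    regimen: RegimenSpec,
    costs: UnitCosts,
    utilities: UtilitySet,
    ae: AEProfile,
    rate: float,
    patient: PatientProfile = PatientProfile(),
    half_cycle: bool = False,
) -> EconResult:
    """Accumulate discounted cost, life-years and QALYs over a cohort trace."""
    H = trace.n_cycles
    cyc_years = trace.cycle_days / DAYS_PER_YEAR

    if half_cycle:
        n_pfs = 0.5 * (trace.n_pfs[:H] + trace.n_pfs[1:H + 1])
        n_pd = 0.5 * (trace.n_pd[:H] + trace.n_pd[1:H + 1])
    else:
        n_pfs = trace.n_pfs[:H]
        n_pd = trace.n_pd[:H]
    k = np.arange(H)
    df = discount_factor(k, rate, trace.cycle_days)
    df_t = discount_factor(np.arange(1, H + 1), rate, trace.cycle_days)

    # drug acquisition: per-cycle amounts are cycle-dependent only through caps
    drug_amounts = np.array(
        [drug_cost_per_cycle(regimen, costs, int(c), "pfs", patient) for c in k]
    )
    cost = float((drug_amounts * n_pfs * df).sum())

    for rec in (costs.supportive, costs.followup):
        occ = _state_occ((n_pfs, n_pd), rec.state)
        amounts = np.full(H, rec.amount)
        if rec.max_cycles is not None:
            amounts[rec.max_cycles:] = 0.0
        cost += float((amounts * occ * df).sum())

    cost += costs.terminal_care * float((trace.new_dead[1:H + 1] * df_t).sum())

    df1 = float(discount_factor(1, rate, trace.cycle_days))
    ae_cost = sum(
        ae.incidence.get(name, 0.0) * c for name, c in costs.ae_event_costs.items()
    )
    ae_dis = sum(
        ae.incidence.get(name, 0.0) * d for name, d in utilities.ae_disutilities.items()
    )
    cost += ae_cost * df1

    life_years = float(((n_pfs + n_pd) * cyc_years * df).sum())
    qalys = float(
        ((utilities.pfs * n_pfs + utilities.pd * n_pd) * cyc_years * df).sum()
    )
    qalys -= ae_dis * df1
    return EconResult(cost, life_years, max(qalys, 0.0))


@dataclass(frozen=True)
class ICERResult:
    delta_cost: float
    delta_qaly: float
    icer: Optional[float]
    dominance: Optional[str] = None  # "dominant" | "dominated" | "equivalent"


def icer(intervention: EconResult, comparator: EconResult) -> ICERResult:
    """Incremental cost-effectiveness ratio with dominance flags.

    Sign-discordant or zero-QALY differences are reported as flags, never
    as a misleading ratio.
    """
    dc = intervention.cost - comparator.cost
    dq = intervention.qalys - comparator.qalys
    if dq == 0.0:
        flag = "dominated" if dc > 0 else ("dominant" if dc < 0 else "equivalent")
        return ICERResult(dc, dq, None, flag)
    if dq > 0 and dc <= 0:
        return ICERResult(dc, dq, None, "dominant")
    if dq < 0 and dc >= 0:
        return ICERResult(dc, dq, None, "dominated")
    return ICERResult(dc, dq, dc / dq, None)


def apply_price_discount(config, drug: str, fraction: float):
    """Return a config copy with one drug's unit price cut by ``fraction``."""
    if not 0.0 <= fraction <= 1.0:
        raise EconomicsError("price-discount fraction must lie in [0, 1]")
    new = copy.deepcopy(config)
    prices = new.costs.drug_prices_per_100mg
    if drug not in prices:
        raise EconomicsError(f"unknown drug {drug!r}")
    prices[drug] = prices[drug] * (1.0 - fraction)
    return new
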