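"""Run a configured two-arm analysis: traces, discounted totals, ICER."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .config import AnalysisConfig, StrategyConfig
from .economics import EconResult, ICERResult, accumulate_outcomes, icer
from .markov import BackgroundMortality, CohortTrace, run_cohort

__all__ = ["ArmResult", "AnalysisResult", "run_strategy", "run_analysis"]


@dataclass
class ArmResult:
    name: str
    trace: CohortTrace
    econ: EconResult


@dataclass
class AnalysisResult:
    intervention: ArmResult
    comparator: ArmResult
    incremental: ICERResult

    def summary(self) -> pd.DataFrame:
        rows = []
        for arm in (self.intervention, self.comparator):
            rows.append({
                "strategy": arm.name,
                "cost": arm.econ.cost,
                "life_years": arm.econ.life_years,
                "qalys": arm.econ.qalys,
            })
        df = pd.DataFrame(rows)
        df["incremental_cost"] = [self.incremental.delta_cost, np.nan]
        df["incremental_qaly"] = [self.incremental.delta_qaly, np.nan]
        df["icer"] = [
            self.incremental.icer if self.incremental.icer is not None
            else self.incremental.dominance,
            np.nan,
        ]
        return df


def build_trace(config: AnalysisConfig, strategy: StrategyConfig) -> CohortTrace:
    return run_cohort(
        strategy.pfs_curve,
        strategy.os_curve,
        BackgroundMortality(config.settings.background_mortality_annual),
        config.settings.horizon_cycles,
        config.settings.cycle_days,
    )


def run_strategy(
    config: AnalysisConfig,
    which: str,
    trace: Optional[CohortTrace] = None,
) -> ArmResult:
    """Run one arm; an externally computed trace can be reused (PSA fast path)."""
    strategy = config.strategy(which)
    if trace is None:
        trace = build_trace(config, strategy)
    econ = accumulate_outcomes(
        trace,
        strategy.regimen,
        config.costs,
        config.utilities,
        strategy.ae,
        config.settings.discount_rate,
        config.patient,
        half_cycle=config.settings.half_cycle_correction,
    )
    return ArmResult(strategy.name, trace, econ)


def run_analysis(
    config: AnalysisConfig,
    traces: Optional[dict] = None,
) -> AnalysisResult:
    """Run both arms and compute the incremental comparison."""
    traces = traces or {}
    arm_i = run_strategy(config, "intervention", traces.get("intervention"))
    arm_c = run_strategy(config, "comparator", traces.get("comparator"))
    return AnalysisResult(arm_i, arm_c, icer(arm_i.econ, arm_c.econ))
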