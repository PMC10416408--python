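"""National budget impact of rolling out an intervention for 15 years.

A static cohort of prehypertensive people (no new entrants) is filtered by
age band and, optionally, by an annual CVE-risk threshold. Per single year
of age, paired per-capita Markov runs (intervention vs non-intervention)
over the horizon give the per-year programme cost and the per-year medical
cost saving; both are scaled by the eligible count and the compliance
fraction and left undiscounted, as is standard for affordability analyses.
Compliance gates both the BP effect and the variable programme cost; any
one-time first-year design surcharge is charged on every enrolled person.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd

from .cea import ModelContext, accumulate_costs, run_strategy_trace
from .epi_inputs import annual_cve_probabilities, CVE_EVENTS
from .interventions import InterventionProfile
from .model_core import PREHYPERTENSION

AGE_BANDS = {
    "45-49": (45, 49),
    "50-54": (50, 54),
    "55-59": (55, 59),
    "60-64": (60, 64),
    "all": (45, 64),
}

DEFAULT_HORIZON = 15


@dataclass(frozen=True)
class BIAStrategy:
    """One rollout configuration: who is enrolled, for how long, how well."""

    age_band: str = "all"
    high_risk_only: bool = False
    risk_threshold: float | None = None  # annual combined CVE probability
    duration: int = DEFAULT_HORIZON
    compliance: float = 1.0
    horizon: int = DEFAULT_HORIZON

    def __post_init__(self) -> None:
        if self.age_band not in AGE_BANDS:
            raise ValueError(f"unknown age band {self.age_band!r}")
        if not (0.0 < self.compliance <= 1.0):
            raise ValueError("compliance must lie in (0, 1]")
        if not (0 <= self.duration <= self.horizon):
            raise ValueError("duration must lie within the simulation horizon")


@dataclass(frozen=True)
class BIAResult:
    strategy: BIAStrategy
    eligible: float
    program_cost: np.ndarray  # per-year, length horizon
    medical_cost_saving: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.program_cost < 0):
            raise ValueError("program cost cannot be negative")
        if len(self.program_cost) != self.strategy.horizon:
            raise ValueError("cost series length must equal the horizon")

    @property
    def cumulative_program_cost(self) -> float:
        return float(self.program_cost.sum())

    @property
    def cumulative_saving(self) -> float:
        return float(self.medical_cost_saving.sum())

    def to_frame(self) -> pd.DataFrame:
        years = np.arange(1, self.strategy.horizon + 1)
        return pd.DataFrame(
            {
                "year": years,
                "program_cost": self.program_cost,
                "medical_cost_saving": self.medical_cost_saving,
                "cumulative_program_cost": np.cumsum(self.program_cost),
                "cumulative_saving": np.cumsum(self.medical_cost_saving),
            }
        )


def combined_cve_risk(age: float, ctx: ModelContext) -> float:
    """Annual probability of any CVE for a prehypertensive person this age."""
    p = annual_cve_probabilities(age, PREHYPERTENSION, ctx.cohort.sbp, ctx.risk)
    surv = 1.0
    for e in CVE_EVENTS:
        surv *= 1.0 - p[e]
    return 1.0 - surv


def median_risk_threshold(demographics: pd.DataFrame, strategy: BIAStrategy, ctx: ModelContext) -> float:
    """Count-weighted median annual CVE risk over the age band's strata."""
    lo, hi = AGE_BANDS[strategy.age_band]
    band = demographics[(demographics["age"] >= lo) & (demographics["age"] <= hi)]
    risks = np.array([combined_cve_risk(a, ctx) for a in band["age"]])
    order = np.argsort(risks)
    w = band["prehypertensive_count"].to_numpy()[order]
    cum = np.cumsum(w) / w.sum()
    return float(risks[order][np.searchsorted(cum, 0.5)])


def eligible_strata(
    demographics: pd.DataFrame, strategy: BIAStrategy, ctx: ModelContext
) -> pd.DataFrame:
    """Per-age eligible counts after the band and risk filters."""
    lo, hi = AGE_BANDS[strategy.age_band]
    band = demographics[(demographics["age"] >= lo) & (demographics["age"] <= hi)].copy()
    if strategy.high_risk_only:
        thr = strategy.risk_threshold
        if thr is None:
            thr = median_risk_threshold(demographics, strategy, ctx)
        keep = [combined_cve_risk(a, ctx) > thr for a in band["age"]]
        band = band[keep]
    return band.reset_index(drop=True)


def eligible_population(
    demographics: pd.DataFrame, strategy: BIAStrategy, ctx: ModelContext
) -> float:
    """Total enrolled population under the strategy's filters."""
    band = eligible_strata(demographics, strategy, ctx)
    total = float(band["prehypertensive_count"].sum())
    if total == 0:
        warnings.warn("no eligible population under this strategy; zero-cost result")
    return total


def _per_capita_streams(
    ctx: ModelContext, intervention: InterventionProfile, horizon: int
) -> tuple:
    """(programme cost, medical cost) per enrolled person per year."""
    trace = run_strategy_trace(ctx, intervention, horizon=horizon)
    null = intervention.with_duration(0)  # zero programme, same accounting
    medical = accumulate_costs(trace, ctx.params, null)
    total = accumulate_costs(trace, ctx.params, intervention)
    return total - medical, medical


def run_bia(
    strategy: BIAStrategy,
    intervention: InterventionProfile,
    demographics: pd.DataFrame,
    ctx: ModelContext,
) -> BIAResult:
    """Programme cost vs medical cost saving over the rollout horizon.

    Medical cost saving per year is the reduction, relative to
    non-intervention, in the medical costs of every state downstream of
    prehypertension (management, acute and post-CVE care, end of life),
    summed over the eligible strata.
    """
    iv = intervention.with_duration(strategy.duration)
    h = strategy.horizon
    band = eligible_strata(demographics, strategy, ctx)
    program = np.zeros(h)
    saving = np.zeros(h)
    from dataclasses import replace as _rep

    for _, row in band.iterrows():
        n = float(row["prehypertensive_count"])
        stratum_ctx = _rep(ctx, cohort=_rep(ctx.cohort, age_mean=float(row["age"])))
        prog_iv, med_iv = _per_capita_streams(stratum_ctx, iv, h)
        _, med_ni = _per_capita_streams(stratum_ctx, iv.with_duration(0), h)
        design_extra = np.zeros(h)
        design_extra[0] = max(0.0, iv.first_year_cost - iv.recurring_annual_cost)
        # variable cost and effect only for the compliant fraction; the
        # one-time design surcharge is charged on all enrolled
        variable = prog_iv.copy()
        variable[0] -= design_extra[0]
        program += n * (strategy.compliance * variable + design_extra)
        saving += n * strategy.compliance * (med_ni - med_iv)
    return BIAResult(
        strategy=strategy,
        eligible=float(band["prehypertensive_count"].sum()),
        program_cost=program,
        medical_cost_saving=saving,
    )


def strategy_grid(
    strategies: list,
    intervention: InterventionProfile,
    demographics: pd.DataFrame,
    ctx: ModelContext,
) -> pd.DataFrame:
    """Cumulative cost/saving comparison table across rollout strategies."""
    if not strategies:
        raise ValueError("at least one strategy required")
    rows = []
    for s in strategies:
        r = run_bia(s, intervention, demographics, ctx)
        rows.append(
            {
                "age_band": s.age_band,
                "high_risk_only": s.high_risk_only,
                "duration": s.duration,
                "compliance": s.compliance,
                "eligible": r.eligible,
                "cumulative_program_cost": r.cumulative_program_cost,
                "cumulative_saving": r.cumulative_saving,
            }
        )
    return pd.DataFrame(rows)
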