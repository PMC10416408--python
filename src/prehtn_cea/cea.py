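"""Cost-effectiveness accounting and the dominance frontier.

A strategy evaluation propagates the cohort to age 100 under one
intervention, accumulates discounted costs (programme, hypertension
management, acute and post-CVE care, end-of-life) and discounted QALYs, and
records the mean undiscounted sojourn in the prehypertension state ("Trans",
the average time to hypertension). The frontier analysis classifies
strategies as strongly dominated, extended dominated or on the
cost-effectiveness frontier and reports the ICER ladder of the survivors.

Conventions: annual cycles indexed from 1; cycle-1 cash flows undiscounted
(divisor ``(1+r)**(t-1)``); person-time for cycle ``t`` is the start-of-cycle
occupancy; no half-cycle correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .epi_inputs import CohortProfile, LifeTable, RiskModel, TERMINAL_AGE
from .interventions import BPLevel, InterventionProfile, effective_bp, intervention_cost
from .model_core import (
    DEATH,
    HYPERTENSION,
    MarkovTrace,
    PREHYPERTENSION,
    STATES,
    assemble_transition_matrix,
    propagate,
)

log = logging.getLogger(__name__)

FRONTIER = "frontier"
STRONGLY_DOMINATED = "strongly_dominated"
EXTENDED_DOMINATED = "extended_dominated"


class UndefinedICER(ZeroDivisionError):
    """Signalled when an ICER is requested for a zero QALY difference."""


@dataclass(frozen=True)
class ParameterSet:
    """Costs, utilities, discounting and willingness-to-pay thresholds.

    Monetary values are 2021 USD per person-year (``end_of_life_cost`` per
    death event). ``distributions`` carries the uncertainty metadata used by
    the sensitivity analyses, keyed by dotted parameter id.
    """

    state_costs: dict
    end_of_life_cost: float
    utilities: dict
    discount_rate: float = 0.05
    wtp: float = 12_728.0
    wtp_high: float = 38_184.0
    distributions: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for s, u in self.utilities.items():
            if not (0.0 <= u <= 1.0):
                raise ValueError(f"utility for {s} outside [0, 1]: {u}")
        if self.utilities.get(DEATH, 0.0) != 0.0:
            raise ValueError("death utility must be 0")
        if self.utilities[PREHYPERTENSION] < self.utilities[HYPERTENSION]:
            raise ValueError("prehypertension utility must be >= hypertension utility")
        if not (0.0 <= self.discount_rate <= 0.08):
            raise ValueError("discount rate outside [0, 0.08]")

    def utility_vector(self) -> np.ndarray:
        return np.array([self.utilities[s] for s in STATES])

    def medical_cost_vector(self) -> np.ndarray:
        """Per-person-year medical cost by state (no programme costs)."""
        out = np.zeros(len(STATES))
        for s, c in self.state_costs.items():
            out[STATES.index(s)] = c
        return out


@dataclass(frozen=True)
class ModelContext:
    """Everything one strategy evaluation needs besides the intervention."""

    cohort: CohortProfile
    life_table: LifeTable
    risk: RiskModel
    params: ParameterSet
    #: five-year progression target behind the calibrated intercept; kept so
    #: sensitivity analyses can re-solve the intercept when they vary it
    progression_target: float = 0.40

    @property
    def start_age(self) -> int:
        return int(round(self.cohort.age_mean))

    @property
    def lifetime_horizon(self) -> int:
        """Cycles until the cohort's age passes the terminal age."""
        return TERMINAL_AGE + 1 - self.start_age

    @property
    def baseline_bp(self) -> BPLevel:
        return BPLevel(self.cohort.sbp, self.cohort.dbp)


@dataclass(frozen=True)
class StrategyResult:
    name: str
    total_cost: float
    total_qalys: float
    trans: float

    def __post_init__(self) -> None:
        if self.trans < 0:
            raise ValueError("mean time to hypertension cannot be negative")


@dataclass(frozen=True)
class FrontierResult:
    """Dominance classification and the ICER ladder of frontier strategies."""

    classification: dict
    ladder: list

    def frontier_names(self) -> list:
        return [n for n, c in self.classification.items() if c == FRONTIER]


# ---------------------------------------------------------------------------
# Accounting
# ---------------------------------------------------------------------------


def discount_stream(values, rate: float) -> float:
    """Present value of a per-cycle stream, cycles indexed from 1.

    ``total = sum_t values[t] / (1+rate)**(t-1)``: the first cycle's flow is
    taken at face value.
    """
    if rate < 0:
        raise ValueError("discount rate must be non-negative")
    v = np.asarray(values, dtype=float)
    t = np.arange(len(v))
    return float(np.sum(v / (1.0 + rate) ** t))


def accumulate_costs(
    trace: MarkovTrace, params: ParameterSet, intervention: InterventionProfile
) -> np.ndarray:
    """Undiscounted per-cycle cost stream for one evaluated strategy.

    Per cycle: programme cost on prehypertensive person-time, state medical
    costs on person-time, and the end-of-life cost on the newly dead.
    """
    for s in params.state_costs:
        if s not in STATES:
            raise KeyError(f"state cost for unknown state {s!r}")
    med = params.medical_cost_vector()
    py = trace.person_years
    n = trace.n_cycles
    iv = np.array(
        [intervention_cost(intervention, t, PREHYPERTENSION) for t in range(1, n + 1)]
    )
    pre = py[:, STATES.index(PREHYPERTENSION)]
    return py @ med + iv * pre + params.end_of_life_cost * trace.death_inflow


def accumulate_qalys(trace: MarkovTrace, params: ParameterSet) -> np.ndarray:
    """Undiscounted per-cycle QALY stream: occupancy-weighted utilities."""
    return trace.person_years @ params.utility_vector()


def mean_time_to_hypertension(trace: MarkovTrace) -> float:
    """Undiscounted expected person-years spent in prehypertension.

    This is the unconditional mean sojourn before leaving the initial state
    by any route (the "Trans" summary)."""
    return float(trace.person_years[:, STATES.index(PREHYPERTENSION)].sum())


# ---------------------------------------------------------------------------
# Strategy evaluation pipeline
# ---------------------------------------------------------------------------


def build_cycle_matrices(
    ctx: ModelContext, intervention: InterventionProfile, horizon: int | None = None
):
    """Per-cycle transition matrices for one strategy over the horizon."""
    h = ctx.lifetime_horizon if horizon is None else horizon
    mats = []
    for t in range(1, h + 1):
        age = ctx.start_age + t - 1
        bp = effective_bp(ctx.baseline_bp, intervention, t, PREHYPERTENSION)
        mats.append(
            assemble_transition_matrix(
                t, age, ctx.risk, bp, ctx.life_table, sex_mix=ctx.cohort.female_fraction
            )
        )
    return mats


def run_strategy_trace(
    ctx: ModelContext, intervention: InterventionProfile, horizon: int | None = None
) -> MarkovTrace:
    """Propagate a pure prehypertensive cohort under one strategy."""
    mats = build_cycle_matrices(ctx, intervention, horizon)
    initial = np.zeros(len(STATES))
    initial[STATES.index(PREHYPERTENSION)] = 1.0
    return propagate(initial, mats)


def evaluate_strategy(
    ctx: ModelContext,
    intervention: InterventionProfile,
    duration: int | None = "base",
    horizon: int | None = None,
) -> StrategyResult:
    """Full pipeline for one strategy: trace, accounting, discounting.

    ``duration`` overrides the intervention's implementation duration
    (``"base"`` keeps the profile's own setting).
    """
    iv = intervention if duration == "base" else intervention.with_duration(duration)
    trace = run_strategy_trace(ctx, iv, horizon)
    costs = accumulate_costs(trace, ctx.params, iv)
    qalys = accumulate_qalys(trace, ctx.params)
    r = ctx.params.discount_rate
    return StrategyResult(
        name=iv.name,
        total_cost=discount_stream(costs, r),
        total_qalys=discount_stream(qalys, r),
        trans=mean_time_to_hypertension(trace),
    )


def evaluate_strategies(ctx: ModelContext, interventions: dict, **kw) -> list:
    return [evaluate_strategy(ctx, iv, **kw) for iv in interventions.values()]


# ---------------------------------------------------------------------------
# ICERs and the dominance frontier
# ---------------------------------------------------------------------------


def icer(a: StrategyResult, b: StrategyResult) -> float:
    """Incremental cost per QALY of ``a`` relative to ``b``.

    Raises :class:`UndefinedICER` on a zero QALY difference rather than
    returning an infinity.
    """
    dq = a.total_qalys - b.total_qalys
    if dq == 0.0:
        raise UndefinedICER(f"zero QALY difference between {a.name} and {b.name}")
    return (a.total_cost - b.total_cost) / dq


def frontier_analysis(results: list) -> FrontierResult:
    """Classify strategies and build the strictly increasing ICER ladder.

    Strategies are sorted by cost; any strategy with another no more costly
    and no less effective alternative (strict in one) is strongly dominated.
    Among the survivors, a strategy whose incremental ICER is not below that
    of the next more-effective option is removed as extended dominated, and
    the ladder is recomputed until it is strictly increasing.
    """
    if len(results) < 2:
        raise ValueError("frontier analysis needs at least 2 strategies")
    order = sorted(results, key=lambda r: (r.total_cost, -r.total_qalys, r.name))
    classification = {}

    seen = {}
    for r in order:
        key = (r.total_cost, r.total_qalys)
        if key in seen:
            log.warning(
                "duplicate (cost, QALY) pair for %s and %s; keeping %s by name order",
                seen[key].name, r.name, min(seen[key].name, r.name),
            )
            first, second = sorted([seen[key], r], key=lambda x: x.name)
            classification[second.name] = STRONGLY_DOMINATED
            seen[key] = first
        else:
            seen[key] = r

    for r in order:
        if r.name in classification:
            continue
        for s in order:
            if s is r:
                continue
            if (
                s.total_cost <= r.total_cost
                and s.total_qalys >= r.total_qalys
                and (s.total_cost < r.total_cost or s.total_qalys > r.total_qalys)
            ):
                classification[r.name] = STRONGLY_DOMINATED
                break

    surv = [r for r in order if r.name not in classification]
    while len(surv) >= 3:
        icers = [icer(surv[i], surv[i - 1]) for i in range(1, len(surv))]
        removed = False
        for k in range(len(icers) - 1):
            if icers[k] >= icers[k + 1]:
                classification[surv[k + 1].name] = EXTENDED_DOMINATED
                del surv[k + 1]
                removed = True
                break
        if not removed:
            break

    for r in surv:
        classification[r.name] = FRONTIER
    ladder = [
        {
            "from": surv[i - 1].name,
            "to": surv[i].name,
            "delta_cost": surv[i].total_cost - surv[i - 1].total_cost,
            "delta_qalys": surv[i].total_qalys - surv[i - 1].total_qalys,
            "icer": icer(surv[i], surv[i - 1]),
        }
        for i in range(1, len(surv))
    ]
    return FrontierResult(classification=classification, ladder=ladder)


def results_table(results: list, frontier: FrontierResult | None = None) -> pd.DataFrame:
    """Base-case table: strategies by cost with adjacent-pair increments.

    Mirrors the published layout: Trans, Costs, QALYs, ΔCosts, ΔQALYs and
    the ICER between cost-adjacent strategies, plus the dominance label.
    """
    if frontier is None:
        frontier = frontier_analysis(results)
    order = sorted(results, key=lambda r: (r.total_cost, -r.total_qalys, r.name))
    rows = []
    prev = None
    for r in order:
        row = {
            "strategy": r.name,
            "trans": r.trans,
            "cost": r.total_cost,
            "qalys": r.total_qalys,
            "delta_cost": np.nan,
            "delta_qalys": np.nan,
            "icer": np.nan,
            "classification": frontier.classification[r.name],
        }
        if prev is not None:
            row["delta_cost"] = r.total_cost - prev.total_cost
            row["delta_qalys"] = r.total_qalys - prev.total_qalys
            try:
                row["icer"] = icer(r, prev)
            except UndefinedICER:
                row["icer"] = np.nan
        rows.append(row)
        prev = r
    return pd.DataFrame(rows)
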