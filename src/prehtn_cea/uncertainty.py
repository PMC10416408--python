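"""Deterministic and probabilistic sensitivity analyses and duration scenarios.

Parameters are addressed by dotted ids spanning the whole model context:

* ``discount_rate``
* ``utility.<state>`` / ``cost.<state>`` / ``cost.end_of_life``
* ``intervention.<name>.annual_cost`` / ``effect.<name>.delta_sbp``
  (the effect id carries the SBP-reduction magnitude, >= 0)
* ``risk.progression_5yr`` (five-year anchor; the progression intercept is
  re-solved whenever it moves) / ``risk.cve_base.<event>`` /
  ``risk.case_fatality.<event>`` / ``risk.post_excess.<event>``

One-way DSA re-runs the full pipeline at each bound; the PSA draws every
parameter from its prior (beta for probabilities and utilities, gamma for
costs, normal truncated at zero for effect magnitudes), with hyperparameters
moment-matched from the mean and the 95% interval implied by the bounds.
Cost-effectiveness acceptability curves use per-draw net-monetary-benefit
maximisation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .cea import (
    ModelContext,
    ParameterSet,
    STRONGLY_DOMINATED,
    evaluate_strategy,
    frontier_analysis,
    icer,
)
from .epi_inputs import calibrate_progression_intercept
from .model_core import HYPERTENSION, PREHYPERTENSION

log = logging.getLogger(__name__)

DEFAULT_WTP_GRID = np.arange(0.0, 50_000.0 + 1, 500.0)


class InfeasibleDistribution(ValueError):
    """Moment matching cannot produce a valid distribution for a parameter."""


@dataclass(frozen=True)
class Distribution:
    """Prior for one parameter: family, mean and (low, high) bounds.

    Bounds are read as a 95% interval; the implied standard deviation is
    half the width divided by 1.96. Zero-width bounds denote a degenerate
    (fixed) parameter.
    """

    family: str
    mean: float
    low: float
    high: float

    def __post_init__(self) -> None:
        if self.family not in ("beta", "gamma", "normal"):
            raise ValueError(f"unknown distribution family {self.family!r}")
        if self.high < self.low:
            raise ValueError("distribution bounds reversed")

    @property
    def sd(self) -> float:
        return (self.high - self.low) / (2.0 * 1.96)

    @property
    def degenerate(self) -> bool:
        return self.high == self.low

    def sample(self, rng: np.random.Generator, param_id: str = "?") -> float:
        if self.degenerate:
            return self.mean
        m, s = self.mean, self.sd
        if self.family == "beta":
            if not (0.0 < m < 1.0):
                raise InfeasibleDistribution(f"{param_id}: beta mean {m} outside (0, 1)")
            nu = m * (1.0 - m) / s**2 - 1.0
            if nu <= 0:
                raise InfeasibleDistribution(
                    f"{param_id}: variance {s**2:.4g} too large for beta mean {m}"
                )
            return float(rng.beta(m * nu, (1.0 - m) * nu))
        if self.family == "gamma":
            if m <= 0:
                raise InfeasibleDistribution(f"{param_id}: gamma mean {m} must be > 0")
            shape = (m / s) ** 2
            return float(rng.gamma(shape, s**2 / m))
        return float(rng.normal(m, s))


# ---------------------------------------------------------------------------
# Parameter overrides on a (context, interventions) pair
# ---------------------------------------------------------------------------


_clip_warned: set = set()


def _clip(value: float, lo: float, hi: float, param_id: str) -> float:
    clipped = min(max(value, lo), hi)
    if clipped != value:
        # warn once per parameter, then demote to debug (PSA draws clip often)
        level = logging.DEBUG if param_id in _clip_warned else logging.WARNING
        _clip_warned.add(param_id)
        log.log(level, "%s: value %.6g clipped to [%g, %g]", param_id, value, lo, hi)
    return clipped


def apply_override(
    ctx: ModelContext, interventions: dict, param_id: str, value: float
) -> tuple:
    """Return a new (context, interventions) with one parameter replaced.

    Values violating the parameter's support are clipped with a logged
    warning rather than rejected, so DSA bounds such as utility + 20% remain
    usable.
    """
    parts = param_id.split(".")
    p = ctx.params
    if param_id == "discount_rate":
        v = _clip(value, 0.0, 0.08, param_id)
        return replace(ctx, params=replace(p, discount_rate=v)), interventions
    if parts[0] == "utility":
        state = parts[1]
        hi = 1.0
        lo = 0.0
        # preserve the prehypertension >= hypertension ordering by clipping
        if state == HYPERTENSION:
            hi = p.utilities[PREHYPERTENSION]
        elif state == PREHYPERTENSION:
            lo = p.utilities[HYPERTENSION]
        u = dict(p.utilities)
        u[state] = _clip(value, lo, hi, param_id)
        return replace(ctx, params=replace(p, utilities=u)), interventions
    if parts[0] == "cost":
        v = _clip(value, 0.0, np.inf, param_id)
        if parts[1] == "end_of_life":
            return replace(ctx, params=replace(p, end_of_life_cost=v)), interventions
        costs = dict(p.state_costs)
        if parts[1] not in costs:
            raise KeyError(f"unknown state cost {param_id!r}")
        costs[parts[1]] = v
        return replace(ctx, params=replace(p, state_costs=costs)), interventions
    if parts[0] == "intervention":
        name = parts[1]
        v = _clip(value, 0.0, np.inf, param_id)
        ivs = dict(interventions)
        ivs[name] = replace(ivs[name], recurring_annual_cost=v, first_year_cost=v)
        return ctx, ivs
    if parts[0] == "effect":
        name = parts[1]
        mag = _clip(value, 0.0, np.inf, param_id)
        ivs = dict(interventions)
        ivs[name] = replace(ivs[name], delta_sbp=-mag)
        return ctx, ivs
    if param_id == "risk.progression_5yr":
        target = _clip(value, 0.01, 0.99, param_id)
        risk = calibrate_progression_intercept(
            ctx.risk,
            target=target,
            start_age=ctx.cohort.age_mean,
            sbp=ctx.cohort.sbp,
            sex_mix=ctx.cohort.female_fraction,
            years=5,
        )
        return replace(ctx, risk=risk, progression_target=target), interventions
    if parts[0] == "risk" and parts[1] in ("cve_base", "case_fatality", "post_excess"):
        event = parts[2]
        field = {
            "cve_base": "cve_base",
            "case_fatality": "cve_case_fatality",
            "post_excess": "post_cve_excess_mortality",
        }[parts[1]]
        hi = np.inf if parts[1] == "post_excess" else 1.0
        d = dict(getattr(ctx.risk, field))
        d[event] = _clip(value, 0.0, hi, param_id)
        return replace(ctx, risk=replace(ctx.risk, **{field: d})), interventions
    raise KeyError(f"unknown parameter id {param_id!r}")


# ---------------------------------------------------------------------------
# One-way deterministic sensitivity analysis
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TornadoEntry:
    parameter: str
    low_value: float
    high_value: float
    icer_low: float
    icer_high: float

    @property
    def swing(self) -> float:
        return abs(self.icer_high - self.icer_low)


def _pair_icer(ctx: ModelContext, interventions: dict, comparison: tuple) -> float:
    a = evaluate_strategy(ctx, interventions[comparison[0]])
    b = evaluate_strategy(ctx, interventions[comparison[1]])
    return icer(a, b)


def one_way_dsa(
    param_id: str,
    bounds: tuple,
    ctx: ModelContext,
    interventions: dict,
    comparison: tuple = ("strengthen_exercise", "non_intervention"),
) -> TornadoEntry:
    """Re-run the pipeline at a parameter's two bounds, all else base case.

    ``comparison`` names the (more effective, reference) strategies whose
    ICER the tornado tracks.
    """
    lo, hi = bounds
    icers = []
    for v in (lo, hi):
        c2, iv2 = apply_override(ctx, interventions, param_id, v)
        icers.append(_pair_icer(c2, iv2, comparison))
    return TornadoEntry(
        parameter=param_id,
        low_value=lo,
        high_value=hi,
        icer_low=icers[0],
        icer_high=icers[1],
    )


def tornado_table(
    ctx: ModelContext,
    interventions: dict,
    param_ids: list | None = None,
    comparison: tuple = ("strengthen_exercise", "non_intervention"),
) -> pd.DataFrame:
    """One-way DSA over registered parameters, sorted by ICER swing."""
    if param_ids is None:
        param_ids = sorted(ctx.params.distributions) + ["discount_rate"]
    base = _pair_icer(ctx, interventions, comparison)
    rows = []
    for pid in param_ids:
        if pid == "discount_rate":
            bounds = (0.0, 0.08)
        else:
            d = ctx.params.distributions[pid]
            bounds = (d.low, d.high)
        e = one_way_dsa(pid, bounds, ctx, interventions, comparison)
        rows.append(
            {
                "parameter": e.parameter,
                "low_value": e.low_value,
                "high_value": e.high_value,
                "icer_low": e.icer_low,
                "icer_high": e.icer_high,
                "base_icer": base,
                "swing": e.swing,
            }
        )
    return pd.DataFrame(rows).sort_values("swing", ascending=False, ignore_index=True)


# ---------------------------------------------------------------------------
# Probabilistic sensitivity analysis
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PSAResult:
    """Per-draw (cost, QALY) pairs and the acceptability curves."""

    strategies: tuple
    costs: np.ndarray  # (n_iter, n_strategies)
    qalys: np.ndarray
    seed: int
    wtp_grid: np.ndarray
    ceac: pd.DataFrame  # index: wtp, columns: strategies, values: P(best NMB)

    def iterations_frame(self) -> pd.DataFrame:
        n, s = self.costs.shape
        return pd.DataFrame(
            {
                "iteration": np.repeat(np.arange(n), s),
                "strategy": np.tile(self.strategies, n),
                "cost": self.costs.ravel(),
                "qaly": self.qalys.ravel(),
            }
        )

    def most_probable(self, wtp: float) -> str:
        row = self.ceac.loc[wtp]
        return str(row.idxmax())


def sample_parameter_set(base: ParameterSet, seed) -> ParameterSet:
    """Draw the cost/utility parameters of a ParameterSet from their priors.

    Ids outside the ParameterSet (intervention effects, risk parameters) are
    left to :func:`sample_context`. Reproducible under a seed or Generator.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    utilities = dict(base.utilities)
    costs = dict(base.state_costs)
    eol = base.end_of_life_cost
    for pid in sorted(base.distributions):
        d = base.distributions[pid]
        parts = pid.split(".")
        if parts[0] == "utility":
            utilities[parts[1]] = min(max(d.sample(rng, pid), 0.0), 1.0)
        elif pid == "cost.end_of_life":
            eol = max(d.sample(rng, pid), 0.0)
        elif parts[0] == "cost":
            costs[parts[1]] = max(d.sample(rng, pid), 0.0)
    # keep the prehypertension >= hypertension utility ordering
    utilities[HYPERTENSION] = min(utilities[HYPERTENSION], utilities[PREHYPERTENSION])
    return replace(
        base, utilities=utilities, state_costs=costs, end_of_life_cost=eol
    )


def _draw_order(pid: str) -> tuple:
    # draw the prehypertension utility before the hypertension one so the
    # ordering constraint clips the dependent parameter, not the anchor
    return (0 if pid == f"utility.{PREHYPERTENSION}" else 1, pid)


def sample_context(ctx: ModelContext, interventions: dict, rng: np.random.Generator) -> tuple:
    """One PSA draw of the full model context (all registered parameters)."""
    c2, iv2 = ctx, interventions
    for pid in sorted(ctx.params.distributions, key=_draw_order):
        d = ctx.params.distributions[pid]
        v = d.sample(rng, pid)
        if d.family == "normal" and v < 0.0:
            log.debug("%s: normal draw %.4g truncated at 0", pid, v)
            v = 0.0
        c2, iv2 = apply_override(c2, iv2, pid, v)
    return c2, iv2


def compute_ceac(
    costs: np.ndarray, qalys: np.ndarray, strategies: tuple, wtp_grid: np.ndarray
) -> pd.DataFrame:
    """P(highest net monetary benefit) per strategy across the WTP grid."""
    n = costs.shape[0]
    rows = np.empty((len(wtp_grid), len(strategies)))
    for i, w in enumerate(wtp_grid):
        nmb = w * qalys - costs
        winners = np.argmax(nmb, axis=1)
        rows[i] = np.bincount(winners, minlength=len(strategies)) / n
    return pd.DataFrame(rows, index=np.asarray(wtp_grid, float), columns=list(strategies))


def run_psa(
    n_iterations: int,
    seed: int,
    ctx: ModelContext,
    interventions: dict,
    wtp_grid: np.ndarray | None = None,
) -> PSAResult:
    """Monte-Carlo PSA: full-pipeline evaluation per draw, CEAC by NMB."""
    if n_iterations < 1:
        raise ValueError("PSA needs at least one iteration")
    wtp_grid = DEFAULT_WTP_GRID if wtp_grid is None else np.asarray(wtp_grid, float)
    rng = np.random.default_rng(seed)
    names = tuple(interventions)
    costs = np.empty((n_iterations, len(names)))
    qalys = np.empty((n_iterations, len(names)))
    for i in range(n_iterations):
        c2, iv2 = sample_context(ctx, interventions, rng)
        for j, name in enumerate(names):
            r = evaluate_strategy(c2, iv2[name])
            costs[i, j] = r.total_cost
            qalys[i, j] = r.total_qalys
    ceac = compute_ceac(costs, qalys, names, wtp_grid)
    return PSAResult(
        strategies=names, costs=costs, qalys=qalys, seed=seed,
        wtp_grid=wtp_grid, ceac=ceac,
    )


# ---------------------------------------------------------------------------
# Duration scenarios
# ---------------------------------------------------------------------------


def scenario_duration(
    durations,
    ctx: ModelContext,
    interventions: dict,
    exclude_strongly_dominated: bool = True,
) -> pd.DataFrame:
    """Re-run the CEA with the implementation duration varied.

    Strategies strongly dominated in the base case are dropped first (they
    stay dominated at every duration, since shorter programmes only shrink
    their costs and effects toward non-intervention). Returns the
    cost-adjacent ICER ladder per duration.
    """
    included = dict(interventions)
    if exclude_strongly_dominated:
        base = [evaluate_strategy(ctx, iv) for iv in interventions.values()]
        cls = frontier_analysis(base).classification
        included = {
            n: iv for n, iv in interventions.items() if cls[n] != STRONGLY_DOMINATED
        }
    rows = []
    for d in durations:
        res = [evaluate_strategy(ctx, iv, duration=d) for iv in included.values()]
        order = sorted(res, key=lambda r: (r.total_cost, -r.total_qalys, r.name))
        for i in range(1, len(order)):
            try:
                v = icer(order[i], order[i - 1])
            except Exception:
                v = np.nan
            rows.append(
                {
                    "duration": "lifetime" if d is None else d,
                    "comparison": f"{order[i].name} vs {order[i-1].name}",
                    "more_effective": order[i].name,
                    "reference": order[i - 1].name,
                    "icer": v,
                }
            )
    return pd.DataFrame(rows)
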