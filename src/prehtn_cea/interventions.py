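"""Intervention strategies: blood-pressure effects and cost schedules.

Six strategies are modelled: non-intervention plus five non-pharmacological
interventions (usual care, lifestyle, strengthen exercise, relaxation, diet
therapy). Each NPI lowers BP in its first year and maintains that level while
the person remains prehypertensive and the programme is running; on leaving
the prehypertension state (or when the programme's duration ends) both the
effect and the programme cost stop. Annual per-capita programme totals
already include the early-hypertension-management bundle (37.02 USD) for the
five active strategies.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .model_core import PREHYPERTENSION

#: annual cost of the early-hypertension-management bundle, 2021 USD
HYPERTENSION_MANAGEMENT_COST = 37.02


@dataclass(frozen=True)
class BPLevel:
    """Systolic / diastolic blood pressure in mmHg."""

    sbp: float
    dbp: float

    def __post_init__(self) -> None:
        if not (70.0 <= self.sbp <= 250.0):
            raise ValueError(f"SBP {self.sbp} outside physiologic bounds [70, 250]")
        if not (40.0 <= self.dbp <= 150.0):
            raise ValueError(f"DBP {self.dbp} outside physiologic bounds [40, 150]")

    def shifted(self, delta_sbp: float, delta_dbp: float) -> "BPLevel":
        return BPLevel(self.sbp + delta_sbp, self.dbp + delta_dbp)


@dataclass(frozen=True)
class InterventionProfile:
    """One strategy's BP effect, cost schedule and implementation duration.

    ``duration=None`` means the programme runs over the whole lifetime
    horizon. ``first_year_cost`` defaults to the recurring annual total; the
    one-time programme-design line items are folded into the published annual
    totals, which are authoritative here.
    """

    name: str
    delta_sbp: float = 0.0
    delta_dbp: float = 0.0
    recurring_annual_cost: float = 0.0
    first_year_cost: float | None = None
    duration: int | None = None

    def __post_init__(self) -> None:
        if self.delta_sbp > 0 or self.delta_dbp > 0:
            raise ValueError("interventions may not raise blood pressure (deltas must be <= 0)")
        if self.recurring_annual_cost < 0:
            raise ValueError("negative recurring cost")
        if self.first_year_cost is None:
            object.__setattr__(self, "first_year_cost", self.recurring_annual_cost)
        if self.first_year_cost < 0:
            raise ValueError("negative first-year cost")
        if self.duration is not None and self.duration < 0:
            raise ValueError("duration must be >= 0 years")

    def with_duration(self, duration: int | None) -> "InterventionProfile":
        return replace(self, duration=duration)


def default_interventions() -> dict:
    """The six strategies with their published BP effects and annual totals."""
    specs = {
        "non_intervention": (0.0, 0.0, 0.0),
        "usual_care": (-0.47, -0.25, 20.08),
        "lifestyle": (-3.97, -3.11, 142.59),
        "strengthen_exercise": (-6.5, -3.73, 200.50),
        "relaxation": (-5.44, -5.24, 404.49),
        "diet_therapy": (-3.01, -1.98, 527.87),
    }
    return {
        name: InterventionProfile(
            name=name, delta_sbp=ds, delta_dbp=dd, recurring_annual_cost=cost
        )
        for name, (ds, dd, cost) in specs.items()
    }


def _active(intervention: InterventionProfile, cycle: int, state: str) -> bool:
    if cycle < 1:
        raise ValueError("cycles are 1-based")
    if state != PREHYPERTENSION:
        return False
    if intervention.duration is not None and cycle > intervention.duration:
        return False
    return True


def effective_bp(
    baseline: BPLevel, intervention: InterventionProfile, cycle: int, state: str
) -> BPLevel:
    """BP this cycle: baseline shifted while the programme is active.

    Once the person leaves prehypertension, or the implementation duration
    ends, BP reverts to the counterfactual baseline trajectory (no legacy
    effect)."""
    if _active(intervention, cycle, state):
        return baseline.shifted(intervention.delta_sbp, intervention.delta_dbp)
    return baseline


def intervention_cost(intervention: InterventionProfile, cycle: int, state: str) -> float:
    """Per-capita programme cost charged this cycle.

    Charged only while the recipient is prehypertensive and the programme is
    running; the first cycle uses the first-year total (which may include
    one-time design costs). Hypertension-management costs after progression
    are charged by the CEA accounting, not here."""
    if not _active(intervention, cycle, state):
        return 0.0
    return intervention.first_year_cost if cycle == 1 else intervention.recurring_annual_cost
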