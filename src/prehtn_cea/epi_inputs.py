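"""Epidemiological inputs: mortality schedule, risk equations, baseline cohort.

The published risk-prediction equations behind hypertension progression and
cardiovascular-event (CVE) incidence are not reproducible from their sources,
so this module carries documented stand-ins:

* progression (prehypertension -> hypertension): an annual logistic model
  ``p = expit(b0 + b_age*(age-45) + b_sbp*(SBP-130) + b_sex*(female-0.5))``
  whose intercept is calibrated so that an untreated anchor cohort reaches a
  target cumulative five-year progression (40% by default);
* CVE incidence (myocardial infarction, heart failure, stroke): proportional
  annual probabilities ``p_e = p0_e * exp(g_age*(age-45) + g_sbp*(SBP-130)
  + g_htn*[state==hypertension])`` capped below 1;
* case fatality of each acute CVE year and an excess-mortality multiplier for
  each post-CVE state, both plain constants with uncertainty distributions.

All-cause mortality is a Gompertz–Makeham life table standing in for a census
life table.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

CVE_EVENTS = ("mi", "hf", "stroke")

#: highest modelled age; the annual death probability is closed to 1 here
TERMINAL_AGE = 100


class InputDomainError(ValueError):
    """An epidemiological input lies outside its declared validity range."""


# ---------------------------------------------------------------------------
# Life table
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LifeTable:
    """Annual all-cause death probability ``q(age)`` on an integer age grid."""

    ages: np.ndarray
    q: np.ndarray

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=int)
        q = np.asarray(self.q, dtype=float)
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "q", q)
        if ages.shape != q.shape:
            raise ValueError("age grid and q must have equal length")
        if np.any(np.diff(ages) != 1):
            raise ValueError("age grid must be consecutive integer years")
        if np.any((q < 0) | (q > 1)):
            raise ValueError("death probabilities must lie in [0, 1]")

    @property
    def min_age(self) -> int:
        return int(self.ages[0])

    @classmethod
    def zero(cls, min_age: int = 30, max_age: int = TERMINAL_AGE) -> "LifeTable":
        """Diagnostic table with mortality switched off (calibration runs)."""
        ages = np.arange(min_age, max_age + 1)
        return cls(ages=ages, q=np.zeros_like(ages, dtype=float))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"age": self.ages, "qx": self.q})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "LifeTable":
        df = pd.read_csv(path, float_precision="round_trip")
        return cls(ages=df["age"].to_numpy(), q=df["qx"].to_numpy())


def natural_mortality(age: float, table: LifeTable) -> float:
    """Annual all-cause death probability at an integer age.

    Ages above the terminal age return 1 (closure of the lifetime horizon);
    ages below the table support are rejected.
    """
    a = int(round(age))
    if a > TERMINAL_AGE:
        return 1.0
    if a < table.min_age:
        raise InputDomainError(f"age {a} below life-table support ({table.min_age})")
    if a > int(table.ages[-1]):
        return 1.0
    return float(table.q[a - table.min_age])


# ---------------------------------------------------------------------------
# Risk model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RiskModel:
    """Stand-in annual risk equations for progression, CVE and CVE mortality.

    Progression coefficients are on the logit scale; CVE coefficients are
    log-rate-ratios applied to per-event baseline annual probabilities
    anchored at age 45, SBP 130 mmHg, prehypertensive state.
    """

    prog_intercept: float
    prog_age: float = 0.05
    prog_sbp: float = 0.08
    prog_sex: float = -0.15
    anchor_age: float = 45.0
    anchor_sbp: float = 130.0
    cve_base: dict = field(
        default_factory=lambda: {"mi": 0.0015, "hf": 0.0010, "stroke": 0.0030}
    )
    cve_age_slope: float = 0.06
    cve_sbp_slope: float = 0.02
    cve_hypertension_offset: float = 0.45
    cve_cap: float = 0.95
    #: probability of dying during the acute year of each event
    cve_case_fatality: dict = field(
        default_factory=lambda: {"mi": 0.30, "hf": 0.25, "stroke": 0.20}
    )
    #: multiplier on natural mortality while in each post-CVE state
    post_cve_excess_mortality: dict = field(
        default_factory=lambda: {"mi": 2.0, "hf": 3.0, "stroke": 2.5}
    )
    #: representative SBP used for the hypertensive state's CVE risk
    hypertensive_sbp: float = 150.0

    def zero_cve(self) -> "RiskModel":
        """Copy with all CVE incidence switched off (calibration runs)."""
        return replace(self, cve_base={e: 0.0 for e in CVE_EVENTS})


def annual_progression_probability(
    age: float, sbp: float, sex_mix: float, risk: RiskModel
) -> float:
    """Annual probability that a prehypertensive cohort member progresses.

    ``sex_mix`` is the female fraction of the cohort (0.5-centred in the
    linear predictor). Strictly increasing in both age and SBP.
    """
    if not (30.0 <= age <= 100.0):
        raise InputDomainError(f"age {age} outside progression validity range [30, 100]")
    if not (100.0 <= sbp <= 180.0):
        raise InputDomainError(f"SBP {sbp} outside validity range [100, 180]")
    if not (0.0 <= sex_mix <= 1.0):
        raise InputDomainError("sex_mix must be a fraction in [0, 1]")
    eta = (
        risk.prog_intercept
        + risk.prog_age * (age - risk.anchor_age)
        + risk.prog_sbp * (sbp - risk.anchor_sbp)
        + risk.prog_sex * (sex_mix - 0.5)
    )
    return float(expit(eta))


def annual_cve_probabilities(
    age: float, state: str, sbp: float, risk: RiskModel
) -> dict:
    """Annual MI / HF / stroke probabilities from a pre-CVE living state.

    Only ``prehypertension`` and ``hypertension`` are eligible; the
    hypertensive state carries a positive log-rate offset so its risks weakly
    dominate prehypertension at equal age and SBP.
    """
    if state not in ("prehypertension", "hypertension"):
        raise InputDomainError(f"CVE risk is not defined for state {state!r}")
    if not (30.0 <= age <= 100.0):
        raise InputDomainError(f"age {age} outside CVE validity range [30, 100]")
    offset = risk.cve_hypertension_offset if state == "hypertension" else 0.0
    log_rr = (
        risk.cve_age_slope * (age - risk.anchor_age)
        + risk.cve_sbp_slope * (sbp - risk.anchor_sbp)
        + offset
    )
    rr = float(np.exp(log_rr))
    return {e: min(risk.cve_base[e] * rr, risk.cve_cap) for e in CVE_EVENTS}


def cumulative_progression(
    risk: RiskModel,
    start_age: float,
    sbp: float,
    sex_mix: float,
    years: int,
) -> float:
    """Cumulative progressed fraction over ``years`` annual cycles.

    Pure-progression chain: mortality and CVE exits are absent, so this is
    the closed form ``1 - prod_t (1 - p_t)`` used by the calibration solver.
    """
    surv = 1.0
    for t in range(years):
        surv *= 1.0 - annual_progression_probability(start_age + t, sbp, sex_mix, risk)
    return 1.0 - surv


def calibrate_progression_intercept(
    risk: RiskModel,
    target: float,
    start_age: float,
    sbp: float,
    sex_mix: float = 0.5,
    years: int = 5,
    tol: float = 1e-10,
) -> RiskModel:
    """Solve the progression intercept for a target cumulative progression.

    Root-solves ``b0`` so the anchor cohort's cumulative ``years``-cycle
    progression (mortality and CVE off) equals ``target``.
    """
    if not (1e-6 < target < 1.0 - 1e-6):
        raise InputDomainError(f"progression target {target} outside (0, 1)")

    def gap(b0: float) -> float:
        trial = replace(risk, prog_intercept=b0)
        return cumulative_progression(trial, start_age, sbp, sex_mix, years) - target

    lo, hi = -30.0, 10.0
    if gap(lo) > 0 or gap(hi) < 0:
        raise InputDomainError("progression target unreachable within intercept bounds")
    b0 = brentq(gap, lo, hi, xtol=tol)
    return replace(risk, prog_intercept=float(b0))


# ---------------------------------------------------------------------------
# Baseline cohort
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortProfile:
    """Homogeneous-cohort summary of the simulated prehypertensive population."""

    n: int = 10_000
    age_mean: float = 45.0
    age_sd: float = 8.0
    female_fraction: float = 0.5
    sbp: float = 130.0
    dbp: float = 85.0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("cohort size must be at least 1")
        if not (120.0 <= self.sbp <= 139.0):
            raise ValueError("baseline SBP must lie in the prehypertensive band [120, 139]")
        if not (80.0 <= self.dbp <= 89.0):
            raise ValueError("baseline DBP must lie in the prehypertensive band [80, 89]")
        if not (0.0 <= self.female_fraction <= 1.0):
            raise ValueError("female_fraction must be in [0, 1]")
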