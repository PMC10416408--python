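"""Nine-state Markov cohort engine.

States: prehypertension, hypertension, three acute cardiovascular-event (CVE)
tunnel states (MI, heart failure, stroke), their three post-CVE states, and
death. The acute states can be occupied for exactly one annual cycle, after
which survivors move to the matching post state; post states never return to
an acute state (each person has at most one CVE). Death is absorbing.

The engine propagates a homogeneous cohort through per-cycle transition
matrices assembled from the risk equations, a life table and the cohort's
(possibly intervention-shifted) blood pressure. Competing annual risks within
a row are computed independently and the residual mass stays put; if the
independent components exceed unit mass the assembly fails loudly instead of
renormalising.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .epi_inputs import (
    CVE_EVENTS,
    LifeTable,
    RiskModel,
    annual_cve_probabilities,
    annual_progression_probability,
    natural_mortality,
)

PREHYPERTENSION = "prehypertension"
HYPERTENSION = "hypertension"
ACUTE_MI = "acute_mi"
ACUTE_HF = "acute_hf"
ACUTE_STROKE = "acute_stroke"
POST_MI = "post_mi"
POST_HF = "post_hf"
POST_STROKE = "post_stroke"
DEATH = "death"

STATES = (
    PREHYPERTENSION,
    HYPERTENSION,
    ACUTE_MI,
    ACUTE_HF,
    ACUTE_STROKE,
    POST_MI,
    POST_HF,
    POST_STROKE,
    DEATH,
)

ACUTE_OF_EVENT = {"mi": ACUTE_MI, "hf": ACUTE_HF, "stroke": ACUTE_STROKE}
POST_OF_EVENT = {"mi": POST_MI, "hf": POST_HF, "stroke": POST_STROKE}


class ProbabilityError(ValueError):
    """A transition-row assembly produced invalid probability mass."""


@dataclass(frozen=True)
class StateSpace:
    """The fixed nine-state topology."""

    states: tuple = STATES
    tunnel_successor: dict = None
    absorbing: frozenset = frozenset({DEATH})

    def __post_init__(self) -> None:
        if self.tunnel_successor is None:
            object.__setattr__(
                self,
                "tunnel_successor",
                {ACUTE_MI: POST_MI, ACUTE_HF: POST_HF, ACUTE_STROKE: POST_STROKE},
            )

    def index(self, label: str) -> int:
        return self.states.index(label)

    def successor(self, acute_state: str) -> str:
        """Post state entered one cycle after the given acute tunnel state."""
        return self.tunnel_successor[acute_state]

    def successors(self, label: str) -> set:
        """States reachable from ``label`` in one cycle under the topology."""
        if label in self.absorbing:
            return {label}
        if label in self.tunnel_successor:
            return {self.tunnel_successor[label], DEATH}
        if label == PREHYPERTENSION:
            return {PREHYPERTENSION, HYPERTENSION, ACUTE_MI, ACUTE_HF, ACUTE_STROKE, DEATH}
        if label == HYPERTENSION:
            return {HYPERTENSION, ACUTE_MI, ACUTE_HF, ACUTE_STROKE, DEATH}
        # post states: stay or die (no second CVE)
        return {label, DEATH}


def build_state_space() -> StateSpace:
    """Return the fixed nine-state model topology."""
    return StateSpace()


_SPACE = build_state_space()
_IDX = {s: i for i, s in enumerate(STATES)}
N_STATES = len(STATES)


@dataclass(frozen=True)
class TransitionMatrix:
    """One annual transition matrix, validated to be row-stochastic."""

    cycle_index: int
    entries: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.entries, dtype=float)
        object.__setattr__(self, "entries", m)
        if m.shape != (N_STATES, N_STATES):
            raise ProbabilityError(f"expected {N_STATES}x{N_STATES} matrix, got {m.shape}")
        if np.any(m < -1e-15) or np.any(m > 1 + 1e-15):
            raise ProbabilityError("transition entries outside [0, 1]")
        rows = m.sum(axis=1)
        if np.any(np.abs(rows - 1.0) > 1e-12):
            raise ProbabilityError(f"rows not stochastic: sums {rows}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, index=list(STATES), columns=list(STATES))


@dataclass(frozen=True)
class MarkovTrace:
    """Cohort occupancy and arrival flows over the simulated horizon.

    ``occupancy[t]`` is the state distribution after ``t`` transitions
    (row 0 is the initial distribution); ``inflow[t]`` is the proportion
    newly arriving in each state during transition ``t`` (row 0 is zero).
    Person-time for accounting cycle ``t`` (1-based) is ``occupancy[t-1]``,
    i.e. the state occupied during year ``t``.
    """

    occupancy: np.ndarray
    inflow: np.ndarray

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    @property
    def person_years(self) -> np.ndarray:
        """(cycles, 9) person-time weights: start-of-cycle occupancy."""
        return self.occupancy[:-1]

    @property
    def death_inflow(self) -> np.ndarray:
        """Newly dead proportion per cycle (length = n_cycles)."""
        return self.inflow[1:, _IDX[DEATH]]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.occupancy, columns=list(STATES))
        df.insert(0, "cycle", np.arange(self.occupancy.shape[0]))
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _competing_row(
    events: dict, q: float, stay_state: str, cycle: int, state: str
) -> np.ndarray:
    """Assemble one living-state row with hierarchical competing risks.

    Natural mortality ``q`` competes first; the independently computed event
    probabilities apply to the year's survivors and the residual survivor
    mass stays put. If the event components alone exceed unit mass the
    assembly fails loudly rather than renormalising.
    """
    if not (0.0 <= q <= 1.0):
        raise ProbabilityError(f"cycle {cycle}, row {state}: mortality {q} outside [0, 1]")
    row = np.zeros(N_STATES)
    total = 0.0
    for dest, p in events.items():
        if p < 0:
            raise ProbabilityError(
                f"cycle {cycle}, row {state}: negative probability {p} to {dest}"
            )
        row[_IDX[dest]] = (1.0 - q) * p
        total += p
    if total > 1.0 + 1e-12:
        raise ProbabilityError(
            f"cycle {cycle}, row {state}: independent event probabilities sum to "
            f"{total:.6f} > 1; refusing to renormalise"
        )
    row[_IDX[DEATH]] = q
    row[_IDX[stay_state]] = max(0.0, (1.0 - q) * (1.0 - total))
    return row


def assemble_transition_matrix(
    cycle: int,
    cohort_age: float,
    risk: RiskModel,
    bp,
    mortality: LifeTable,
    sex_mix: float = 0.5,
) -> TransitionMatrix:
    """Build the annual transition matrix for one cycle.

    Parameters
    ----------
    cycle
        1-based accounting cycle (stored for bookkeeping).
    cohort_age
        Cohort mean age during this cycle, driving mortality and risks.
    bp
        Blood pressure of the prehypertensive state this cycle
        (intervention-shifted where applicable), either a ``BPLevel`` or a
        bare SBP in mmHg; the hypertensive state's CVE risk uses the risk
        model's representative hypertensive SBP instead.
    """
    bp_sbp = float(getattr(bp, "sbp", bp))
    q = natural_mortality(cohort_age, mortality)
    m = np.zeros((N_STATES, N_STATES))

    # prehypertension: progression and CVE onset among natural-mortality
    # survivors
    p_prog = annual_progression_probability(cohort_age, bp_sbp, sex_mix, risk)
    cve_pre = annual_cve_probabilities(cohort_age, PREHYPERTENSION, bp_sbp, risk)
    events = {HYPERTENSION: p_prog}
    events.update({ACUTE_OF_EVENT[e]: cve_pre[e] for e in CVE_EVENTS})
    m[_IDX[PREHYPERTENSION]] = _competing_row(events, q, PREHYPERTENSION, cycle, PREHYPERTENSION)

    # hypertension: CVE onset at the representative hypertensive SBP
    cve_htn = annual_cve_probabilities(
        cohort_age, HYPERTENSION, risk.hypertensive_sbp, risk
    )
    events = {ACUTE_OF_EVENT[e]: cve_htn[e] for e in CVE_EVENTS}
    m[_IDX[HYPERTENSION]] = _competing_row(events, q, HYPERTENSION, cycle, HYPERTENSION)

    # acute tunnel states: die (case fatality combined with natural risk) or
    # progress to the post state; never linger
    for e in CVE_EVENTS:
        f = risk.cve_case_fatality[e]
        if not (0.0 <= f <= 1.0):
            raise ProbabilityError(f"case fatality for {e} outside [0, 1]: {f}")
        p_die = 1.0 - (1.0 - f) * (1.0 - q)
        row = np.zeros(N_STATES)
        row[_IDX[DEATH]] = p_die
        row[_IDX[POST_OF_EVENT[e]]] = 1.0 - p_die
        m[_IDX[ACUTE_OF_EVENT[e]]] = row

    # post-CVE states: excess mortality multiplier on natural mortality
    for e in CVE_EVENTS:
        mult = risk.post_cve_excess_mortality[e]
        if mult < 0:
            raise ProbabilityError(f"negative excess-mortality multiplier for {e}")
        p_die = min(1.0, mult * q)
        row = np.zeros(N_STATES)
        row[_IDX[DEATH]] = p_die
        row[_IDX[POST_OF_EVENT[e]]] = 1.0 - p_die
        m[_IDX[POST_OF_EVENT[e]]] = row

    m[_IDX[DEATH], _IDX[DEATH]] = 1.0
    return TransitionMatrix(cycle_index=cycle, entries=m)


def propagate(initial: np.ndarray, matrices: list, horizon: int | None = None) -> MarkovTrace:
    """Advance an initial occupancy vector through per-cycle matrices.

    ``matrices`` may be TransitionMatrix objects or raw row-stochastic
    arrays (the latter for oracle checks). Records per-cycle arrival flows
    alongside occupancy.
    """
    x = np.asarray(initial, dtype=float)
    if x.shape != (N_STATES,):
        raise ValueError(f"initial occupancy must have length {N_STATES}")
    if abs(x.sum() - 1.0) > 1e-10:
        raise ValueError("initial occupancy must sum to 1")
    if horizon is None:
        horizon = len(matrices)
    if horizon < 1:
        raise ValueError("horizon must be at least 1 cycle")
    if horizon > len(matrices):
        raise ValueError(f"horizon {horizon} exceeds the {len(matrices)} supplied matrices")

    occ = np.empty((horizon + 1, N_STATES))
    inflow = np.zeros((horizon + 1, N_STATES))
    occ[0] = x
    for t in range(1, horizon + 1):
        m = matrices[t - 1]
        ent = m.entries if isinstance(m, TransitionMatrix) else np.asarray(m, float)
        occ[t] = occ[t - 1] @ ent
        off_diag = ent - np.diag(np.diag(ent))
        inflow[t] = occ[t - 1] @ off_diag
    return MarkovTrace(occupancy=occ, inflow=inflow)
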