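"""Independent oracles shared by the unit and acceptance tests.

These deliberately avoid the package's own algorithms: the frontier oracle
classifies by exhaustive pairwise/mixture domination, and the closed forms
are evaluated directly from their textbook expressions.
"""

from __future__ import annotations

import numpy as np

FRONTIER = "frontier"
STRONG = "strongly_dominated"
EXTENDED = "extended_dominated"


def brute_force_classify(points: dict) -> dict:
    """Classify strategies from (cost, qaly) pairs by exhaustive domination.

    A strategy is strongly dominated if a single alternative is no dearer
    and no less effective (strict in one); it is extended dominated if it is
    not strongly dominated but some convex mixture of two alternatives is.
    Everything else is on the frontier.
    """
    names = list(points)
    out = {}
    for s in names:
        cs, qs = points[s]
        strong = any(
            points[a][0] <= cs
            and points[a][1] >= qs
            and (points[a][0] < cs or points[a][1] > qs)
            for a in names
            if a != s
        )
        if strong:
            out[s] = STRONG
            continue
        mixture = False
        for a in names:
            for b in names:
                if a == b or s in (a, b):
                    continue
                ca, qa = points[a]
                cb, qb = points[b]
                if qa == qb:
                    continue
                if not (min(qa, qb) <= qs <= max(qa, qb)):
                    continue
                mu = (qs - qb) / (qa - qb)
                cost_line = mu * ca + (1 - mu) * cb
                if cost_line < cs - 1e-9:
                    mixture = True
                    break
            if mixture:
                break
        out[s] = EXTENDED if mixture else FRONTIER
    return out


def annuity_present_value(v: float, rate: float, cycles: int) -> float:
    """PV of a constant stream, first cycle undiscounted (annuity-due form)."""
    if rate == 0:
        return v * cycles
    return v * (1 - (1 + rate) ** -cycles) / rate * (1 + rate)


def gompertz_makeham_q(age: float, makeham: float, b: float, theta: float) -> float:
    return 1.0 - np.exp(-(makeham + b * np.exp(theta * age)))


def geometric_sojourn(p_exit: float, horizon: int) -> float:
    """Expected cycles spent before a constant-probability exit."""
    return sum((1 - p_exit) ** (t - 1) for t in range(1, horizon + 1))
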