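#!/usr/bin/env python
"""National 15-year budget impact of rolling out strengthen exercise.

Base rollout (all ages 45-64, full compliance, 15-year duration) plus a
grid of targeting strategies: age bands, high-CVE-risk-only enrolment,
shorter durations and partial compliance. Writes per-year series and the
strategy comparison to results/.
"""

from pathlib import Path

from prehtn_cea import BIAStrategy, gen_fixture_bundle, run_bia, strategy_grid
from prehtn_cea.bia import AGE_BANDS
from prehtn_cea.synthetic_data import COMPLIANCE_GRID

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    bundle = gen_fixture_bundle()
    ctx = bundle.context()
    se = bundle.interventions["strengthen_exercise"]
    demo = bundle.demographics
    OUT.mkdir(exist_ok=True)

    base = run_bia(BIAStrategy(), se, demo, ctx)
    base.to_frame().to_csv(OUT / "bia_series.csv", index=False)
    print(
        f"base rollout: {base.eligible:,.0f} eligible; over 15 years the programme "
        f"costs {base.cumulative_program_cost/1e9:,.1f}B USD against "
        f"{base.cumulative_saving/1e9:,.1f}B USD of medical cost saving"
    )
    print("-> the medical cost saving is far less than the programme cost")
    print()

    strategies = [BIAStrategy(age_band=b) for b in AGE_BANDS]
    strategies += [BIAStrategy(high_risk_only=True)]
    strategies += [BIAStrategy(duration=d) for d in (5, 10)]
    strategies += [BIAStrategy(compliance=c) for c in COMPLIANCE_GRID[1:]]
    grid = strategy_grid(strategies, se, demo, ctx)
    grid.to_csv(OUT / "bia_strategies.csv", index=False)
    print("targeting strategies (cumulative, 15 years):")
    shown = grid.copy()
    shown["cumulative_program_cost"] = (shown["cumulative_program_cost"] / 1e9).round(1)
    shown["cumulative_saving"] = (shown["cumulative_saving"] / 1e9).round(1)
    shown = shown.rename(
        columns={"cumulative_program_cost": "program_cost_B", "cumulative_saving": "saving_B"}
    )
    print(shown.to_string(index=False))
    print(
        "-> later starting age, high-risk targeting and shorter duration all cut "
        "the programme cost with comparatively little loss of saving"
    )


if __name__ == "__main__":
    main()
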