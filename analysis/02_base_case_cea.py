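#!/usr/bin/env python
"""Base-case cost-effectiveness analysis of the six strategies.

Evaluates each strategy over the lifetime horizon, classifies dominance,
and writes the base-case table to results/cea_results.csv.
"""

from pathlib import Path

from prehtn_cea import evaluate_strategy, frontier_analysis, gen_fixture_bundle, results_table

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    bundle = gen_fixture_bundle()
    ctx = bundle.context()
    results = [evaluate_strategy(ctx, iv) for iv in bundle.interventions.values()]
    fr = frontier_analysis(results)
    table = results_table(results, fr)
    OUT.mkdir(exist_ok=True)
    table.round(4).to_csv(OUT / "cea_results.csv", index=False)

    print("base-case results (discounted 2021 USD, discounted QALYs):")
    print(table.round(2).to_string(index=False))
    print()
    print(f"frontier: {fr.frontier_names()}")
    for step in fr.ladder:
        print(
            f"  {step['to']} vs {step['from']}: "
            f"dC {step['delta_cost']:.2f}, dQ {step['delta_qalys']:.4f}, "
            f"ICER {step['icer']:.2f} per QALY"
        )
    wtp = ctx.params.wtp
    best = fr.ladder[-1]
    verdict = "below" if best["icer"] < wtp else "above"
    print(f"frontier ICER is {verdict} the WTP threshold of {wtp:,.0f} USD/QALY")


if __name__ == "__main__":
    main()
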