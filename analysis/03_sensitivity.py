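#!/usr/bin/env python
"""Deterministic and probabilistic sensitivity analyses.

One-way DSA over every registered parameter (tornado table) and a
10,000-iteration PSA with cost-effectiveness acceptability curves. The
tornado and CEAC tables go to results/; the large per-draw scatter goes to
scratch/ (not part of the deliverable tables).
"""

from pathlib import Path

from prehtn_cea import gen_fixture_bundle, run_psa
from prehtn_cea.synthetic_data import PSA_ITERATIONS
from prehtn_cea.uncertainty import tornado_table

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results"
SCRATCH = ROOT / "scratch"


def main() -> None:
    bundle = gen_fixture_bundle()
    ctx, ivs = bundle.context(), bundle.interventions
    OUT.mkdir(exist_ok=True)

    tt = tornado_table(ctx, ivs)
    tt.round(4).to_csv(OUT / "tornado.csv", index=False)
    print("one-way DSA, strengthen exercise vs non-intervention")
    print("five widest ICER swings:")
    print(tt.head(5).round(1).to_string(index=False))
    print()

    psa = run_psa(PSA_ITERATIONS, seed=bundle.seed, ctx=ctx, interventions=ivs)
    psa.ceac.round(6).to_csv(OUT / "ceac.csv", index_label="wtp")
    SCRATCH.mkdir(exist_ok=True)
    psa.iterations_frame().round(4).to_csv(SCRATCH / "psa_scatter.csv", index=False)

    for wtp in (ctx.params.wtp, ctx.params.wtp_high):
        grid_wtp = min(psa.wtp_grid, key=lambda g: abs(g - wtp))
        row = psa.ceac.loc[grid_wtp]
        best = row.idxmax()
        print(
            f"PSA ({PSA_ITERATIONS:,} iterations): at WTP {wtp:,.0f} USD/QALY, "
            f"{best} is cost-effective with probability {row[best]:.1%}"
        )


if __name__ == "__main__":
    main()
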