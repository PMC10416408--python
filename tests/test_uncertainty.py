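"""One-way DSA, probabilistic sensitivity analysis, CEAC and duration scenarios."""

from dataclasses import replace

import numpy as np
import pytest

from prehtn_cea import (
    Distribution,
    evaluate_strategy,
    icer,
    run_psa,
    sample_parameter_set,
    scenario_duration,
)
from prehtn_cea.uncertainty import (
    InfeasibleDistribution,
    apply_override,
    compute_ceac,
    one_way_dsa,
    sample_context,
)


def _degenerate_ctx(ctx):
    dists = {
        k: Distribution(d.family, d.mean, d.mean, d.mean)
        for k, d in ctx.params.distributions.items()
    }
    return replace(ctx, params=replace(ctx.params, distributions=dists))


class TestDistribution:
    def test_zero_width_bounds_return_mean_exactly(self):
        rng = np.random.default_rng(0)
        d = Distribution("beta", 0.8, 0.8, 0.8)
        assert d.sample(rng) == 0.8

    @pytest.mark.parametrize(
        "family, mean, lo, hi",
        [("beta", 0.8, 0.64, 0.96), ("gamma", 200.0, 160.0, 240.0), ("normal", 6.5, 5.2, 7.8)],
    )
    def test_moment_matching_recovers_mean_and_sd(self, family, mean, lo, hi):
        """Sample moments sit within 3 standard errors of their targets."""
        rng = np.random.default_rng(123)
        d = Distribution(family, mean, lo, hi)
        n = 10_000
        draws = np.array([d.sample(rng) for _ in range(n)])
        se_mean = d.sd / np.sqrt(n)
        assert abs(draws.mean() - mean) < 3 * se_mean
        assert abs(draws.std(ddof=1) - d.sd) < 0.1 * d.sd

    def test_beta_support(self):
        rng = np.random.default_rng(5)
        d = Distribution("beta", 0.5, 0.1, 0.9)
        draws = [d.sample(rng) for _ in range(2000)]
        assert all(0.0 <= x <= 1.0 for x in draws)

    def test_infeasible_moment_matching_reports_parameter(self):
        rng = np.random.default_rng(0)
        d = Distribution("beta", 0.999, 0.0, 1.0)
        with pytest.raises(InfeasibleDistribution, match="my_param"):
            d.sample(rng, "my_param")


class TestApplyOverride:
    def test_unknown_parameter_rejected(self, ctx, interventions):
        with pytest.raises(KeyError):
            apply_override(ctx, interventions, "no.such.param", 1.0)

    def test_out_of_support_values_clipped_with_warning(self, ctx, interventions, caplog):
        import logging

        # repeat clips are demoted to debug, so capture both levels
        with caplog.at_level(logging.DEBUG, logger="prehtn_cea.uncertainty"):
            c2, _ = apply_override(ctx, interventions, "utility.hypertension", 1.2)
        assert c2.params.utilities["hypertension"] <= c2.params.utilities["prehypertension"]
        assert any("clipped" in r.message for r in caplog.records)

    def test_progression_target_override_recalibrates(self, ctx, interventions):
        from prehtn_cea.epi_inputs import cumulative_progression

        c2, _ = apply_override(ctx, interventions, "risk.progression_5yr", 0.30)
        got = cumulative_progression(c2.risk, 45, 130.0, 0.5, 5)
        assert got == pytest.approx(0.30, abs=1e-6)


class TestOneWayDSA:
    def test_base_value_bounds_reproduce_base_icer(self, ctx, interventions):
        base = icer(
            evaluate_strategy(ctx, interventions["strengthen_exercise"]),
            evaluate_strategy(ctx, interventions["non_intervention"]),
        )
        u = ctx.params.utilities["hypertension"]
        e = one_way_dsa("utility.hypertension", (u, u), ctx, interventions)
        assert e.icer_low == pytest.approx(base)
        assert e.icer_high == pytest.approx(base)

    def test_discount_bounds_zero_to_eight_percent(self, ctx, interventions):
        e = one_way_dsa("discount_rate", (0.0, 0.08), ctx, interventions)
        assert e.icer_low != e.icer_high
        # undiscounted totals exceed the discounted base-case totals
        c0, _ = apply_override(ctx, interventions, "discount_rate", 0.0)
        r0 = evaluate_strategy(c0, interventions["strengthen_exercise"])
        rb = evaluate_strategy(ctx, interventions["strengthen_exercise"])
        assert r0.total_cost > rb.total_cost
        assert r0.total_qalys > rb.total_qalys

    def test_hypertension_utility_flips_decision_near_indifference(self, ctx, interventions):
        """On a context tuned so the base ICER sits at the WTP threshold, the
        +/-20% hypertension-utility bounds move the decision both ways."""
        se, ni = interventions["strengthen_exercise"], interventions["non_intervention"]
        wtp = ctx.params.wtp

        def icer_at(cost):
            _, ivs = apply_override(ctx, interventions, "intervention.strengthen_exercise.annual_cost", cost)
            return icer(evaluate_strategy(ctx, ivs["strengthen_exercise"]), evaluate_strategy(ctx, ni))

        # ICER is affine in the annual cost: solve for the indifference cost
        c1, c2 = 100.0, 500.0
        i1, i2 = icer_at(c1), icer_at(c2)
        c_star = c1 + (wtp - i1) * (c2 - c1) / (i2 - i1)
        assert icer_at(c_star) == pytest.approx(wtp, rel=1e-6)

        _, tuned = apply_override(ctx, interventions, "intervention.strengthen_exercise.annual_cost", c_star)
        u = ctx.params.utilities["hypertension"]
        e = one_way_dsa("utility.hypertension", (0.8 * u, 1.2 * u), ctx, tuned)
        # lower hypertension utility -> bigger QALY gain -> cost-effective;
        # higher utility (clipped at the prehypertension level) -> not
        assert e.icer_low < wtp
        assert e.icer_high > wtp


class TestPSA:
    def test_degenerate_distributions_collapse_to_base_case(self, ctx, interventions):
        dctx = _degenerate_ctx(ctx)
        psa = run_psa(4, seed=11, ctx=dctx, interventions=interventions)
        base = {
            name: evaluate_strategy(dctx, iv) for name, iv in interventions.items()
        }
        for j, name in enumerate(psa.strategies):
            np.testing.assert_allclose(psa.costs[:, j], base[name].total_cost, rtol=1e-12)
            np.testing.assert_allclose(psa.qalys[:, j], base[name].total_qalys, rtol=1e-12)
        # CEAC is a one-hot step function of WTP
        assert set(np.unique(psa.ceac.to_numpy())) <= {0.0, 1.0}

    def test_ceac_normalised_and_bounded(self, ctx, interventions):
        psa = run_psa(30, seed=3, ctx=ctx, interventions=interventions)
        arr = psa.ceac.to_numpy()
        np.testing.assert_allclose(arr.sum(axis=1), 1.0, atol=1e-12)
        assert np.all((arr >= 0) & (arr <= 1))

    def test_same_seed_bit_identical(self, ctx, interventions):
        a = run_psa(20, seed=99, ctx=ctx, interventions=interventions)
        b = run_psa(20, seed=99, ctx=ctx, interventions=interventions)
        np.testing.assert_array_equal(a.costs, b.costs)
        np.testing.assert_array_equal(a.qalys, b.qalys)
        assert a.ceac.equals(b.ceac)

    def test_ceac_converges_with_iterations(self, ctx, interventions):
        """Prefix CEACs approach the full-run CEAC as draws accumulate."""
        psa = run_psa(600, seed=17, ctx=ctx, interventions=interventions)
        full = psa.ceac.to_numpy()

        def prefix_ceac(n):
            return compute_ceac(
                psa.costs[:n], psa.qalys[:n], psa.strategies, psa.wtp_grid
            ).to_numpy()

        d_small = np.abs(prefix_ceac(40) - full).mean()
        d_large = np.abs(prefix_ceac(300) - full).mean()
        assert d_large < d_small

    def test_sampled_utilities_respect_support(self, ctx):
        rng = np.random.default_rng(8)
        for _ in range(200):
            p = sample_parameter_set(ctx.params, rng)
            assert all(0.0 <= u <= 1.0 for u in p.utilities.values())
            assert p.utilities["prehypertension"] >= p.utilities["hypertension"]

    def test_effect_draws_never_raise_bp(self, ctx, interventions):
        rng = np.random.default_rng(21)
        for _ in range(50):
            _, ivs = sample_context(ctx, interventions, rng)
            assert all(iv.delta_sbp <= 0 for iv in ivs.values())


class TestScenarioDuration:
    def test_lifetime_duration_reproduces_base_case(self, ctx, interventions):
        iv = interventions["strengthen_exercise"]
        assert evaluate_strategy(ctx, iv, duration=None) == evaluate_strategy(ctx, iv)

    def test_duration_zero_collapses_to_non_intervention(self, ctx, interventions):
        ni = evaluate_strategy(ctx, interventions["non_intervention"])
        for name, iv in interventions.items():
            r = evaluate_strategy(ctx, iv, duration=0)
            assert (r.total_cost, r.total_qalys, r.trans) == (
                ni.total_cost, ni.total_qalys, ni.trans,
            )

    def test_strongly_dominated_strategies_excluded(self, ctx, interventions):
        df = scenario_duration([1], ctx, interventions)
        names = set(df["more_effective"]) | set(df["reference"])
        assert "relaxation" not in names
        assert "diet_therapy" not in names
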