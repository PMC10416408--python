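# Methods

## Model

`prehtn_cea` implements a nine-state Markov cohort model of disease
progression in prehypertensive adults (SBP 120–139 / DBP 80–89 mmHg) under
six management strategies: non-intervention and five non-pharmacological
interventions (NPIs) — usual care, lifestyle modification, strengthen
exercise, relaxation, and diet therapy.

States: `prehypertension` → `hypertension` → acute cardiovascular events
(`acute_mi`, `acute_hf`, `acute_stroke`) → post-event states (`post_mi`,
`post_hf`, `post_stroke`) → `death`. The three acute states are one-year
tunnel states: survivors of the acute year move to the matching post state
in the next cycle and cannot linger or relapse (each person experiences at
most one cardiovascular event; post states only exit to death). Direct
prehypertension → acute-event transitions are included alongside the
hypertension → acute-event pathway. Death is the single absorbing state.

Key behavioural assumptions:

1. an NPI lowers blood pressure in its first year and *maintains* that level
   while the recipient stays prehypertensive and the programme is running;
2. NPIs are applied only in the prehypertension state — both the effect and
   the programme cost stop on progression to hypertension (or when the
   implementation duration ends), after which BP reverts to the
   counterfactual trajectory (no legacy effect);
3. cardiovascular event risk while hypertensive does not depend on which NPI
   was received earlier (the hypertensive state's risk is evaluated at a
   fixed representative SBP of 150 mmHg).

Cycle length is one year; cycles are indexed from 1. The lifetime horizon is
operationalised as simulation until the cohort's mean age passes 100, where
the annual death probability is closed at 1, so the cohort is fully absorbed
(death occupancy ≥ 0.999 is asserted in tests). The cohort is homogeneous:
its mean age advances one year per cycle and drives the age-dependent
mortality and risk functions (a cohort model, not a microsimulation).
Person-time for accounting cycle *t* is the start-of-cycle occupancy; there
is no half-cycle correction. Cycle-1 cash flows are undiscounted — the
present-value divisor is (1+r)^(t−1) — so first-year programme costs are
charged at face value.

### Competing risks within a row

Within each living-state row, annual natural mortality *q(age)* competes
first; the independently computed event probabilities (progression and the
three event onsets) apply to the year's survivors, and the residual survivor
mass stays put:

    P(die)   = q
    P(event) = (1 − q) · p_event
    P(stay)  = (1 − q) · (1 − Σ p_event)

If the event components alone exceed unit mass the assembly fails loudly
rather than renormalising. A flat independent-probabilities construction
(death mass in the same pool as the events) was rejected because it cannot
close the lifetime horizon: at the terminal age q = 1 and any progression
mass overflows the row, and even at age 99 the fixture's q ≈ 0.30 plus
late-age progression ≈ 0.6 exceeds 1. The hierarchical form is
unconditionally row-stochastic and reduces to the flat form when q = 0.

Acute-state rows combine case fatality *f* with natural mortality,
P(die) = 1 − (1−f)(1−q), remainder to the post state. Post-state rows apply
an excess-mortality multiplier, P(die) = min(1, m·q).

## Stand-in epidemiological inputs

The risk-prediction equations and census life table behind the original
parameterisation are not publicly reproducible, so the package generates
documented synthetic stand-ins (module `synthetic_data`; every generated
field is flagged `synthetic` in the emitted config, printed values
`printed`).

**Progression** (annual prehypertension → hypertension probability):

    p = expit(β₀ + β_age·(age − 45) + β_sbp·(SBP − 130) + β_sex·(female − 0.5))

with β_age = 0.05 /year, β_sbp = 0.08 /mmHg, β_sex = −0.15. β_sbp > 0 makes
the five NPIs' distinct SBP reductions produce distinct progression curves;
its magnitude implies an odds ratio of ≈ 0.59 for the largest effect
(−6.5 mmHg), a clinically plausible separation. β₀ is solved by Brent root
finding (tolerance 1e-10) so that the cumulative five-cycle progression of
an untreated anchor cohort (age 45, SBP 130, balanced sex mix) equals the
40% five-year progression rate reported for prehypertensive populations.
**Anchor definition:** the calibration target and its re-simulation both
disable mortality *and* competing cardiovascular-event exits — the anchor is
a pure-progression quantity, so the closed form 1 − Π(1 − p_t) and the
Markov engine agree to solver precision. With competing exits left on, the
progressed fraction would be a few tenths of a percentage point lower by
construction, which is a statement about competing risks, not about the
progression model.

Only SBP drives the risk functions; DBP is carried for completeness (the
joint contribution of SBP and DBP to risk is not identifiable from available
information).

**Cardiovascular event onset** (annual probability per event, from
prehypertension or hypertension):

    p_e = p0_e · exp(γ_age·(age − 45) + γ_sbp·(SBP − 130) + γ_htn·1[hypertension])

with baselines p0 = 0.0015 (MI), 0.0010 (HF), 0.0030 (stroke) at the anchor
(stroke dominant, as in East-Asian populations), γ_age = 0.06 /year,
γ_sbp = 0.02 /mmHg, γ_htn = 0.45 (rate ratio ≈ 1.57), capped at 0.95.
Monotone in age and SBP, hypertensive ≥ prehypertensive at equal age by
construction; bounds are grid-checked over ages 30–100 and SBP 100–180.

**Event mortality:** case fatality 0.30 / 0.25 / 0.20 (MI / HF / stroke)
during the acute year; post-event excess-mortality multipliers 2.0 / 3.0 /
2.5 on natural mortality. Synthetic constants with uncertainty
distributions.

**Life table:** Gompertz–Makeham, q(a) = 1 − exp(−(λ + B·e^{θa})) with
λ = 5e-4, B = 3e-5, θ = 0.095 on ages 30–100 (q(45) ≈ 0.003,
q(80) ≈ 0.06), terminal q(100) = 1.

**Cohort:** n = 10,000, mean age 45 (SD 8), 50% female, SBP/DBP 130/85 —
mid-life values at the centre of the prehypertensive band, standing in for
survey-derived baseline characteristics that are not published.

## Costs, utilities, interventions

All money is 2021 USD. Printed, hard-wired values: the five NPIs' BP effects
(SBP/DBP, mmHg) and annual per-capita programme totals (usual care 20.08,
lifestyle 142.59, strengthen exercise 200.50, relaxation 404.49, diet
therapy 527.87 — each inclusive of the 37.02 early-hypertension-management
bundle), the hypertension-state management cost 37.02/year, utilities 0.931
(prehypertension) and 0.8 (hypertension), discount rate 5%, and WTP
thresholds 12,728 and 38,184 USD/QALY. The programme totals are treated as
authoritative annual per-capita costs; the underlying line items (shared
salaries, discounted equipment, one-time design costs) do not re-sum exactly
and are not modelled separately, so `first_year_cost` defaults to the
recurring total.

Synthetic values: acute-event costs 8,000 / 6,000 / 7,000 (MI/HF/stroke),
post-event annual costs 800 / 1,000 / 900, end-of-life cost 5,000 per death
event, and event-state utilities ordered acute < post < hypertension
(0.65/0.60/0.55 acute, 0.75/0.70/0.65 post). The end-of-life cost is applied
to every inflow into death regardless of origin state.

QALYs are occupancy-weighted utilities per cycle. "Trans" is the
*unconditional* mean sojourn in the prehypertension state (undiscounted
expected person-years before leaving it by any route); a
conditional-on-progressing definition was the open alternative, but the
unconditional form is the one a cohort trace yields directly and preserves
the ordering across strategies.

## Frontier analysis

Strategies are sorted by cost. Strong dominance: another strategy is no
dearer and no less effective, strict in one (exact duplicates are broken by
name order and logged). Extended dominance: among survivors, any strategy
whose incremental ICER is not strictly below that of the next more-effective
option is removed and the ladder recomputed until strictly increasing. This
is the standard lower-convex-hull frontier; tests verify exact agreement
with an exhaustive mixture-domination oracle on 1,000 random strategy sets.
Comparisons use full precision; reports round to 2 decimals. A worked
example in the test suite shows the algorithm is sensitive to input
rounding: with (cost, QALY) pairs rounded to 2 decimals, two adjacent ICERs
4 USD/QALY apart can swap order relative to the unrounded values, flipping a
marginal extended-dominance call.

## Sensitivity analyses

Parameters are addressed by dotted ids (`utility.hypertension`,
`cost.acute_mi`, `intervention.strengthen_exercise.annual_cost`,
`effect.strengthen_exercise.delta_sbp`, `risk.progression_5yr`, …).
Bounds are ±20% of the mean where no interval is available; the discount
rate varies over 0–8%.

* **One-way DSA** re-runs the full pipeline at each bound, all else at base
  case, reporting the ICER of a chosen comparison (default strengthen
  exercise vs non-intervention). Values that would violate a parameter's
  support are clipped with a logged warning — including clipping the
  hypertension utility at the prehypertension utility to preserve their
  ordering.
* **PSA** draws every registered parameter per iteration: beta for
  probabilities and utilities, gamma for costs and multipliers, normal for
  effect magnitudes (truncated at zero so an NPI never raises BP).
  Hyperparameters are moment-matched, treating the half-width of the bounds
  divided by 1.96 as the standard deviation; infeasible matches (beta
  variance ≥ m(1−m)) raise an error naming the parameter. The prehypertension
  utility is drawn before the hypertension utility so the ordering constraint
  clips the dependent parameter, not the anchor. Varying
  `risk.progression_5yr` re-solves the progression intercept per draw.
  The CEAC assigns each draw to the strategy with the highest net monetary
  benefit; the default WTP grid is 0–50,000 in steps of 500. All randomness
  flows from one explicit seed; same seed ⇒ bit-identical output. The default
  is 10,000 iterations (≈ 2 minutes on one CPU); tests use far fewer draws
  and check structural properties and prefix convergence instead of
  magnitudes.
* **Duration scenarios** re-run the CEA with the programme stopped after
  1…15 years or never. Strategies strongly dominated at base case are
  excluded (shrinking their programmes only moves them toward
  non-intervention).

## Budget impact

A static national cohort (no new entrants) of prehypertensive people aged
45–64, from a synthetic demographics table (~74M total, a few million per
year of age, thinning with age). Eligibility filters: age band (45–49,
50–54, 55–59, 60–64, all) and optionally high-CVE-risk-only, defined as
annual combined event probability above the count-weighted median of the
band (no published threshold exists; the median is configurable). Per year
of age, paired per-capita Markov runs over the 15-year horizon give the
programme-cost and medical-cost streams; "medical cost saving" is the
reduction, relative to non-intervention, in the costs of *all* states
downstream of prehypertension (management, acute, post, end-of-life).
Compliance (100/80/60/40/20%) gates both the effect and the variable
programme cost; any one-time design surcharge would be charged on all
enrolled. Flows are undiscounted, as is standard for affordability
analyses.

## What the synthetic fixtures do and do not show

The generator reproduces the *structure* of the original evaluation — state
topology, effect sizes, programme costs, printed utilities and thresholds,
the 40% progression anchor — but not its unpublished parameters (true risk
equations, event costs/utilities, census life table, demographic counts).
Consequently the package's absolute costs, QALYs, CEAC percentages and
budget magnitudes are fixture-dependent and are *not* estimates for any real
population; what is reproducible, and what the tests assert, is the
calibration anchor, the dominance classification, the ordering of Trans
across strategies, the direction of every sensitivity finding, and the
budget-impact conclusions (programme cost ≫ saving; targeting and shorter
duration cut cost with little loss of saving). On the default fixture the
base case lands on the same frontier as the published analysis
({non-intervention, strengthen exercise}, ICER ≈ 3,800 USD/QALY < WTP).

## Numerical choices and problem sizes

* Row-stochasticity enforced to 1e-12; trace conservation asserted to 1e-10.
* Calibration root solve: Brent on β₀ ∈ [−30, 10], xtol 1e-10; unreachable
  targets (outside (1e-6, 1−1e-6)) are rejected.
* ICERs are undefined (signalled, never computed) at zero QALY difference.
* Duration 0 and a zero-effect/zero-cost profile are exact aliases of
  non-intervention (bit-identical results, asserted in tests).
* Analysis drivers use the full defaults (lifetime horizon ≈ 56 cycles,
  10,000 PSA draws, 16 scenario durations, 12 BIA strategies); the test
  suite uses 3–600 PSA draws, 1,000 random frontier sets and 4 scenario
  durations, completing in well under two minutes.

## Known limitations

* Homogeneous cohort: one mean age and one BP level per run; heterogeneity
  is handled by running strata separately (as the BIA does by age).
* Event risks while hypertensive ignore any residual benefit of earlier BP
  control, and the representative hypertensive SBP is fixed.
* End-of-life cost applies to natural deaths as well as event deaths; the
  alternative (event deaths only) was not adopted because the accounting
  definition used here does not restrict it.
* DBP is tracked but never enters risk; utilities are time-invariant within
  a state; no half-cycle correction or age-specific utility decrement.
* The BIA's static cohort understates long-run saving (no replacement of
  decedents, no benefit beyond year 15).
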