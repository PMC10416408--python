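"""Synthetic fixture generator for every model input.

Published values are hard-wired verbatim (BP effects, programme cost totals,
prehypertension/hypertension utilities, the 5% discount rate, the 12,728 /
38,184 USD willingness-to-pay thresholds, the 40% five-year progression
anchor, the 10,000-iteration PSA default, the 15-year budget-impact horizon
and its compliance grid). Everything the original supplementary tables would
have supplied — the life table, risk-equation coefficients, CVE costs and
utilities, national demographics — is generated here and flagged
``synthetic`` in the serialized configuration.
"""

from __future__ import annotations

import io
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cea import ModelContext, ParameterSet
from .epi_inputs import (
    CohortProfile,
    LifeTable,
    RiskModel,
    TERMINAL_AGE,
    calibrate_progression_intercept,
)
from .interventions import (
    HYPERTENSION_MANAGEMENT_COST,
    InterventionProfile,
    default_interventions,
)
from .model_core import (
    ACUTE_HF,
    ACUTE_MI,
    ACUTE_STROKE,
    DEATH,
    HYPERTENSION,
    POST_HF,
    POST_MI,
    POST_STROKE,
    PREHYPERTENSION,
)
from .uncertainty import Distribution

DEFAULT_SEED = 2021
PSA_ITERATIONS = 10_000
BIA_HORIZON = 15
COMPLIANCE_GRID = (1.0, 0.8, 0.6, 0.4, 0.2)
PROGRESSION_TARGET_5Y = 0.40


@dataclass(frozen=True)
class FixtureBundle:
    """All generated inputs for one reproducible model run."""

    life_table: LifeTable
    risk: RiskModel
    cohort: CohortProfile
    params: ParameterSet
    interventions: dict
    demographics: pd.DataFrame
    seed: int

    def context(self) -> ModelContext:
        return ModelContext(
            cohort=self.cohort,
            life_table=self.life_table,
            risk=self.risk,
            params=self.params,
            progression_target=PROGRESSION_TARGET_5Y,
        )


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------


def gen_life_table(
    seed: int = DEFAULT_SEED,
    makeham: float = 5e-4,
    gompertz_b: float = 3e-5,
    gompertz_theta: float = 0.095,
    min_age: int = 30,
) -> LifeTable:
    """Gompertz–Makeham life table on ages ``min_age``..100.

    ``q(a) = 1 - exp(-(makeham + b * exp(theta * a)))`` with the terminal
    age closed at ``q(100) = 1``. Deterministic; ``seed`` is accepted for
    interface symmetry only.
    """
    if makeham < 0 or gompertz_b <= 0 or gompertz_theta <= 0:
        raise ValueError("Gompertz–Makeham parameters must be positive")
    ages = np.arange(min_age, TERMINAL_AGE + 1)
    hazard = makeham + gompertz_b * np.exp(gompertz_theta * ages)
    q = 1.0 - np.exp(-hazard)
    if np.any(q >= 1.0):
        raise ValueError("Gompertz–Makeham parameters yield q >= 1 before the terminal age")
    q[-1] = 1.0
    return LifeTable(ages=ages, q=q)


def gen_cohort(n: int = 10_000, seed: int = DEFAULT_SEED) -> CohortProfile:
    """Baseline prehypertensive cohort (homogeneous-cohort summary).

    Mid-life mean age, balanced sex mix, BP at the centre of the
    prehypertensive band; the summary is deterministic given the defaults.
    """
    return CohortProfile(
        n=n, age_mean=45.0, age_sd=8.0, female_fraction=0.5, sbp=130.0, dbp=85.0
    )


def calibrate_risk_model(
    target_5yr: float = PROGRESSION_TARGET_5Y,
    cohort: CohortProfile | None = None,
    **risk_overrides,
) -> RiskModel:
    """Risk model with the progression intercept solved for the anchor.

    The anchor is an untreated cohort at the baseline profile: cumulative
    five-cycle progression (mortality and CVE exits off) equals
    ``target_5yr``.
    """
    cohort = cohort or gen_cohort()
    base = RiskModel(prog_intercept=0.0, **risk_overrides)
    return calibrate_progression_intercept(
        base,
        target=target_5yr,
        start_age=cohort.age_mean,
        sbp=cohort.sbp,
        sex_mix=cohort.female_fraction,
        years=5,
    )


def _pct_bounds(mean: float, frac: float = 0.2) -> tuple:
    return mean * (1 - frac), mean * (1 + frac)


def gen_parameter_set(seed: int = DEFAULT_SEED) -> ParameterSet:
    """Costs, utilities and uncertainty metadata.

    Prehypertension/hypertension utilities, the hypertension-management
    cost, discount rate and WTP thresholds are published values; CVE-state
    costs and utilities are synthetic, ordered so acute years are worse and
    dearer than post-CVE years (acute utility < post utility < hypertension
    utility; acute cost >> annual management cost).
    """
    state_costs = {
        HYPERTENSION: HYPERTENSION_MANAGEMENT_COST,  # printed
        ACUTE_MI: 8000.0,  # synthetic
        ACUTE_HF: 6000.0,  # synthetic
        ACUTE_STROKE: 7000.0,  # synthetic
        POST_MI: 800.0,  # synthetic
        POST_HF: 1000.0,  # synthetic
        POST_STROKE: 900.0,  # synthetic
    }
    utilities = {
        PREHYPERTENSION: 0.931,  # printed
        HYPERTENSION: 0.8,  # printed
        ACUTE_MI: 0.65,  # synthetic
        ACUTE_HF: 0.60,  # synthetic
        ACUTE_STROKE: 0.55,  # synthetic
        POST_MI: 0.75,  # synthetic
        POST_HF: 0.70,  # synthetic
        POST_STROKE: 0.65,  # synthetic
        DEATH: 0.0,
    }
    end_of_life_cost = 5000.0  # synthetic

    # discount rate is varied deterministically (0-8%) in the DSA only and
    # therefore carries no sampling distribution here
    dists: dict = {}
    for s, u in utilities.items():
        lo, hi = _pct_bounds(u)
        dists[f"utility.{s}"] = Distribution("beta", u, lo, min(hi, 1.0))
    for s, c in state_costs.items():
        dists[f"cost.{s}"] = Distribution("gamma", c, *_pct_bounds(c))
    dists["cost.end_of_life"] = Distribution(
        "gamma", end_of_life_cost, *_pct_bounds(end_of_life_cost)
    )
    for name, iv in default_interventions().items():
        if iv.recurring_annual_cost > 0:
            dists[f"intervention.{name}.annual_cost"] = Distribution(
                "gamma", iv.recurring_annual_cost, *_pct_bounds(iv.recurring_annual_cost)
            )
        if iv.delta_sbp < 0:
            mag = -iv.delta_sbp
            dists[f"effect.{name}.delta_sbp"] = Distribution(
                "normal", mag, *_pct_bounds(mag)
            )
    dists["risk.progression_5yr"] = Distribution(
        "beta", PROGRESSION_TARGET_5Y, *_pct_bounds(PROGRESSION_TARGET_5Y)
    )
    base_risk = RiskModel(prog_intercept=0.0)
    for e in ("mi", "hf", "stroke"):
        p0 = base_risk.cve_base[e]
        dists[f"risk.cve_base.{e}"] = Distribution("beta", p0, *_pct_bounds(p0))
        f = base_risk.cve_case_fatality[e]
        dists[f"risk.case_fatality.{e}"] = Distribution("beta", f, *_pct_bounds(f))
        m = base_risk.post_cve_excess_mortality[e]
        dists[f"risk.post_excess.{e}"] = Distribution("gamma", m, *_pct_bounds(m))

    return ParameterSet(
        state_costs=state_costs,
        end_of_life_cost=end_of_life_cost,
        utilities=utilities,
        discount_rate=0.05,  # printed
        wtp=12_728.0,  # printed
        wtp_high=38_184.0,  # printed
        distributions=dists,
    )


def gen_demographics(seed: int = DEFAULT_SEED) -> pd.DataFrame:
    """Synthetic national prehypertensive counts per single year of age 45-64.

    Magnitudes are plausible for a large national population (a few million
    prehypertensive people per year of age, thinning with age); the true
    census-derived counts are not available. Bit-identical under a seed.
    """
    rng = np.random.default_rng(seed)
    ages = np.arange(45, 65)
    base = 4.2e6 * (1.0 - 0.012 * (ages - 45))
    jitter = rng.normal(0.0, 5e4, size=ages.size)
    counts = np.round(base + jitter).astype(int)
    return pd.DataFrame({"age": ages, "prehypertensive_count": counts})


def gen_fixture_bundle(seed: int = DEFAULT_SEED) -> FixtureBundle:
    """Generate the full input bundle for one model run."""
    cohort = gen_cohort(seed=seed)
    return FixtureBundle(
        life_table=gen_life_table(seed=seed),
        risk=calibrate_risk_model(cohort=cohort),
        cohort=cohort,
        params=gen_parameter_set(seed=seed),
        interventions=default_interventions(),
        demographics=gen_demographics(seed=seed),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Serialization (round-trip byte-identical)
# ---------------------------------------------------------------------------

_SYNTHETIC_FIELDS = [
    "life_table", "risk_model", "cve_state_costs", "cve_state_utilities",
    "end_of_life_cost", "demographics", "cohort_baseline",
]
_PRINTED_FIELDS = [
    "intervention_effects", "intervention_annual_costs",
    "utility.prehypertension", "utility.hypertension",
    "cost.hypertension_management", "discount_rate", "wtp", "wtp_high",
    "psa_iterations", "bia_horizon_years", "compliance_grid",
    "progression_target_5yr",
]


def bundle_to_config(bundle: FixtureBundle) -> dict:
    return {
        "seed": bundle.seed,
        "provenance": {
            "synthetic": sorted(_SYNTHETIC_FIELDS),
            "printed": sorted(_PRINTED_FIELDS),
        },
        "cohort": asdict(bundle.cohort),
        "risk_model": asdict(bundle.risk),
        "parameters": {
            "state_costs": dict(bundle.params.state_costs),
            "end_of_life_cost": bundle.params.end_of_life_cost,
            "utilities": dict(bundle.params.utilities),
            "discount_rate": bundle.params.discount_rate,
            "wtp": bundle.params.wtp,
            "wtp_high": bundle.params.wtp_high,
            "distributions": {
                k: asdict(d) for k, d in sorted(bundle.params.distributions.items())
            },
        },
        "interventions": {
            name: asdict(iv) for name, iv in bundle.interventions.items()
        },
        "analysis_defaults": {
            "psa_iterations": PSA_ITERATIONS,
            "bia_horizon_years": BIA_HORIZON,
            "compliance_grid": list(COMPLIANCE_GRID),
            "progression_target_5yr": PROGRESSION_TARGET_5Y,
        },
    }


def config_to_bundle(cfg: dict, life_table: LifeTable, demographics: pd.DataFrame) -> FixtureBundle:
    p = cfg["parameters"]
    dists = {
        k: Distribution(**d) for k, d in p.get("distributions", {}).items()
    }
    params = ParameterSet(
        state_costs=dict(p["state_costs"]),
        end_of_life_cost=p["end_of_life_cost"],
        utilities=dict(p["utilities"]),
        discount_rate=p["discount_rate"],
        wtp=p["wtp"],
        wtp_high=p["wtp_high"],
        distributions=dists,
    )
    return FixtureBundle(
        life_table=life_table,
        risk=RiskModel(**cfg["risk_model"]),
        cohort=CohortProfile(**cfg["cohort"]),
        params=params,
        interventions={
            name: InterventionProfile(**iv) for name, iv in cfg["interventions"].items()
        },
        demographics=demographics,
        seed=cfg["seed"],
    )


def dump_config_yaml(bundle: FixtureBundle) -> str:
    return yaml.safe_dump(bundle_to_config(bundle), sort_keys=True)


def write_bundle(bundle: FixtureBundle, out_dir) -> dict:
    """Write config.yaml, life_table.csv and demographics.csv; return paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "config": out / "config.yaml",
        "life_table": out / "life_table.csv",
        "demographics": out / "demographics.csv",
    }
    paths["config"].write_text(dump_config_yaml(bundle))
    bundle.life_table.to_csv(paths["life_table"])
    bundle.demographics.to_csv(paths["demographics"], index=False)
    return paths


def load_bundle(in_dir) -> FixtureBundle:
    d = Path(in_dir)
    cfg = yaml.safe_load((d / "config.yaml").read_text())
    life = LifeTable.from_csv(d / "life_table.csv")
    demo = pd.read_csv(d / "demographics.csv")
    return config_to_bundle(cfg, life, demo)
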