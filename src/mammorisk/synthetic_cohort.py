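"""Synthetic reference populations and prospective cohorts with known truth.

The generator emulates the study conditions of a questionnaire + PRS +
mammographic-density breast cancer risk model: twelve questionnaire risk
factors (reproductive, anthropometric, lifestyle, benign disease, hormone
use), a standardized PRS coupled to family history, a 4-level density
category driven by age/BMI/reproductive covariates through a
proportional-odds model, and discrete-time outcomes (breast cancer vs.
competing death vs. censoring) under the multiplicative hazard model.

Validation cohorts follow the registry-linkage convention: the first year
after study entry is excluded from validation (events there are recorded but
flagged), and follow-up runs for five years starting one year after entry.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .model_core import calibrate_baseline_hazard
from .rates import BaselineHazard, RateTable
from .reference_population import (DensityImputationModel, PrsFamilyModel,
                                   impute_density,
                                   simulate_prs_given_family_history)
from .schema import (AGE_STRATUM_BOUNDARY, CovariateDef, CovariateSchema,
                     ModelSpec)

logger = logging.getLogger("mammorisk")

__all__ = [
    "ScenarioConfig",
    "load_rate_table",
    "default_schema",
    "default_log_rr",
    "default_model_spec",
    "default_density_model",
    "default_scenario",
    "generate_reference",
    "simulate_outcomes",
    "sample_nested_case_control",
    "simulate_cohort",
]

FOLLOWUP_YEARS = 5

QUESTIONNAIRE_COVARIATES = (
    "age_menarche_cat", "parity_cat", "age_first_birth_cat",
    "age_menopause_cat", "height_cm", "bmi", "alcohol_g_day",
    "family_history", "benign_breast_disease", "oc_use", "mht_use", "mht_type",
)


def load_rate_table(name: str) -> RateTable:
    """Load a bundled rate table: ``incidence_us``, ``mortality_us``,
    ``incidence_sweden`` or ``mortality_sweden``."""
    ref = resources.files("mammorisk.data").joinpath(f"{name}.csv")
    with resources.as_file(ref) as path:
        return RateTable.from_csv(path)


# ---------------------------------------------------------------------------
# default model configuration (literature-plausible log relative risks)
# ---------------------------------------------------------------------------

def default_schema() -> CovariateSchema:
    """Covariate schema: 12 questionnaire risk factors + PRS + density."""
    c, k = CovariateDef, "categorical"
    return CovariateSchema((
        c("age_menarche_cat", k, ("ge14", "12_13", "lt12"), "ge14"),
        c("parity_cat", k, ("parous_1_2", "nulliparous", "parous_3plus"),
          "parous_1_2"),
        c("age_first_birth_cat", k, ("lt25", "25_29", "ge30"), "lt25"),
        c("age_menopause_cat", k, ("premenopausal", "lt45", "ge45"),
          "premenopausal"),
        c("height_cm", "continuous", reference_value=165.0, unit="cm"),
        c("bmi", "continuous", reference_value=25.0, unit="kg/m2"),
        c("alcohol_g_day", "continuous", reference_value=0.0, unit="g/day"),
        c("family_history", k, ("no", "yes"), "no"),
        c("benign_breast_disease", k, ("no", "yes"), "no"),
        c("oc_use", k, ("never", "ever"), "never"),
        c("mht_use", k, ("never", "former", "current"), "never"),
        c("mht_type", k, ("none", "estrogen", "combined"), "none"),
        c("prs", "continuous", reference_value=0.0, unit="SD"),
        c("density_category", k, ("1", "2", "3", "4"), "1"),
    ))


def default_log_rr(age_stratum: str) -> dict:
    """Literature-plausible log relative risks per covariate.

    The density relative risks differ by stratum (stronger age-adjusted
    associations among younger women), with the extreme-vs-fatty ratio inside
    the established 2- to 4-fold band.
    """
    ln = math.log
    density = ({"1": 0.0, "2": ln(1.8), "3": ln(2.7), "4": ln(3.6)}
               if age_stratum == "under50" else
               {"1": 0.0, "2": ln(1.6), "3": ln(2.3), "4": ln(3.0)})
    return {
        "age_menarche_cat": {"ge14": 0.0, "12_13": ln(1.10), "lt12": ln(1.20)},
        "parity_cat": {"parous_1_2": 0.0, "nulliparous": ln(1.15),
                       "parous_3plus": ln(0.90)},
        "age_first_birth_cat": {"lt25": 0.0, "25_29": ln(1.10), "ge30": ln(1.25)},
        "age_menopause_cat": {"premenopausal": 0.0, "lt45": ln(0.85),
                              "ge45": ln(1.05)},
        "height_cm": ln(1.10) / 10.0,
        "bmi": 0.015,
        "alcohol_g_day": 0.007,
        "family_history": {"no": 0.0, "yes": ln(1.80)},
        "benign_breast_disease": {"no": 0.0, "yes": ln(1.50)},
        "oc_use": {"never": 0.0, "ever": ln(1.07)},
        "mht_use": {"never": 0.0, "former": ln(1.05), "current": ln(1.30)},
        "mht_type": {"none": 0.0, "estrogen": ln(1.10), "combined": ln(1.50)},
        "prs": ln(1.60),
        "density_category": density,
    }


def default_model_spec(age_stratum: str) -> ModelSpec:
    return ModelSpec(age_stratum, default_schema(), default_log_rr(age_stratum))


def default_density_model() -> DensityImputationModel:
    """Proportional-odds density model whose induced marginal over a US-like
    age 40-74 population is close to the BI-RADS-like 10/40/40/10 split
    (categories 3-4 together about half of women)."""
    return DensityImputationModel(
        predictors=("age", "bmi", "nulliparous", "postmenopausal", "mht_current"),
        slopes=np.array([-0.045, -0.12, 0.35, -0.40, 0.30]),
        cut_points=np.array([-8.40, -5.94, -3.48]),
        fill_values={"age": 55.0, "bmi": 26.5, "nulliparous": 0.15,
                     "postmenopausal": 0.60, "mht_current": 0.10},
    )


DEFAULT_MARGINALS = {
    "age_menarche_cat": {"kind": "categorical",
                         "levels": ["ge14", "12_13", "lt12"],
                         "probs": [0.30, 0.50, 0.20]},
    "parity_cat": {"kind": "categorical",
                   "levels": ["parous_1_2", "nulliparous", "parous_3plus"],
                   "probs": [0.55, 0.15, 0.30]},
    "age_first_birth_cat": {"kind": "categorical",
                            "levels": ["lt25", "25_29", "ge30"],
                            "probs": [0.45, 0.30, 0.25]},
    "height_cm": {"kind": "normal", "mean": 165.0, "sd": 6.5,
                  "lo": 140.0, "hi": 195.0},
    "bmi": {"kind": "normal", "mean": 26.5, "sd": 5.0, "lo": 15.0, "hi": 50.0},
    "alcohol_g_day": {"kind": "exponential", "mean": 5.0},
    "family_history": {"kind": "categorical", "levels": ["no", "yes"],
                       "probs": [0.88, 0.12]},
    "benign_breast_disease": {"kind": "categorical", "levels": ["no", "yes"],
                              "probs": [0.75, 0.25]},
    "oc_use": {"kind": "categorical", "levels": ["never", "ever"],
               "probs": [0.40, 0.60]},
}


@dataclass(frozen=True)
class ScenarioConfig:
    """Everything needed to generate a reference population and a cohort.

    ``marginals`` configures independent covariate marginals; menopausal
    status, hormone-therapy use, density and PRS are generated with built-in
    age / covariate dependence (menopause probability rises with age; MHT use
    concentrates among postmenopausal women; density follows the
    proportional-odds model; PRS is coupled to family history).
    """

    name: str = "over50-us"
    n: int = 10000
    seed: int = 0
    age_lo: int = 50
    age_hi: int = 70
    marginals: dict = field(default_factory=lambda: dict(DEFAULT_MARGINALS))
    density_model: DensityImputationModel = field(default_factory=default_density_model)
    prs_model: PrsFamilyModel = field(default_factory=PrsFamilyModel)
    spec_under50: ModelSpec = field(
        default_factory=lambda: default_model_spec("under50"))
    spec_over50: ModelSpec = field(
        default_factory=lambda: default_model_spec("over50"))
    incidence: RateTable = field(default_factory=lambda: load_rate_table("incidence_us"))
    mortality: RateTable = field(default_factory=lambda: load_rate_table("mortality_us"))
    censoring_rate: float = 0.02
    followup_years: int = FOLLOWUP_YEARS
    controls_per_case: int = 1

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not (0.0 <= self.censoring_rate < 1.0):
            raise ValueError("censoring_rate must lie in [0, 1)")
        if self.age_hi < self.age_lo:
            raise ValueError("age_hi must be >= age_lo")
        # entries project one year of exclusion plus the follow-up window
        if not self.incidence.covers(self.age_lo,
                                     self.age_hi + self.followup_years + 1):
            raise ValueError("incidence table does not cover the entry band "
                             "plus follow-up window")
        for name, spec in self.marginals.items():
            if spec["kind"] == "categorical":
                probs = np.asarray(spec["probs"], dtype=float)
                if np.any(probs < 0) or not np.isclose(probs.sum(), 1.0):
                    raise ValueError(f"marginal {name!r}: probabilities must be "
                                     "non-negative and sum to 1")
                if len(probs) != len(spec["levels"]):
                    raise ValueError(f"marginal {name!r}: levels/probs mismatch")

    def spec_for_stratum(self, age: float) -> ModelSpec:
        return (self.spec_under50 if age < AGE_STRATUM_BOUNDARY
                else self.spec_over50)

    def replace(self, **changes) -> "ScenarioConfig":
        return dataclasses.replace(self, **changes)


def default_scenario(stratum: str = "over50", n: int = 10000, seed: int = 0,
                     country: str = "us", **overrides) -> ScenarioConfig:
    """Study-condition defaults: entry ages 40-49 (under-50 scenario) or
    50-70 (over-50 scenario), US or Sweden rate tables."""
    if stratum not in ("under50", "over50"):
        raise ValueError("stratum must be 'under50' or 'over50'")
    age_lo, age_hi = (40, 49) if stratum == "under50" else (50, 70)
    cfg = ScenarioConfig(
        name=f"{stratum}-{country}", n=n, seed=seed, age_lo=age_lo, age_hi=age_hi,
        incidence=load_rate_table(f"incidence_{country}"),
        mortality=load_rate_table(f"mortality_{country}"),
    )
    return cfg.replace(**overrides) if overrides else cfg


# ---------------------------------------------------------------------------
# reference generation
# ---------------------------------------------------------------------------

def _sample_marginal(rng: np.random.Generator, n: int, spec: dict):
    kind = spec["kind"]
    if kind == "categorical":
        return rng.choice(np.asarray(spec["levels"], dtype=object), size=n,
                          p=spec["probs"])
    if kind == "normal":
        x = rng.normal(spec["mean"], spec["sd"], size=n)
        return np.clip(x, spec.get("lo", -np.inf), spec.get("hi", np.inf))
    if kind == "exponential":
        return rng.exponential(spec["mean"], size=n)
    if kind == "point":
        value = spec["value"]
        return np.full(n, value, dtype=object if isinstance(value, str) else float)
    raise ValueError(f"unknown marginal kind {kind!r}")


def generate_reference(config: ScenarioConfig) -> pd.DataFrame:
    """Sample a reference population, then augment it with density and PRS.

    Fully reproducible from ``config.seed``.  The output carries the schema
    covariates plus numeric helper columns (``age``, ``nulliparous``,
    ``postmenopausal``, ``mht_current``) used by the density model, and a unit
    ``weight`` column.
    """
    ss = np.random.SeedSequence(config.seed)
    s_cov, s_dens, s_prs = ss.spawn(3)
    rng = np.random.default_rng(s_cov)
    n = config.n

    df = pd.DataFrame({"age": rng.integers(config.age_lo, config.age_hi + 1,
                                           size=n).astype(float)})
    for name, spec in config.marginals.items():
        df[name] = _sample_marginal(rng, n, spec)

    # menopausal status depends on age; MHT use concentrates after menopause.
    # Columns supplied through `marginals` (including these derived ones,
    # density_category and prs) are taken as given and not re-derived.
    if "age_menopause_cat" in df.columns:
        post = (df["age_menopause_cat"] != "premenopausal").to_numpy()
    else:
        p_post = 1.0 / (1.0 + np.exp(-(df["age"].to_numpy() - 50.0) / 2.5))
        post = rng.uniform(size=n) < p_post
        df["age_menopause_cat"] = np.where(
            post, np.where(rng.uniform(size=n) < 0.30, "lt45", "ge45"),
            "premenopausal")
    if "mht_use" not in df.columns:
        u = rng.uniform(size=n)
        df["mht_use"] = np.where(
            post,
            np.select([u < 0.15, u < 0.40], ["current", "former"], "never"),
            np.select([u < 0.02, u < 0.07], ["current", "former"], "never"))
    current = (df["mht_use"] == "current").to_numpy()
    if "mht_type" not in df.columns:
        df["mht_type"] = np.where(
            current,
            np.where(rng.uniform(size=n) < 0.4, "estrogen", "combined"),
            "none")

    # numeric helpers for the density model
    df["nulliparous"] = (df["parity_cat"] == "nulliparous").astype(float)
    df["postmenopausal"] = post.astype(float)
    df["mht_current"] = current.astype(float)
    df["weight"] = 1.0

    df = impute_density(df, config.density_model, s_dens)
    df = simulate_prs_given_family_history(df, config.prs_model, s_prs)
    return df


# ---------------------------------------------------------------------------
# outcome simulation
# ---------------------------------------------------------------------------

def _rr_by_entry_stratum(df: pd.DataFrame, entry: np.ndarray, spec) -> np.ndarray:
    """Relative risk per row; the stratum model is fixed by entry age for the
    whole projection, matching the prediction-side convention."""
    from .model_core import relative_risk_frame
    if isinstance(spec, ModelSpec):
        return relative_risk_frame(df, spec)
    rr = np.empty(len(df))
    under = entry < AGE_STRATUM_BOUNDARY
    for mask, key in ((under, "under50"), (~under, "over50")):
        if mask.any():
            rr[mask] = relative_risk_frame(df.loc[mask], spec[key])
    return rr


def simulate_outcomes(
    reference: pd.DataFrame,
    true_spec,
    lambda0: BaselineHazard,
    mortality: RateTable,
    config: ScenarioConfig,
    seed,
) -> pd.DataFrame:
    """Discrete-time outcome simulation under the multiplicative hazard model.

    Each woman is followed from her entry age through one excluded year plus
    ``config.followup_years`` follow-up years.  Within a year, breast cancer
    (probability ``h = lambda0 * rr``) is drawn before other-cause death
    (``mu``) before random censoring (``config.censoring_rate``).  Events in
    the first year are recorded but flagged ``first_year_excluded`` and do not
    count as observed cases; remaining women are administratively censored at
    the end of follow-up (``event == "none"``).

    ``true_spec`` may be one :class:`ModelSpec` or ``{"under50": ..., "over50": ...}``.
    """
    rng = np.random.default_rng(seed)
    n = len(reference)
    entry = reference["age"].to_numpy(dtype=float).astype(int)
    rr = _rr_by_entry_stratum(reference, entry, true_spec)
    censor = config.censoring_rate

    event = np.full(n, "none", dtype=object)
    event_time = np.full(n, float(config.followup_years + 1))
    alive = np.ones(n, dtype=bool)
    total_years = config.followup_years + 1  # year 0 precedes follow-up
    for t in range(total_years):
        if not alive.any():
            break
        idx = np.flatnonzero(alive)
        ages = entry[idx] + t
        h = lambda0.at(ages) * rr[idx]
        mu = mortality.at(ages)
        if np.any(h + mu + censor > 1.0):
            raise ValueError("annual cancer + death + censoring probability "
                             "exceeds 1; rejecting scenario config")
        u = rng.uniform(size=idx.size)
        is_case = u < h
        is_death = (~is_case) & (u < h + mu)
        is_cens = (~is_case) & (~is_death) & (u < h + mu + censor)
        hit = is_case | is_death | is_cens
        event[idx[is_case]] = "case"
        event[idx[is_death]] = "death"
        event[idx[is_cens]] = "censored"
        event_time[idx[hit]] = t + 1.0
        alive[idx[hit]] = False

    cohort = reference.copy()
    cohort["entry_age"] = entry.astype(float)
    cohort["event"] = event
    cohort["event_time"] = event_time
    cohort["first_year_excluded"] = (event != "none") & (event_time <= 1.0)
    cohort["observed_case"] = (event == "case") & ~cohort["first_year_excluded"]
    if "weight" not in cohort.columns:
        cohort["weight"] = 1.0
    return cohort


def sample_nested_case_control(cohort: pd.DataFrame, controls_per_case: int,
                               seed) -> pd.DataFrame:
    """Nested case-control subsample: keep all eligible cases, sample controls
    without replacement, and weight controls by the inverse sampling fraction
    so weighted control counts match the cohort."""
    if controls_per_case < 1:
        raise ValueError("controls_per_case must be >= 1")
    rng = np.random.default_rng(seed)
    eligible = ~cohort["first_year_excluded"].to_numpy(dtype=bool)
    is_case = cohort["observed_case"].to_numpy(dtype=bool)
    case_idx = np.flatnonzero(eligible & is_case)
    ctrl_idx = np.flatnonzero(eligible & ~is_case)
    if case_idx.size == 0:
        raise ValueError("cohort contains no eligible cases")
    n_want = controls_per_case * case_idx.size
    if n_want >= ctrl_idx.size:
        logger.warning("requested %d controls but only %d available; keeping "
                       "all with weight 1", n_want, ctrl_idx.size)
        picked = ctrl_idx
        ctrl_w = 1.0
    else:
        picked = rng.choice(ctrl_idx, size=n_want, replace=False)
        ctrl_w = ctrl_idx.size / n_want
    sub = cohort.iloc[np.sort(np.concatenate([case_idx, picked]))].copy()
    w = sub["weight"].to_numpy(dtype=float)
    w[~sub["observed_case"].to_numpy(dtype=bool)] *= ctrl_w
    sub["weight"] = w
    return sub


def simulate_cohort(config: ScenarioConfig):
    """Convenience pipeline: reference -> calibrated baseline -> cohort.

    Returns ``(reference, baseline_hazard, cohort)``.  The baseline hazard is
    calibrated stratum by stratum against the configured incidence table.
    """
    ss = np.random.SeedSequence(config.seed)
    _, _, _, s_out = ss.spawn(4)
    reference = generate_reference(config)
    ages = config.incidence.ages
    under = ages < AGE_STRATUM_BOUNDARY
    lam0 = np.empty(len(ages))
    for mask, spec in ((under, config.spec_under50), (~under, config.spec_over50)):
        if mask.any():
            sub = calibrate_baseline_hazard(
                spec, RateTable(ages[mask], config.incidence.rates[mask]), reference)
            lam0[mask] = sub.lambda0
    lambda0 = BaselineHazard(ages, lam0)
    spec = {"under50": config.spec_under50, "over50": config.spec_over50}
    cohort = simulate_outcomes(reference, spec, lambda0, config.mortality,
                               config, s_out)
    return reference, lambda0, cohort
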