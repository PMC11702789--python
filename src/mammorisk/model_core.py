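"""Absolute risk synthesis: multiplicative relative risks, baseline-hazard
calibration against population incidence, and 5-year absolute risk with
competing mortality.

The model follows the absolute-risk synthesis framework used by literature-based
breast cancer models (Gail-type / iCARE-type): a multiplicative relative-risk
function ``rr(z) = exp(sum_j beta_j z_j)`` over questionnaire risk factors, a
standardized polygenic risk score and a 4-level mammographic density variable,
combined with registry age-specific incidence ``lambda_m(a)`` and competing
mortality ``mu(a)``.  The baseline hazard ``lambda0(a)`` is calibrated so that
the population-average hazard reproduces the registry incidence, and absolute
risk over a horizon of ``tau`` years is accumulated on a discrete annual grid:

    AR = sum_{t=0}^{tau-1} h(a+t) * prod_{u<t} (1 - h(a+u) - mu(a+u)),
    h(x) = min(lambda0(x) * rr, 1 - mu(x)).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .rates import BaselineHazard, RateTable
from .schema import AGE_STRATUM_BOUNDARY, ModelSpec

logger = logging.getLogger("mammorisk")

__all__ = [
    "RiskProjection",
    "relative_risk",
    "relative_risk_frame",
    "percent_density_to_category",
    "calibrate_baseline_hazard",
    "absolute_risk",
    "project_risks",
    "impute_missing_profile",
    "AbsoluteRiskModel",
]


@dataclass(frozen=True)
class RiskProjection:
    """Absolute risk of disease over ``[entry_age, entry_age + horizon_tau)``."""

    risk: float
    entry_age: float
    horizon_tau: int = 5

    def __post_init__(self) -> None:
        if not (0.0 <= self.risk <= 1.0):
            raise ValueError(f"risk must lie in [0, 1], got {self.risk}")


# ---------------------------------------------------------------------------
# relative risk
# ---------------------------------------------------------------------------

def _is_missing(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and np.isnan(value):
        return True
    return False


def relative_risk(profile: Mapping, spec: ModelSpec) -> float:
    """Multiplicative relative risk ``exp(sum beta . z)`` of one profile.

    Continuous covariates are centred at their declared reference value, so the
    all-reference profile has relative risk exactly 1.  Every schema covariate
    must be present and non-missing; use :func:`impute_missing_profile` for
    profiles with gaps.
    """
    log_rr = 0.0
    for cov in spec.schema:
        if cov.name not in profile or _is_missing(profile[cov.name]):
            raise KeyError(f"profile is missing covariate {cov.name!r}")
        value = profile[cov.name]
        entry = spec.log_rr[cov.name]
        if cov.kind == "categorical":
            value = str(value)
            if value not in entry:
                raise ValueError(f"unknown level {value!r} for covariate {cov.name!r}")
            log_rr += entry[value]
        else:
            x = float(value)
            if not np.isfinite(x):
                raise ValueError(f"non-finite value for covariate {cov.name!r}")
            log_rr += entry * (x - cov.reference_value)
    return float(np.exp(log_rr))


def relative_risk_frame(df: pd.DataFrame, spec: ModelSpec) -> np.ndarray:
    """Vectorized :func:`relative_risk` over the rows of a covariate table."""
    log_rr = np.zeros(len(df))
    for cov in spec.schema:
        if cov.name not in df.columns:
            raise KeyError(f"dataset is missing covariate column {cov.name!r}")
        entry = spec.log_rr[cov.name]
        col = df[cov.name]
        if cov.kind == "categorical":
            mapped = col.astype(str).map(entry)
            if mapped.isna().any():
                bad = sorted(col[mapped.isna()].astype(str).unique())
                raise ValueError(f"unknown level(s) {bad} for covariate {cov.name!r}")
            log_rr += mapped.to_numpy(dtype=float)
        else:
            x = col.to_numpy(dtype=float)
            if not np.all(np.isfinite(x)):
                raise ValueError(f"non-finite value(s) for covariate {cov.name!r}")
            log_rr += entry * (x - cov.reference_value)
    return np.exp(log_rr)


# ---------------------------------------------------------------------------
# percent density -> 4-level category
# ---------------------------------------------------------------------------

#: Upper bin edges of the first three density categories per measurement scheme.
#: Intervals are half-open on the right ([0,10), [10,25), [25,50), [50,100] for
#: Cumulus), giving an exhaustive, non-overlapping partition of [0, 100].
DENSITY_SCHEMES = {
    "cumulus": (10.0, 25.0, 50.0),
    "stratus": (2.0, 8.0, 49.0),
}


def percent_density_to_category(percent, scheme: str = "cumulus"):
    """Convert percent mammographic density to an ordinal 1-4 category.

    The thresholds approximate BI-RADS categories from area-based percent
    density measurements (Cumulus or STRATUS conventions).
    """
    if scheme not in DENSITY_SCHEMES:
        raise ValueError(f"unknown density scheme {scheme!r}; "
                         f"expected one of {sorted(DENSITY_SCHEMES)}")
    p = np.asarray(percent, dtype=float)
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 100):
        raise ValueError("percent density must lie in [0, 100]")
    edges = np.asarray(DENSITY_SCHEMES[scheme])
    cat = np.searchsorted(edges, p, side="right") + 1
    if np.isscalar(percent) or np.ndim(percent) == 0:
        return int(cat)
    return cat.astype(int)


# ---------------------------------------------------------------------------
# baseline-hazard calibration
# ---------------------------------------------------------------------------

def _reference_weights(reference: pd.DataFrame, weights) -> np.ndarray:
    if weights is not None:
        w = np.asarray(weights, dtype=float)
    elif "weight" in reference.columns:
        w = reference["weight"].to_numpy(dtype=float)
    else:
        w = np.ones(len(reference))
    if len(w) != len(reference):
        raise ValueError("weights length does not match reference rows")
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be non-negative with positive sum")
    return w


def calibrate_baseline_hazard(
    spec: ModelSpec,
    incidence: RateTable,
    reference: pd.DataFrame,
    weights=None,
    attrition_adjusted: bool = False,
) -> BaselineHazard:
    """Calibrate the baseline hazard to a marginal incidence table.

    Under the rare-disease approximation the age-``a`` baseline hazard is
    ``lambda0(a) = lambda_m(a) / W`` with ``W`` the reference-weighted mean
    relative risk, which makes the reference-weighted mean of
    ``lambda0(a) * rr_i`` equal to ``lambda_m(a)`` exactly at every age.

    With ``attrition_adjusted=True`` the reference weights are additionally
    depleted age by age in proportion to each individual's disease hazard
    (higher-risk women leave the risk set faster), a refinement of the
    rare-disease approximation.  Competing mortality acts identically on every
    individual under this model and therefore cancels from the weighted mean.
    """
    if len(reference) == 0:
        raise ValueError("reference dataset is empty")
    w = _reference_weights(reference, weights)
    rr = relative_risk_frame(reference, spec)
    if not attrition_adjusted:
        mean_rr = float(np.sum(w * rr) / np.sum(w))
        lam0 = incidence.rates / mean_rr
        return BaselineHazard(incidence.ages, lam0)
    w_live = w.astype(float).copy()
    lam0 = np.empty_like(incidence.rates)
    for i, lam_m in enumerate(incidence.rates):
        mean_rr = float(np.sum(w_live * rr) / np.sum(w_live))
        lam0[i] = lam_m / mean_rr
        w_live = w_live * np.clip(1.0 - lam0[i] * rr, 0.0, 1.0)
    return BaselineHazard(incidence.ages, lam0)


# ---------------------------------------------------------------------------
# absolute risk
# ---------------------------------------------------------------------------

def project_risks(
    rr,
    entry_age,
    lambda0: BaselineHazard,
    mortality: RateTable,
    horizon: int = 5,
) -> np.ndarray:
    """Vectorized discrete-time absolute risk for arrays of rr / entry age.

    Annual disease hazard ``h = lambda0(age) * rr`` competes with mortality
    ``mu(age)``; where ``h + mu`` would exceed 1, ``h`` is clamped to
    ``1 - mu`` and a warning is logged (degenerate-input safety).
    """
    rr = np.atleast_1d(np.asarray(rr, dtype=float))
    entry = np.atleast_1d(np.asarray(entry_age))
    if np.any(rr < 0) or np.any(~np.isfinite(rr)):
        raise ValueError("relative risks must be finite and non-negative")
    if np.any(np.asarray(horizon) < 0):
        raise ValueError("horizon must be non-negative")
    entry_i = entry.astype(int)
    if horizon > 0:
        for table, what in ((lambda0, "baseline hazard"), (mortality, "mortality")):
            if (entry_i.min() < table.age_min
                    or entry_i.max() + horizon - 1 > table.age_max):
                raise ValueError(
                    f"projection window exceeds {what} age support "
                    f"[{table.age_min}, {table.age_max}]")
    risk = np.zeros_like(rr)
    surv = np.ones_like(rr)
    n_clamped = 0
    for t in range(horizon):
        ages = entry_i + t
        h = lambda0.at(ages) * rr
        mu = mortality.at(ages)
        over = h > 1.0 - mu
        if np.any(over):
            n_clamped += int(np.sum(over))
            h = np.minimum(h, 1.0 - mu)
        risk += surv * h
        surv *= 1.0 - h - mu
    if n_clamped:
        logger.warning("clamped disease hazard to 1 - mu in %d person-year(s)",
                       n_clamped)
    return np.clip(risk, 0.0, 1.0)


def absolute_risk(
    profile: Mapping,
    spec: ModelSpec,
    lambda0: BaselineHazard,
    mortality: RateTable,
    entry_age: float,
    horizon_tau: int = 5,
) -> RiskProjection:
    """Absolute risk of disease within ``horizon_tau`` years from ``entry_age``
    for a single covariate profile, accounting for competing mortality."""
    rr = relative_risk(profile, spec)
    risk = project_risks(rr, entry_age, lambda0, mortality, horizon=horizon_tau)
    return RiskProjection(float(risk[0]), float(entry_age), int(horizon_tau))


# ---------------------------------------------------------------------------
# missing-covariate marginalization
# ---------------------------------------------------------------------------

def impute_missing_profile(
    profile: Mapping,
    spec: ModelSpec,
    reference: pd.DataFrame,
    weights=None,
) -> float:
    """Effective relative risk of a profile with missing entries.

    The multiplicative model factorizes, so the profile's relative risk is the
    product of the observed covariates' contribution and the reference-weighted
    mean contribution of the missing covariates among reference individuals
    consistent with the observed entries (consistency is exact matching on
    observed categorical values; continuous covariates do not restrict the
    stratum).  With nothing missing this equals :func:`relative_risk` exactly;
    with everything missing it equals the reference-mean relative risk.
    """
    observed = {name: profile[name] for name in spec.schema.names
                if name in profile and not _is_missing(profile[name])}
    missing = [name for name in spec.schema.names if name not in observed]
    if not missing:
        return relative_risk(profile, spec)
    if len(reference) == 0:
        raise ValueError("reference dataset is empty")
    w = _reference_weights(reference, weights)

    # contribution of the observed covariates (missing ones at reference)
    obs_spec = spec.subset(list(observed)) if observed else None
    rr_obs = relative_risk(observed, obs_spec) if observed else 1.0

    # stratum of reference rows consistent with the observed categorical values
    mask = np.ones(len(reference), dtype=bool)
    for name, value in observed.items():
        if spec.schema[name].kind == "categorical":
            mask &= reference[name].astype(str).to_numpy() == str(value)
    if not mask.any():
        logger.warning("no reference rows match the observed covariates; "
                       "falling back to the marginal reference distribution")
        mask = np.ones(len(reference), dtype=bool)

    miss_spec = spec.subset(missing)
    rr_miss = relative_risk_frame(reference.loc[mask], miss_spec)
    w_m = w[mask]
    return float(rr_obs * np.sum(w_m * rr_miss) / np.sum(w_m))


# ---------------------------------------------------------------------------
# estimator
# ---------------------------------------------------------------------------

class AbsoluteRiskModel(BaseEstimator):
    """Age-stratified 5-year absolute risk model (scikit-learn estimator).

    Parameters
    ----------
    spec_under50, spec_over50 : ModelSpec
        Relative-risk models for entry before / at-or-after age 50 (the strata
        are modelled separately; either may be omitted if the other covers all
        entries).  A projection uses the single stratum selected by its entry
        age; there is no blending across the age-50 boundary.
    incidence, mortality : RateTable
        Marginal disease incidence and competing (non-disease) mortality.
    attrition_adjusted : bool
        Refine the rare-disease baseline calibration by depleting the
        reference risk set age by age (default off).
    horizon : int
        Default projection horizon tau in years.

    Attributes
    ----------
    baseline_hazard_ : BaselineHazard
        Calibrated baseline hazard over the incidence table's age support; at
        each age the stratum model for that age supplies the mean relative
        risk.
    reference_ : pandas.DataFrame
        The reference dataset used for calibration (kept for marginalizing
        profiles with missing covariates).
    """

    def __init__(self, spec_under50=None, spec_over50=None, incidence=None,
                 mortality=None, attrition_adjusted=False, horizon=5):
        self.spec_under50 = spec_under50
        self.spec_over50 = spec_over50
        self.incidence = incidence
        self.mortality = mortality
        self.attrition_adjusted = attrition_adjusted
        self.horizon = horizon

    # -- helpers --

    def _spec_for_age(self, age: float) -> ModelSpec:
        if age < AGE_STRATUM_BOUNDARY:
            spec = self.spec_under50 if self.spec_under50 is not None else self.spec_over50
        else:
            spec = self.spec_over50 if self.spec_over50 is not None else self.spec_under50
        if spec is None:
            raise ValueError("no model spec configured")
        return spec

    # -- estimator API --

    def fit(self, X: pd.DataFrame, y=None, sample_weight=None):
        """Calibrate the baseline hazard from a reference population ``X``."""
        if self.incidence is None or self.mortality is None:
            raise ValueError("incidence and mortality rate tables are required")
        if self.spec_under50 is None and self.spec_over50 is None:
            raise ValueError("at least one age-stratum ModelSpec is required")
        if len(X) == 0:
            raise ValueError("reference dataset is empty")
        ages = self.incidence.ages
        lam0 = np.empty(len(ages), dtype=float)
        for stratum_mask, spec in self._stratum_specs(ages):
            if not stratum_mask.any():
                continue
            sub = calibrate_baseline_hazard(
                spec, RateTable(ages[stratum_mask], self.incidence.rates[stratum_mask]),
                X, weights=sample_weight,
                attrition_adjusted=self.attrition_adjusted)
            lam0[stratum_mask] = sub.lambda0
        self.baseline_hazard_ = BaselineHazard(ages, lam0)
        self.reference_ = X
        self.reference_weights_ = _reference_weights(X, sample_weight)
        return self

    def _stratum_specs(self, ages: np.ndarray):
        under = ages < AGE_STRATUM_BOUNDARY
        if under.any():
            yield under, self._spec_for_age(AGE_STRATUM_BOUNDARY - 1)
        if (~under).any():
            yield ~under, self._spec_for_age(AGE_STRATUM_BOUNDARY)

    def predict(self, X: pd.DataFrame, entry_age=None, horizon=None) -> np.ndarray:
        """Absolute risk for each row of ``X``.

        Entry ages are taken from ``entry_age`` (scalar or array) or from an
        ``entry_age`` column of ``X``.
        """
        self._check_fitted()
        if entry_age is None:
            if "entry_age" not in X.columns:
                raise ValueError("provide entry_age or an 'entry_age' column")
            entry = X["entry_age"].to_numpy(dtype=float)
        else:
            entry = np.broadcast_to(np.asarray(entry_age, dtype=float), (len(X),))
        tau = int(self.horizon if horizon is None else horizon)
        risks = np.empty(len(X), dtype=float)
        under = entry < AGE_STRATUM_BOUNDARY
        for mask in (under, ~under):
            if not mask.any():
                continue
            spec = self._spec_for_age(float(entry[mask][0]))
            rr = relative_risk_frame(X.loc[mask], spec)
            risks[mask] = project_risks(rr, entry[mask], self.baseline_hazard_,
                                        self.mortality, horizon=tau)
        return risks

    def predict_profile(self, profile: Mapping, entry_age: float,
                        horizon=None) -> RiskProjection:
        """Risk projection for a single profile; missing covariates are
        marginalized over the fitted reference population."""
        self._check_fitted()
        spec = self._spec_for_age(entry_age)
        rr = impute_missing_profile(profile, spec, self.reference_,
                                    self.reference_weights_)
        tau = int(self.horizon if horizon is None else horizon)
        risk = project_risks(rr, entry_age, self.baseline_hazard_,
                             self.mortality, horizon=tau)
        return RiskProjection(float(risk[0]), float(entry_age), tau)

    def _check_fitted(self) -> None:
        if not hasattr(self, "baseline_hazard_"):
            raise RuntimeError("AbsoluteRiskModel is not fitted; call fit() first")
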