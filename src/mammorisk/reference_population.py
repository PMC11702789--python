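"""Reference-population augmentation.

A representative reference dataset (one row per woman, optional ``weight``
column) drives both baseline-hazard calibration and population risk
projections.  Two covariates are usually absent from questionnaire-based
reference sources and are added by simulation:

* the 4-level mammographic density category, drawn from a proportional-odds
  (cumulative-logit) regression on questionnaire covariates, and
* the standardized polygenic risk score (PRS), drawn independently of the
  questionnaire factors conditional on family history, via an exponentially
  tilted normal for the family-history-positive stratum and the complementary
  mixture component for the negative stratum so that the population marginal
  stays N(0, sigma^2).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.base import BaseEstimator
from statsmodels.miscmodels.ordinal_model import OrderedModel

logger = logging.getLogger("mammorisk")

__all__ = [
    "DEFAULT_DENSITY_PREDICTORS",
    "DensityImputationModel",
    "PrsFamilyModel",
    "fit_density_model",
    "impute_density",
    "simulate_prs_given_family_history",
    "DensityImputer",
    "PrsSimulator",
]

#: Default numeric predictors of the density category: established density
#: correlates (age and BMI strongly negative; nulliparity positive;
#: postmenopausal negative; current MHT use positive).
DEFAULT_DENSITY_PREDICTORS = ("age", "bmi", "nulliparous", "postmenopausal",
                              "mht_current")


@dataclass(frozen=True)
class DensityImputationModel:
    """Proportional-odds model for the 4-level density category.

    ``P(density <= k | x) = logistic(cut_points[k] - slopes . x)`` for
    k = 1, 2, 3.  ``fill_values`` supply predictor values for rows with
    missing predictors (the predictor means of the training data, for fitted
    models).
    """

    predictors: tuple[str, ...]
    slopes: np.ndarray
    cut_points: np.ndarray
    fill_values: dict = field(default_factory=dict)
    loglike: float | None = None
    slope_se: np.ndarray | None = None
    cut_point_se: np.ndarray | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "predictors", tuple(self.predictors))
        slopes = np.asarray(self.slopes, dtype=float)
        cuts = np.asarray(self.cut_points, dtype=float)
        object.__setattr__(self, "slopes", slopes)
        object.__setattr__(self, "cut_points", cuts)
        if slopes.shape != (len(self.predictors),):
            raise ValueError("one slope per predictor required")
        if cuts.shape != (3,) or not np.all(np.diff(cuts) > 0):
            raise ValueError("cut_points must be 3 strictly increasing values")
        if not (np.all(np.isfinite(slopes)) and np.all(np.isfinite(cuts))):
            raise ValueError("non-finite density-model parameters")

    def linear_predictor(self, X: pd.DataFrame) -> np.ndarray:
        eta = np.zeros(len(X))
        for name, gamma in zip(self.predictors, self.slopes):
            if name in X.columns:
                col = X[name].to_numpy(dtype=float)
            else:
                col = np.full(len(X), np.nan)
            missing = ~np.isfinite(col)
            if missing.any():
                fill = self.fill_values.get(name)
                if fill is None:
                    raise ValueError(
                        f"predictor {name!r} missing and no fill value available")
                logger.warning("density predictor %r missing in %d row(s); "
                               "using fill value %.3g", name, int(missing.sum()), fill)
                col = np.where(missing, fill, col)
            eta += gamma * col
        return eta

    def category_probs(self, X: pd.DataFrame) -> np.ndarray:
        """(n, 4) matrix of conditional category probabilities per row."""
        eta = self.linear_predictor(X)
        cum = expit(self.cut_points[None, :] - eta[:, None])
        probs = np.diff(np.concatenate(
            [np.zeros((len(X), 1)), cum, np.ones((len(X), 1))], axis=1), axis=1)
        return probs

    def to_dict(self) -> dict:
        return {
            "predictors": list(self.predictors),
            "slopes": self.slopes.tolist(),
            "cut_points": self.cut_points.tolist(),
            "fill_values": dict(self.fill_values),
        }

    @classmethod
    def from_dict(cls, d) -> "DensityImputationModel":
        return cls(predictors=tuple(d["predictors"]),
                   slopes=np.asarray(d["slopes"], dtype=float),
                   cut_points=np.asarray(d["cut_points"], dtype=float),
                   fill_values=dict(d.get("fill_values", {})))


@dataclass(frozen=True)
class PrsFamilyModel:
    """Coupling of the standardized PRS with the family-history indicator.

    ``prs_sd`` is the population SD of the PRS; ``fh_log_rr_per_sd`` is the
    log risk ratio of (relative's) family history per SD of the index woman's
    PRS, which equals the conditional mean shift of the PRS in the
    family-history-positive stratum in SD units; ``fh_marginal_prev`` is the
    population prevalence of family history.
    """

    prs_sd: float = 1.0
    fh_log_rr_per_sd: float = 0.25
    fh_marginal_prev: float = 0.12

    def __post_init__(self) -> None:
        if not (self.prs_sd > 0):
            raise ValueError("prs_sd must be positive")
        if not (0.0 < self.fh_marginal_prev < 1.0):
            raise ValueError("fh_marginal_prev must lie in (0, 1)")

    def to_dict(self) -> dict:
        return {"prs_sd": self.prs_sd, "fh_log_rr_per_sd": self.fh_log_rr_per_sd,
                "fh_marginal_prev": self.fh_marginal_prev}

    @classmethod
    def from_dict(cls, d) -> "PrsFamilyModel":
        return cls(**d)


# ---------------------------------------------------------------------------
# density model fit / imputation
# ---------------------------------------------------------------------------

def fit_density_model(
    training: pd.DataFrame,
    predictors=DEFAULT_DENSITY_PREDICTORS,
    density_col: str = "density_category",
) -> DensityImputationModel:
    """Maximum-likelihood cumulative-logit fit of the density category.

    Requires at least 50 rows with all four categories represented.  With an
    empty predictor list the fit is the saturated intercept-only model, whose
    cut points are the logits of the empirical cumulative frequencies.
    """
    predictors = tuple(predictors)
    if len(training) < 50:
        raise ValueError(f"need >= 50 training rows, got {len(training)}")
    y = training[density_col].to_numpy(dtype=float)
    if np.any(~np.isfinite(y)) or not np.all(np.isin(y, (1, 2, 3, 4))):
        raise ValueError("density_category must be 1, 2, 3 or 4 in every row")
    counts = np.array([(y == k).sum() for k in (1, 2, 3, 4)])
    if np.any(counts == 0):
        missing = [k + 1 for k in range(4) if counts[k] == 0]
        raise ValueError(f"density categories {missing} absent from training data")

    if not predictors:
        freqs = counts / counts.sum()
        cum = np.cumsum(freqs)[:3]
        cuts = np.log(cum / (1 - cum))
        return DensityImputationModel(predictors=(), slopes=np.empty(0),
                                      cut_points=cuts, fill_values={},
                                      loglike=float(np.sum(counts * np.log(freqs))))

    X = training[list(predictors)].to_numpy(dtype=float)
    if np.any(~np.isfinite(X)):
        raise ValueError("training predictors contain missing/non-finite values")
    model = OrderedModel(y - 1, X, distr="logit")
    res = model.fit(method="lbfgs", maxiter=500, disp=False)
    if not res.mle_retvals.get("converged", True):
        raise RuntimeError(
            "ordinal density model did not converge "
            f"(possible separation); fit diagnostics: {res.mle_retvals}")
    k = len(predictors)
    params = res.params
    slopes = np.asarray(params[:k], dtype=float)
    cuts = np.asarray(model.transform_threshold_params(params)[1:-1], dtype=float)

    # delta method: cuts = [t1, t1 + e^{d2}, t1 + e^{d2} + e^{d3}]
    d2, d3 = params[k + 1], params[k + 2]
    jac = np.array([[1.0, 0.0, 0.0],
                    [1.0, np.exp(d2), 0.0],
                    [1.0, np.exp(d2), np.exp(d3)]])
    cov_t = np.asarray(res.cov_params())[k:, k:]
    cut_se = np.sqrt(np.diag(jac @ cov_t @ jac.T))

    fill = {name: float(training[name].mean()) for name in predictors}
    return DensityImputationModel(
        predictors=predictors, slopes=slopes, cut_points=cuts, fill_values=fill,
        loglike=float(res.llf), slope_se=np.asarray(res.bse[:k], dtype=float),
        cut_point_se=cut_se)


def impute_density(
    reference: pd.DataFrame,
    model: DensityImputationModel,
    seed,
    density_col: str = "density_category",
) -> pd.DataFrame:
    """Draw the density category for rows lacking one; existing values are
    never overwritten.  Returns a copy with an integer ``density_col``."""
    rng = np.random.default_rng(seed)
    out = reference.copy()
    if density_col in out.columns:
        todo = ~np.isfinite(out[density_col].to_numpy(dtype=float))
    else:
        out[density_col] = np.nan
        todo = np.ones(len(out), dtype=bool)
    if todo.any():
        probs = model.category_probs(out.loc[todo])
        u = rng.uniform(size=int(todo.sum()))
        cum = np.cumsum(probs, axis=1)
        cats = 1 + (u[:, None] > cum[:, :3]).sum(axis=1)
        vals = out[density_col].to_numpy(dtype=float)
        vals[todo] = cats
        out[density_col] = vals.astype(int)
    else:
        out[density_col] = out[density_col].astype(int)
    return out


# ---------------------------------------------------------------------------
# PRS | family history
# ---------------------------------------------------------------------------

def _fh_indicator(col: pd.Series) -> np.ndarray:
    """Family history as float 0/1 with NaN for missing."""
    mapping = {"yes": 1.0, "no": 0.0, "1": 1.0, "0": 0.0,
               "true": 1.0, "false": 0.0, "1.0": 1.0, "0.0": 0.0}
    vals = col.map(lambda v: np.nan if pd.isna(v)
                   else mapping.get(str(v).strip().lower(), np.nan))
    return vals.to_numpy(dtype=float)


def _sample_complement(rng, n: int, sigma: float, theta: float, prev: float):
    """Rejection sampler for the family-history-negative PRS component.

    Target density f0 = (phi_sigma(x) - prev * f1(x)) / (1 - prev) with f1 the
    tilted normal N(sigma^2 theta, sigma^2); proposing from phi_sigma, the
    acceptance probability is 1 - prev * exp(theta x - theta^2 sigma^2 / 2)
    (clamped at 0 in the extreme upper tail, where the exact complement is not
    a density; the clamped mass is negligible for realistic parameters).
    """
    out = np.empty(n)
    todo = np.arange(n)
    while todo.size:
        x = rng.normal(0.0, sigma, size=todo.size)
        acc = 1.0 - prev * np.exp(theta * x - 0.5 * theta ** 2 * sigma ** 2)
        keep = rng.uniform(size=todo.size) < np.clip(acc, 0.0, 1.0)
        out[todo[keep]] = x[keep]
        todo = todo[~keep]
    return out


def simulate_prs_given_family_history(
    reference: pd.DataFrame,
    model: PrsFamilyModel,
    seed,
    fh_col: str = "family_history",
    prs_col: str = "prs",
) -> pd.DataFrame:
    """Draw the standardized PRS conditional on family history.

    In the family-history-positive stratum the PRS follows the exponentially
    tilted normal ``p(x | FH=1) propto phi(x / sigma) exp(theta x)`` with
    ``theta = fh_log_rr_per_sd / sigma`` — a normal with mean
    ``sigma * fh_log_rr_per_sd`` and unchanged variance.  The negative stratum
    draws from the complementary mixture component, so the population marginal
    is N(0, sigma^2).  Rows with missing family history draw from the marginal
    (logged).  Existing PRS values are never overwritten.
    """
    if fh_col not in reference.columns:
        raise KeyError(f"reference lacks family-history column {fh_col!r}")
    rng = np.random.default_rng(seed)
    out = reference.copy()
    sigma = model.prs_sd
    theta = model.fh_log_rr_per_sd / sigma
    prev = model.fh_marginal_prev

    if prs_col in out.columns:
        todo = ~np.isfinite(out[prs_col].to_numpy(dtype=float))
        prs = out[prs_col].to_numpy(dtype=float)
    else:
        todo = np.ones(len(out), dtype=bool)
        prs = np.full(len(out), np.nan)

    fh = _fh_indicator(out[fh_col])
    n_missing_fh = int(np.sum(np.isnan(fh) & todo))
    if n_missing_fh:
        logger.warning("family history missing in %d row(s); drawing PRS from "
                       "the marginal N(0, sigma^2)", n_missing_fh)

    pos = todo & (fh == 1.0)
    neg = todo & (fh == 0.0)
    marg = todo & np.isnan(fh)
    prs[pos] = rng.normal(sigma * model.fh_log_rr_per_sd, sigma, size=int(pos.sum()))
    prs[neg] = _sample_complement(rng, int(neg.sum()), sigma, theta, prev)
    prs[marg] = rng.normal(0.0, sigma, size=int(marg.sum()))
    out[prs_col] = prs
    return out


# ---------------------------------------------------------------------------
# estimator wrappers
# ---------------------------------------------------------------------------

class DensityImputer(BaseEstimator):
    """Scikit-learn wrapper around the proportional-odds density model.

    ``fit(X, y)`` takes the predictor table and the observed 1-4 category;
    ``predict_proba`` returns the (n, 4) conditional distribution; ``sample``
    draws categories for rows of a reference table.
    """

    def __init__(self, predictors=DEFAULT_DENSITY_PREDICTORS,
                 density_col="density_category"):
        self.predictors = predictors
        self.density_col = density_col

    def fit(self, X: pd.DataFrame, y=None):
        training = X
        if y is not None:
            training = X.copy()
            training[self.density_col] = np.asarray(y)
        self.model_ = fit_density_model(training, predictors=self.predictors,
                                        density_col=self.density_col)
        return self

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        return self.model_.category_probs(X)

    def sample(self, X: pd.DataFrame, random_state=None) -> pd.DataFrame:
        return impute_density(X, self.model_, random_state,
                              density_col=self.density_col)


class PrsSimulator(BaseEstimator):
    """Scikit-learn style wrapper for the PRS | family-history sampler."""

    def __init__(self, prs_sd=1.0, fh_log_rr_per_sd=0.25, fh_marginal_prev=0.12,
                 fh_col="family_history", prs_col="prs"):
        self.prs_sd = prs_sd
        self.fh_log_rr_per_sd = fh_log_rr_per_sd
        self.fh_marginal_prev = fh_marginal_prev
        self.fh_col = fh_col
        self.prs_col = prs_col

    @property
    def model(self) -> PrsFamilyModel:
        return PrsFamilyModel(self.prs_sd, self.fh_log_rr_per_sd,
                              self.fh_marginal_prev)

    def sample(self, X: pd.DataFrame, random_state=None) -> pd.DataFrame:
        return simulate_prs_given_family_history(
            X, self.model, random_state, fh_col=self.fh_col, prs_col=self.prs_col)
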