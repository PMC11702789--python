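"""Calibration and discrimination statistics for predicted absolute risks.

Implements the standard prospective-validation toolkit for absolute risk
models: the expected-to-observed case ratio (calibration-in-the-large), a
decile calibration table, the calibration slope and intercept from a linear
regression of decile-specific observed proportions on mean predicted risk, a
Hosmer-Lemeshow-type goodness-of-fit chi-square, the weighted AUC (probability
that a case outranks a control on predicted risk), and fixed-effect
inverse-variance pooling of AUCs across studies.

All statistics accept per-row weights with duplication semantics: doubling a
row's weight is equivalent to duplicating the row (point estimates; interval
widths additionally use unweighted case counts where noted).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger("mammorisk")

__all__ = [
    "EOResult",
    "CalibrationLine",
    "Chi2Result",
    "AucResult",
    "ValidationReport",
    "expected_observed",
    "decile_calibration",
    "calibration_slope_intercept",
    "goodness_of_fit_chi2",
    "auc",
    "meta_auc",
    "validate_cohort",
    "MODEL_VARIANTS",
    "variant_model",
]

Z95 = 1.959963984540054


def _as_wpy(predicted, observed_case, weights, bounded=True):
    p = np.asarray(predicted, dtype=float)
    y = np.asarray(observed_case, dtype=float)
    if p.shape != y.shape or p.ndim != 1:
        raise ValueError("predicted and observed_case must be 1-d and equal length")
    if weights is None:
        w = np.ones_like(p)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != p.shape:
            raise ValueError("weights length mismatch")
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    if np.any(~np.isfinite(p)):
        raise ValueError("predicted values must be finite")
    if bounded and np.any((p < 0) | (p > 1)):
        raise ValueError("predicted risks must lie in [0, 1]")
    return p, y, w


# ---------------------------------------------------------------------------
# expected / observed
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EOResult:
    """Expected-to-observed case ratio with a log-normal 95% CI
    (Poisson SE ``1/sqrt(observed unweighted cases)``)."""

    ratio: float
    ci_lo: float
    ci_hi: float
    expected: float
    observed: float
    observed_unweighted: int

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("ratio", "ci_lo", "ci_hi", "expected", "observed",
                 "observed_unweighted")}


def expected_observed(predicted, observed_case, weights=None) -> EOResult:
    """E/O ratio: weighted sum of predicted risks over weighted observed cases."""
    p, y, w = _as_wpy(predicted, observed_case, weights)
    expected = float(np.sum(w * p))
    observed = float(np.sum(w * y))
    n_obs = int(np.sum(y > 0))
    if observed <= 0:
        logger.warning("zero observed cases; E/O undefined")
        return EOResult(float("nan"), float("nan"), float("nan"),
                        expected, observed, n_obs)
    ratio = expected / observed
    half = Z95 / np.sqrt(n_obs)
    return EOResult(ratio, float(ratio * np.exp(-half)),
                    float(ratio * np.exp(half)), expected, observed, n_obs)


# ---------------------------------------------------------------------------
# decile calibration
# ---------------------------------------------------------------------------

def _weighted_quantile(x: np.ndarray, w: np.ndarray, q: np.ndarray) -> np.ndarray:
    order = np.argsort(x, kind="mergesort")
    xs, ws = x[order], w[order]
    cw = np.cumsum(ws)
    return np.interp(q * cw[-1], cw, xs)


def decile_calibration(predicted, observed_case, weights=None,
                       n_bins: int = 10) -> pd.DataFrame:
    """Weighted-quantile risk-category calibration table.

    Bin edges are weighted empirical quantiles of the predicted risk (the
    lowest bin closed on the left).  When ties make some edges coincide the
    duplicates are merged, yielding fewer bins (logged).  Columns: weighted
    and unweighted n, mean predicted risk, observed case proportion with a
    normal-approximation 95% CI on the effective sample size, expected and
    observed cases, and the per-bin E/O with log-normal 95% CI.
    """
    p, y, w = _as_wpy(predicted, observed_case, weights)
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    n_distinct = np.unique(p).size
    if n_distinct < n_bins:
        logger.warning("only %d distinct predicted values; using %d bin(s)",
                       n_distinct, n_distinct)
        n_bins = n_distinct
    edges = _weighted_quantile(p, w, np.linspace(0, 1, n_bins + 1))
    inner = np.unique(edges[1:-1])
    if inner.size < n_bins - 1:
        logger.warning("tied quantile edges; merged to %d bin(s)", inner.size + 1)
    bin_idx = np.searchsorted(inner, p, side="left")

    rows = []
    for b in range(inner.size + 1):
        mask = bin_idx == b
        if not mask.any():
            continue
        wb, pb, yb = w[mask], p[mask], y[mask]
        n_w = float(wb.sum())
        exp_b = float(np.sum(wb * pb))
        obs_b = float(np.sum(wb * yb))
        prop = obs_b / n_w if n_w > 0 else float("nan")
        n_eff = n_w ** 2 / float(np.sum(wb ** 2)) if n_w > 0 else 0.0
        se_prop = np.sqrt(max(prop * (1 - prop), 0.0) / n_eff) if n_eff > 0 else np.nan
        n_obs_unw = int(np.sum(yb > 0))
        if obs_b > 0:
            eo = exp_b / obs_b
            half = Z95 / np.sqrt(n_obs_unw)
            eo_lo, eo_hi = eo * np.exp(-half), eo * np.exp(half)
        else:
            eo = eo_lo = eo_hi = float("nan")
        rows.append({
            "bin": len(rows) + 1,
            "n_weighted": n_w,
            "n_unweighted": int(mask.sum()),
            "mean_predicted": float(np.sum(wb * pb) / n_w),
            "observed_prop": prop,
            "observed_prop_lo": max(prop - Z95 * se_prop, 0.0),
            "observed_prop_hi": min(prop + Z95 * se_prop, 1.0),
            "expected_cases": exp_b,
            "observed_cases": obs_b,
            "observed_cases_unweighted": n_obs_unw,
            "eo": eo, "eo_lo": eo_lo, "eo_hi": eo_hi,
        })
    table = pd.DataFrame(rows)
    assert table["mean_predicted"].is_monotonic_increasing
    return table


# ---------------------------------------------------------------------------
# calibration slope / intercept
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CalibrationLine:
    """OLS fit of decile observed proportions on mean predicted risk."""

    slope: float
    slope_ci: tuple[float, float]
    intercept: float
    intercept_ci: tuple[float, float]

    def to_dict(self) -> dict:
        return {"slope": self.slope, "slope_ci": list(self.slope_ci),
                "intercept": self.intercept,
                "intercept_ci": list(self.intercept_ci)}


def calibration_slope_intercept(decile_table: pd.DataFrame) -> CalibrationLine:
    """Ordinary least squares of observed proportion on mean predicted risk
    across risk categories; 95% CIs from the regression t distribution."""
    if len(decile_table) < 3:
        raise ValueError("need >= 3 risk categories for the calibration line")
    x = sm.add_constant(decile_table["mean_predicted"].to_numpy())
    fit = sm.OLS(decile_table["observed_prop"].to_numpy(), x).fit()
    ci = fit.conf_int(alpha=0.05)
    return CalibrationLine(
        slope=float(fit.params[1]), slope_ci=(float(ci[1][0]), float(ci[1][1])),
        intercept=float(fit.params[0]),
        intercept_ci=(float(ci[0][0]), float(ci[0][1])))


# ---------------------------------------------------------------------------
# goodness of fit
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Chi2Result:
    statistic: float
    df: int
    pvalue: float

    def to_dict(self) -> dict:
        return {"statistic": self.statistic, "df": self.df, "pvalue": self.pvalue}


def goodness_of_fit_chi2(decile_table: pd.DataFrame, df: int | None = None
                         ) -> Chi2Result:
    """Hosmer-Lemeshow-type goodness-of-fit statistic on the decile table:
    ``sum_b (O_b - E_b)^2 / (E_b (1 - E_b / n_b))``.

    For externally supplied (not refitted) predictions the statistic is
    referred to a chi-square with ``df = number of bins`` (no parameters were
    estimated on the validation data); pass ``df`` to override, e.g.
    ``bins - 2`` for the development-data convention.  Bins with zero expected
    cases are merged into their lower neighbour (logged).
    """
    tab = decile_table.copy()
    if (tab["expected_cases"] <= 0).any():
        logger.warning("merging %d bin(s) with zero expected cases",
                       int((tab["expected_cases"] <= 0).sum()))
        merged = []
        for _, row in tab.iterrows():
            if merged and (row["expected_cases"] <= 0
                           or merged[-1]["expected_cases"] <= 0):
                for c in ("n_weighted", "expected_cases", "observed_cases"):
                    merged[-1][c] += row[c]
            else:
                merged.append(row[["n_weighted", "expected_cases",
                                   "observed_cases"]].to_dict())
        tab = pd.DataFrame(merged)
    if (tab["expected_cases"] < 1).any():
        logger.warning("expected cases < 1 in some bins; chi-square "
                       "approximation may be poor")
    o = tab["observed_cases"].to_numpy(dtype=float)
    e = tab["expected_cases"].to_numpy(dtype=float)
    n = tab["n_weighted"].to_numpy(dtype=float)
    var = e * (1.0 - e / n)
    stat = float(np.sum((o - e) ** 2 / var))
    dof = int(df) if df is not None else len(tab)
    return Chi2Result(stat, dof, float(stats.chi2.sf(stat, dof)))


# ---------------------------------------------------------------------------
# AUC
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AucResult:
    auc: float
    ci_lo: float
    ci_hi: float
    se: float

    def to_dict(self) -> dict:
        return {"auc": self.auc, "ci_lo": self.ci_lo, "ci_hi": self.ci_hi,
                "se": self.se}


def auc(predicted, case_status, weights=None) -> AucResult:
    """Weighted Wilcoxon AUC: probability that a random case's predicted risk
    exceeds a random control's, ties counted 1/2.

    The 95% CI uses the Hanley-McNeil SE evaluated at effective (Kish) case
    and control counts, truncated to [0, 1].
    """
    p, y, w = _as_wpy(predicted, case_status, weights, bounded=False)
    case = y > 0
    w_case, w_ctrl = np.where(case, w, 0.0), np.where(case, 0.0, w)
    W1, W0 = float(w_case.sum()), float(w_ctrl.sum())
    if W1 <= 0 or W0 <= 0:
        logger.warning("AUC undefined without both cases and controls")
        return AucResult(*(float("nan"),) * 4)

    order = np.argsort(p, kind="mergesort")
    ps, wc, wn = p[order], w_case[order], w_ctrl[order]
    # group tied predicted values
    boundaries = np.flatnonzero(np.diff(ps)) + 1
    wc_g = np.add.reduceat(wc, np.r_[0, boundaries])
    wn_g = np.add.reduceat(wn, np.r_[0, boundaries])
    ctrl_below = np.concatenate([[0.0], np.cumsum(wn_g)[:-1]])
    a = float(np.sum(wc_g * (ctrl_below + 0.5 * wn_g)) / (W1 * W0))

    n1 = W1 ** 2 / float(np.sum(w_case ** 2)) if np.any(w_case > 0) else 0.0
    n0 = W0 ** 2 / float(np.sum(w_ctrl ** 2)) if np.any(w_ctrl > 0) else 0.0
    q1 = a / (2.0 - a)
    q2 = 2.0 * a ** 2 / (1.0 + a)
    var = (a * (1 - a) + (n1 - 1) * (q1 - a ** 2) + (n0 - 1) * (q2 - a ** 2))
    se = float(np.sqrt(max(var, 0.0) / (n1 * n0)))
    return AucResult(a, max(a - Z95 * se, 0.0), min(a + Z95 * se, 1.0), se)


def meta_auc(per_study) -> AucResult:
    """Fixed-effect inverse-variance pooling of per-study (AUC, SE) pairs."""
    studies = list(per_study)
    if not studies:
        raise ValueError("need at least one study")
    a = np.array([s[0] for s in studies], dtype=float)
    se = np.array([s[1] for s in studies], dtype=float)
    if np.any(se <= 0):
        raise ValueError("study SEs must be positive")
    wgt = 1.0 / se ** 2
    pooled = float(np.sum(wgt * a) / np.sum(wgt))
    pooled_se = float(np.sqrt(1.0 / np.sum(wgt)))
    return AucResult(pooled, pooled - Z95 * pooled_se, pooled + Z95 * pooled_se,
                     pooled_se)


# ---------------------------------------------------------------------------
# cohort-level report
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ValidationReport:
    """Bundle of validation statistics for one cohort and one model variant."""

    eo: EOResult
    calibration: CalibrationLine
    chi2: Chi2Result
    auc: AucResult
    decile_table: pd.DataFrame
    n_total: float
    n_cases: float
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "eo": self.eo.to_dict(),
            "calibration": self.calibration.to_dict(),
            "chi2": self.chi2.to_dict(),
            "auc": self.auc.to_dict(),
            "decile_table": self.decile_table.to_dict(orient="records"),
            "n_total": self.n_total,
            "n_cases": self.n_cases,
            "metadata": dict(self.metadata),
        }


#: Covariate groups for the model variants contrasted in validation:
#: questionnaire risk factors (QRF), PRS and mammographic breast density.
_QRF = ("age_menarche_cat", "parity_cat", "age_first_birth_cat",
        "age_menopause_cat", "height_cm", "bmi", "alcohol_g_day",
        "family_history", "benign_breast_disease", "oc_use", "mht_use",
        "mht_type")
MODEL_VARIANTS = {
    "qrf": _QRF,
    "qrf_density": _QRF + ("density_category",),
    "qrf_prs": _QRF + ("prs",),
    "prs": ("prs",),
    "prs_density": ("prs", "density_category"),
    "qrf_prs_density": _QRF + ("prs", "density_category"),
}


def variant_model(model, variant: str):
    """Refit an :class:`~mammorisk.model_core.AbsoluteRiskModel` keeping only
    the covariates of a named variant (baseline hazard recalibrated)."""
    from .model_core import AbsoluteRiskModel

    if variant not in MODEL_VARIANTS:
        raise KeyError(f"unknown variant {variant!r}; "
                       f"expected one of {sorted(MODEL_VARIANTS)}")
    keep = MODEL_VARIANTS[variant]

    def _sub(spec):
        if spec is None:
            return None
        names = [n for n in keep if n in spec.schema]
        return spec.subset(names)

    sub = AbsoluteRiskModel(
        spec_under50=_sub(model.spec_under50), spec_over50=_sub(model.spec_over50),
        incidence=model.incidence, mortality=model.mortality,
        attrition_adjusted=model.attrition_adjusted, horizon=model.horizon)
    return sub.fit(model.reference_, sample_weight=model.reference_weights_)


def validate_cohort(cohort: pd.DataFrame, model, n_bins: int = 10,
                    horizon: int | None = None, metadata: dict | None = None
                    ) -> ValidationReport:
    """Validate a fitted absolute-risk model on a simulated/observed cohort.

    First-year-excluded rows are dropped from both expected and observed
    counts; predictions are made from one year after entry (the start of the
    validation follow-up window) over the model horizon.
    """
    eligible = cohort.loc[~cohort["first_year_excluded"].astype(bool)]
    entry = eligible["entry_age"].to_numpy(dtype=float) + 1.0
    predicted = model.predict(eligible, entry_age=entry, horizon=horizon)
    observed = eligible["observed_case"].to_numpy(dtype=float)
    w = (eligible["weight"].to_numpy(dtype=float)
         if "weight" in eligible.columns else None)

    eo = expected_observed(predicted, observed, w)
    table = decile_calibration(predicted, observed, w, n_bins=n_bins)
    line = calibration_slope_intercept(table)
    chi2 = goodness_of_fit_chi2(table)
    disc = auc(predicted, observed, w)
    w_arr = np.ones_like(observed) if w is None else w
    return ValidationReport(
        eo=eo, calibration=line, chi2=chi2, auc=disc, decile_table=table,
        n_total=float(w_arr.sum()), n_cases=float(np.sum(w_arr * observed)),
        metadata=metadata or {})
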