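"""Population risk stratification and threshold reclassification.

Given per-woman 5-year absolute risks in a representative population, these
routines quantify how many women (and how many expected future cases) fall at
or above clinical high-risk thresholds — 3% corresponding to the USPSTF
risk-reducing-medication recommendation and 6% to the approximate risk of a
BRCA carrier — and how adding a covariate to the model moves women across the
thresholds.  "Future cases" are expected cases, i.e. risk-weighted counts
``sum w * r``, scaled to census population sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StratificationScenario",
    "US_SCENARIO",
    "SWEDEN_SCENARIO",
    "StratificationReport",
    "ReclassificationReport",
    "risk_distribution",
    "reclassify",
    "scale_to_population",
]


@dataclass(frozen=True)
class StratificationScenario:
    """Census scaling target: population count of women in the age band and
    the absolute-risk thresholds to report at."""

    population_size: int
    age_band: tuple[int, int] = (50, 70)
    thresholds: tuple[float, ...] = (0.03, 0.06)
    name: str = ""

    def __post_init__(self) -> None:
        if self.population_size <= 0:
            raise ValueError("population_size must be positive")
        th = tuple(float(t) for t in self.thresholds)
        if any(not (0.0 < t < 1.0) for t in th):
            raise ValueError("thresholds must lie in (0, 1)")
        if tuple(sorted(th)) != th:
            raise ValueError("thresholds must be sorted increasing")
        object.__setattr__(self, "thresholds", th)


#: 2020 US Census Bureau estimate of women aged 50-70.
US_SCENARIO = StratificationScenario(43_718_160, (50, 70), (0.03, 0.06), "us")
#: 2016 Statistics Sweden estimate of women aged 50-70.
SWEDEN_SCENARIO = StratificationScenario(1_249_695, (50, 70), (0.03, 0.06),
                                         "sweden")


def scale_to_population(pct: float, scenario: StratificationScenario) -> int:
    """Nearest-integer count of women corresponding to ``pct`` percent of the
    scenario's census population."""
    if not (0.0 <= pct <= 100.0):
        raise ValueError("pct must lie in [0, 100]")
    return int(round(pct / 100.0 * scenario.population_size))


def _check_risks(risks, weights):
    r = np.asarray(risks, dtype=float)
    if r.ndim != 1:
        raise ValueError("risks must be a 1-d vector")
    if np.any(~np.isfinite(r)) or np.any((r < 0) | (r > 1)):
        raise ValueError("risks must lie in [0, 1]")
    w = np.ones_like(r) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != r.shape or np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be non-negative, matching length, "
                         "positive sum")
    return r, w


@dataclass(frozen=True)
class StratificationReport:
    """Per-threshold high-risk fractions and census-scaled counts."""

    scenario: StratificationScenario
    mean_risk: float
    per_threshold: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"scenario": self.scenario.name,
                "population_size": self.scenario.population_size,
                "mean_risk": self.mean_risk,
                "per_threshold": list(self.per_threshold)}


def risk_distribution(risks, scenario: StratificationScenario,
                      weights=None) -> StratificationReport:
    """Fraction of women (and of expected future cases) at or above each
    threshold, scaled to the census population.

    ``pct_women_above(t)`` is the weighted fraction with risk >= t;
    ``pct_future_cases_above(t)`` is the risk-weighted fraction
    ``sum w r 1(r >= t) / sum w r``.  Expected future cases in the population
    are ``mean risk x population_size``.
    """
    r, w = _check_risks(risks, weights)
    total_w = float(w.sum())
    total_cases = float(np.sum(w * r))
    mean_risk = total_cases / total_w
    n_cases_pop = mean_risk * scenario.population_size
    rows = []
    for t in scenario.thresholds:
        above = r >= t
        pct_women = 100.0 * float(w[above].sum()) / total_w
        if total_cases > 0:
            pct_cases = 100.0 * float(np.sum(w[above] * r[above])) / total_cases
        else:
            pct_cases = float("nan")
        rows.append({
            "threshold": t,
            "pct_women_above": pct_women,
            "n_women_above": scale_to_population(pct_women, scenario),
            "pct_future_cases_above": pct_cases,
            "n_future_cases_above": (int(round(pct_cases / 100.0 * n_cases_pop))
                                     if np.isfinite(pct_cases) else None),
        })
    return StratificationReport(scenario, mean_risk, rows)


@dataclass(frozen=True)
class ReclassificationReport:
    """Per-threshold reclassification flows between two nested models."""

    scenario: StratificationScenario
    per_threshold: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"scenario": self.scenario.name,
                "population_size": self.scenario.population_size,
                "per_threshold": list(self.per_threshold)}


def reclassify(risks_without, risks_with, scenario: StratificationScenario,
               weights=None, case_denominator: str = "with"
               ) -> ReclassificationReport:
    """Threshold cross-classification of paired risks from two models.

    ``pct_up`` / ``pct_down`` are the weighted fractions moving from below to
    at-or-above the threshold (and vice versa) when going from the reduced
    model (``risks_without``) to the fuller model (``risks_with``);
    ``pct_reclassified_total = pct_up + pct_down`` exactly.

    ``pct_additional_future_cases`` is the net change in expected cases
    captured above the threshold, with expected cases evaluated under the
    fuller model:
    ``[sum w r_with 1(r_with >= t) - sum w r_with 1(r_without >= t)] /
    sum w r_with``.  Set ``case_denominator="without"`` to evaluate the
    captured-case numerator and denominator under the reduced model's risks
    instead.
    """
    r0, w = _check_risks(risks_without, weights)
    r1, _ = _check_risks(risks_with, weights)
    if r0.shape != r1.shape:
        raise ValueError("paired risk vectors must have equal length")
    if case_denominator not in ("with", "without"):
        raise ValueError("case_denominator must be 'with' or 'without'")
    r_case = r1 if case_denominator == "with" else r0
    total_w = float(w.sum())
    total_cases = float(np.sum(w * r_case))
    rows = []
    for t in scenario.thresholds:
        up = (r0 < t) & (r1 >= t)
        down = (r0 >= t) & (r1 < t)
        pct_up = 100.0 * float(w[up].sum()) / total_w
        pct_down = 100.0 * float(w[down].sum()) / total_w
        captured_with = float(np.sum(w * r_case * (r1 >= t)))
        captured_without = float(np.sum(w * r_case * (r0 >= t)))
        if total_cases > 0:
            pct_extra = 100.0 * (captured_with - captured_without) / total_cases
        else:
            pct_extra = float("nan")
        rows.append({
            "threshold": t,
            "pct_up": pct_up,
            "pct_down": pct_down,
            "pct_reclassified_total": pct_up + pct_down,
            "n_up": scale_to_population(pct_up, scenario),
            "n_down": scale_to_population(pct_down, scenario),
            "n_reclassified_total": scale_to_population(pct_up + pct_down,
                                                        scenario),
            "pct_additional_future_cases": pct_extra,
        })
    return ReclassificationReport(scenario, rows)
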