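"""Age-indexed annual rate tables (incidence, competing mortality, baseline hazard).

Registry rates are typically published in 5-year age bins; :meth:`RateTable.from_csv`
expands bins to annual rates by constant interpolation within each bin so that
all downstream arithmetic works on an integer-year grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["RateTable", "BaselineHazard"]


def _validate_support(ages: np.ndarray, what: str) -> None:
    if ages.size == 0:
        raise ValueError(f"{what}: empty age support")
    if np.any(np.diff(ages) != 1):
        raise ValueError(f"{what}: ages must be contiguous integer years")


@dataclass(frozen=True)
class RateTable:
    """Annual event probability per integer year of age.

    Invariants: contiguous integer ages; ``0 <= rate < 1`` everywhere.
    """

    ages: np.ndarray
    rates: np.ndarray

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=int)
        rates = np.asarray(self.rates, dtype=float)
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "rates", rates)
        if ages.shape != rates.shape or ages.ndim != 1:
            raise ValueError("ages and rates must be 1-d arrays of equal length")
        _validate_support(ages, "RateTable")
        if np.any(~np.isfinite(rates)) or np.any(rates < 0) or np.any(rates >= 1):
            raise ValueError("rates must be finite and in [0, 1)")

    @property
    def age_min(self) -> int:
        return int(self.ages[0])

    @property
    def age_max(self) -> int:
        return int(self.ages[-1])

    def covers(self, age_lo: float, age_hi: float) -> bool:
        """Whether integer ages ``[age_lo, age_hi)`` are all in support."""
        return self.age_min <= int(age_lo) and int(np.ceil(age_hi)) - 1 <= self.age_max

    def at(self, ages) -> np.ndarray:
        """Rate(s) at integer age(s); raises outside support."""
        a = np.asarray(ages, dtype=int)
        if np.any(a < self.age_min) or np.any(a > self.age_max):
            raise ValueError(
                f"age outside rate-table support [{self.age_min}, {self.age_max}]")
        return self.rates[a - self.age_min]

    def scaled(self, factor: float) -> "RateTable":
        """Rate table with every annual rate multiplied by ``factor``."""
        return RateTable(self.ages, self.rates * factor)

    def restrict(self, age_lo: int, age_hi: int) -> "RateTable":
        """Restrict support to ``[age_lo, age_hi]`` inclusive."""
        mask = (self.ages >= age_lo) & (self.ages <= age_hi)
        return RateTable(self.ages[mask], self.rates[mask])

    # ---- I/O ----

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, source: str = "<dataframe>") -> "RateTable":
        """Build from columns ``age_lo, age_hi, rate`` (bins expanded to years).

        ``age_hi`` is inclusive, SEER-style (a row ``50,54,0.002`` covers ages
        50..54).  Single-year tables use ``age_lo == age_hi``.
        """
        required = {"age_lo", "age_hi", "rate"}
        if not required.issubset(df.columns):
            raise ValueError(f"{source}: rate table needs columns {sorted(required)}, "
                             f"got {list(df.columns)}")
        ages: list[int] = []
        rates: list[float] = []
        for idx, row in df.iterrows():
            line = idx + 2  # header is line 1
            try:
                lo, hi, rate = int(row.age_lo), int(row.age_hi), float(row.rate)
            except (TypeError, ValueError) as exc:
                raise ValueError(f"{source}, line {line}: non-numeric entry "
                                 f"({exc})") from None
            if not np.isfinite(rate) or not (0 <= rate < 1):
                raise ValueError(f"{source}, line {line}: rate {rate} outside [0, 1)")
            if hi < lo:
                raise ValueError(f"{source}, line {line}: age_hi < age_lo")
            ages.extend(range(lo, hi + 1))
            rates.extend([rate] * (hi - lo + 1))
        ages_arr = np.asarray(ages)
        if np.any(np.diff(ages_arr) != 1):
            raise ValueError(f"{source}: age bins must be contiguous and non-overlapping")
        return cls(ages_arr, np.asarray(rates))

    @classmethod
    def from_csv(cls, path) -> "RateTable":
        try:
            df = pd.read_csv(path)
        except pd.errors.ParserError as exc:
            raise ValueError(f"{path}: malformed CSV ({exc})") from None
        return cls.from_dataframe(df, source=str(path))

    def to_csv(self, path) -> None:
        pd.DataFrame({"age_lo": self.ages, "age_hi": self.ages,
                      "rate": self.rates}).to_csv(path, index=False)


@dataclass(frozen=True)
class BaselineHazard:
    """Annual baseline hazard for a reference-level individual, per integer age.

    Produced by calibrating a relative-risk model to a marginal incidence
    table; shares the incidence table's age support.
    """

    ages: np.ndarray
    lambda0: np.ndarray

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=int)
        lam = np.asarray(self.lambda0, dtype=float)
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "lambda0", lam)
        if ages.shape != lam.shape or ages.ndim != 1:
            raise ValueError("ages and lambda0 must be 1-d arrays of equal length")
        _validate_support(ages, "BaselineHazard")
        if np.any(~np.isfinite(lam)) or np.any(lam < 0):
            raise ValueError("lambda0 must be finite and non-negative")

    @property
    def age_min(self) -> int:
        return int(self.ages[0])

    @property
    def age_max(self) -> int:
        return int(self.ages[-1])

    def at(self, ages) -> np.ndarray:
        a = np.asarray(ages, dtype=int)
        if np.any(a < self.age_min) or np.any(a > self.age_max):
            raise ValueError(
                f"age outside baseline-hazard support [{self.age_min}, {self.age_max}]")
        return self.lambda0[a - self.age_min]
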