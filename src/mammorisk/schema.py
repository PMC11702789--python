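"""Covariate schema and relative-risk model specification.

A risk model is defined by a :class:`CovariateSchema` (which covariates exist,
their type, levels and reference values) together with a table of log relative
risks, one entry per categorical level or one per-unit coefficient per
continuous covariate.  The pair is held by :class:`ModelSpec`.  Log relative
risks are literature-derived inputs supplied through configuration, not fitted
by this package.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import yaml

__all__ = [
    "CovariateDef",
    "CovariateSchema",
    "ModelSpec",
    "AGE_STRATA",
    "AGE_STRATUM_BOUNDARY",
]

#: Recognised age strata for the stratified model; the switch is at exact age 50.
AGE_STRATA = ("under50", "over50")
AGE_STRATUM_BOUNDARY = 50


@dataclass(frozen=True)
class CovariateDef:
    """One covariate in the risk-factor vector.

    Parameters
    ----------
    name : str
        Unique identifier, used as the column name in datasets.
    kind : {"categorical", "continuous"}
    levels : sequence of str, optional
        Ordered level labels; required for categorical covariates.
    reference_level : str, optional
        The level whose relative risk is 1 (categorical only).
    reference_value : float
        Value at which a continuous covariate contributes relative risk 1.
    unit : str
        Free-text unit for documentation (e.g. ``"kg/m2"``).
    """

    name: str
    kind: str
    levels: tuple[str, ...] = ()
    reference_level: str | None = None
    reference_value: float = 0.0
    unit: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("categorical", "continuous"):
            raise ValueError(f"covariate {self.name!r}: kind must be "
                             f"'categorical' or 'continuous', got {self.kind!r}")
        if self.kind == "categorical":
            if len(self.levels) < 2:
                raise ValueError(f"categorical covariate {self.name!r} needs >=2 levels")
            if len(set(self.levels)) != len(self.levels):
                raise ValueError(f"covariate {self.name!r} has duplicate levels")
            if self.reference_level not in self.levels:
                raise ValueError(
                    f"covariate {self.name!r}: reference level "
                    f"{self.reference_level!r} not among levels {self.levels}")
        else:
            if not math.isfinite(self.reference_value):
                raise ValueError(f"covariate {self.name!r}: non-finite reference value")
        # normalise levels to tuple so instances hash / compare predictably
        object.__setattr__(self, "levels", tuple(self.levels))

    def to_dict(self) -> dict:
        d: dict = {"name": self.name, "kind": self.kind}
        if self.kind == "categorical":
            d["levels"] = list(self.levels)
            d["reference_level"] = self.reference_level
        else:
            d["reference_value"] = self.reference_value
        if self.unit:
            d["unit"] = self.unit
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "CovariateDef":
        return cls(
            name=d["name"],
            kind=d["kind"],
            levels=tuple(d.get("levels", ())),
            reference_level=d.get("reference_level"),
            reference_value=float(d.get("reference_value", 0.0)),
            unit=d.get("unit", ""),
        )


@dataclass(frozen=True)
class CovariateSchema:
    """Ordered collection of covariate definitions with unique names."""

    entries: tuple[CovariateDef, ...]

    def __post_init__(self) -> None:
        entries = tuple(self.entries)
        object.__setattr__(self, "entries", entries)
        names = [e.name for e in entries]
        if len(set(names)) != len(names):
            raise ValueError("covariate names must be unique")

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, name: str) -> CovariateDef:
        for e in self.entries:
            if e.name == name:
                return e
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return any(e.name == name for e in self.entries)

    def subset(self, names: Sequence[str]) -> "CovariateSchema":
        """Schema restricted to ``names``, preserving order of ``self``."""
        keep = set(names)
        missing = keep - set(self.names)
        if missing:
            raise KeyError(f"unknown covariates: {sorted(missing)}")
        return CovariateSchema(tuple(e for e in self.entries if e.name in keep))

    def to_dict(self) -> dict:
        return {"entries": [e.to_dict() for e in self.entries]}

    @classmethod
    def from_dict(cls, d: Mapping) -> "CovariateSchema":
        return cls(tuple(CovariateDef.from_dict(e) for e in d["entries"]))


@dataclass(frozen=True)
class ModelSpec:
    """Multiplicative relative-risk model for one age stratum.

    ``log_rr`` maps each covariate name to either a ``{level: log RR}`` mapping
    (categorical; the reference level must map to exactly 0) or a single float
    (continuous; log RR per unit above the declared reference value).
    """

    age_stratum: str
    schema: CovariateSchema
    log_rr: Mapping[str, Mapping[str, float] | float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.age_stratum not in AGE_STRATA:
            raise ValueError(f"age_stratum must be one of {AGE_STRATA}, "
                             f"got {self.age_stratum!r}")
        log_rr = {k: (dict(v) if isinstance(v, Mapping) else float(v))
                  for k, v in self.log_rr.items()}
        object.__setattr__(self, "log_rr", log_rr)
        for cov in self.schema:
            if cov.name not in log_rr:
                raise ValueError(f"missing log_rr entry for covariate {cov.name!r}")
            entry = log_rr[cov.name]
            if cov.kind == "categorical":
                if not isinstance(entry, dict):
                    raise ValueError(f"covariate {cov.name!r}: expected per-level "
                                     "log RR mapping")
                extra = set(entry) - set(cov.levels)
                if extra:
                    raise ValueError(f"covariate {cov.name!r}: log RR for unknown "
                                     f"levels {sorted(extra)}")
                for lvl in cov.levels:
                    if lvl not in entry:
                        raise ValueError(f"covariate {cov.name!r}: no log RR for "
                                         f"level {lvl!r}")
                    if not math.isfinite(entry[lvl]):
                        raise ValueError(f"covariate {cov.name!r}: non-finite log RR")
                if entry[cov.reference_level] != 0.0:
                    raise ValueError(
                        f"covariate {cov.name!r}: log RR at reference level "
                        f"{cov.reference_level!r} must be 0, got "
                        f"{entry[cov.reference_level]}")
            else:
                if isinstance(entry, dict) or not math.isfinite(float(entry)):
                    raise ValueError(f"covariate {cov.name!r}: expected a finite "
                                     "per-unit log RR")
        extra = set(log_rr) - set(self.schema.names)
        if extra:
            raise ValueError(f"log_rr entries for unknown covariates: {sorted(extra)}")

    def subset(self, names: Sequence[str]) -> "ModelSpec":
        """Model restricted to a subset of covariates (e.g. a QRF-only variant)."""
        sub = self.schema.subset(names)
        return ModelSpec(self.age_stratum, sub,
                         {n: self.log_rr[n] for n in sub.names})

    # ---- serialization (lossless JSON/YAML round trip) ----

    def to_dict(self) -> dict:
        return {
            "age_stratum": self.age_stratum,
            "schema": self.schema.to_dict(),
            "log_rr": {k: (dict(v) if isinstance(v, dict) else v)
                       for k, v in self.log_rr.items()},
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ModelSpec":
        return cls(
            age_stratum=d["age_stratum"],
            schema=CovariateSchema.from_dict(d["schema"]),
            log_rr=d["log_rr"],
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_file(cls, path) -> "ModelSpec":
        text = open(path).read()
        data = yaml.safe_load(text)  # YAML is a superset of JSON
        return cls.from_dict(data)

    def to_file(self, path) -> None:
        path = str(path)
        with open(path, "w") as fh:
            if path.endswith((".yaml", ".yml")):
                fh.write(self.to_yaml())
            else:
                fh.write(self.to_json())


def spec_for_age(specs: Mapping[str, ModelSpec], age: float) -> ModelSpec:
    """Pick the age-stratum model for ``age`` (switch at exact age 50)."""
    key = "under50" if age < AGE_STRATUM_BOUNDARY else "over50"
    if key not in specs:
        raise KeyError(f"no model spec for stratum {key!r}")
    return specs[key]
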