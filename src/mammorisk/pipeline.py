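"""End-to-end orchestration: simulate -> predict -> validate -> stratify ->
reclassify, with a reproducibility manifest.

The pipeline is driven by a single configuration mapping (YAML/JSON file or
dict) with sections ``scenario``, ``validation``, ``stratification`` and
``reclassification``.  Every stochastic stage derives its stream from the
top-level seed, so a rerun with the same config and seed reproduces every
output byte for byte.  Each report embeds the manifest hash — a digest of the
configuration, seed and package version — so outputs can be traced to the run
that produced them.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .model_core import AbsoluteRiskModel
from .stratification import (SWEDEN_SCENARIO, US_SCENARIO,
                             StratificationScenario, reclassify,
                             risk_distribution)
from .synthetic_cohort import default_scenario, simulate_cohort
from .validation import validate_cohort, variant_model

logger = logging.getLogger("mammorisk")

__all__ = ["RunManifest", "run_pipeline", "DEMO_CONFIG", "load_config"]


DEMO_CONFIG: dict = {
    "scenario": {"stratum": "over50", "country": "us", "n": 20000,
                 "censoring_rate": 0.02},
    "validation": {"n_bins": 10,
                   "variants": ["qrf_prs", "qrf_prs_density"]},
    "stratification": {"scenario": "us"},
    "reclassification": {"baseline_variant": "qrf_prs",
                         "full_variant": "qrf_prs_density"},
    "seed": 20240,
}

_CENSUS = {"us": US_SCENARIO, "sweden": SWEDEN_SCENARIO}


def load_config(path) -> dict:
    """Read a pipeline configuration from a YAML or JSON file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    return cfg


@dataclass(frozen=True)
class RunManifest:
    """Provenance record written alongside pipeline outputs.

    ``hash`` digests the configuration, seed and package version (not the
    timestamp), so reruns of identical inputs share a hash and every report
    can embed it.
    """

    subcommand: str
    config: dict
    seed: int
    version: str = __version__
    timestamp: str = ""
    checksums: dict = field(default_factory=dict)

    @property
    def hash(self) -> str:
        payload = json.dumps(
            {"subcommand": self.subcommand, "config": self.config,
             "seed": self.seed, "version": self.version},
            sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def to_dict(self) -> dict:
        return {"subcommand": self.subcommand, "config": self.config,
                "seed": self.seed, "version": self.version,
                "timestamp": self.timestamp, "hash": self.hash,
                "checksums": dict(self.checksums)}


def _write_json(path: Path, payload: dict) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True,
                               default=float) + "\n")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _stratification_scenario(section: dict) -> StratificationScenario:
    if "scenario" in section:
        return _CENSUS[section["scenario"]]
    return StratificationScenario(
        population_size=int(section["population_size"]),
        age_band=tuple(section.get("age_band", (50, 70))),
        thresholds=tuple(section.get("thresholds", (0.03, 0.06))),
        name=section.get("name", "custom"))


def run_pipeline(config: dict | str | Path, outdir, seed: int | None = None
                 ) -> dict:
    """Execute the requested stages and write artifacts under ``outdir``.

    Returns a dict of in-memory stage results (reports keyed by stage name).
    Stage outputs on disk: ``reference.csv``, ``cohort.csv``,
    ``predictions.csv``, ``validation_<variant>.json`` (+ decile CSVs),
    ``stratification.json``, ``reclassification.json`` and ``manifest.json``.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0) if seed is None else seed)

    manifest = RunManifest(
        subcommand="pipeline", config=config, seed=seed,
        timestamp=datetime.now(timezone.utc).isoformat())
    mhash = manifest.hash
    results: dict = {"manifest_hash": mhash}

    # --- simulate ---
    sc = dict(config.get("scenario", {}))
    scenario = default_scenario(
        stratum=sc.get("stratum", "over50"), n=int(sc.get("n", 10000)),
        seed=seed, country=sc.get("country", "us"),
        censoring_rate=float(sc.get("censoring_rate", 0.02)))
    reference, lambda0, cohort = simulate_cohort(scenario)
    reference.to_csv(outdir / "reference.csv", index=False)
    cohort.to_csv(outdir / "cohort.csv", index=False)
    results["scenario"] = scenario
    results["cohort"] = cohort

    # --- fit the full model + requested variants ---
    model = AbsoluteRiskModel(
        spec_under50=scenario.spec_under50, spec_over50=scenario.spec_over50,
        incidence=scenario.incidence, mortality=scenario.mortality).fit(reference)
    val_cfg = dict(config.get("validation", {}))
    variants = list(val_cfg.get("variants", ["qrf_prs", "qrf_prs_density"]))
    models = {v: variant_model(model, v) for v in variants}

    # --- predict population risks (reference population, 5-year horizon) ---
    pred = pd.DataFrame({"age": reference["age"]})
    for v, m in models.items():
        pred[f"risk_{v}"] = m.predict(reference,
                                      entry_age=reference["age"].to_numpy())
    pred.to_csv(outdir / "predictions.csv", index=False)
    results["predictions"] = pred

    # --- validate ---
    results["validation"] = {}
    for v, m in models.items():
        report = validate_cohort(cohort, m, n_bins=int(val_cfg.get("n_bins", 10)),
                                 metadata={"variant": v, "manifest_hash": mhash})
        results["validation"][v] = report
        payload = report.to_dict()
        payload["manifest_hash"] = mhash
        _write_json(outdir / f"validation_{v}.json", payload)
        report.decile_table.to_csv(outdir / f"deciles_{v}.csv", index=False)

    # --- stratify / reclassify ---
    strat_cfg = dict(config.get("stratification", {}))
    census = _stratification_scenario(strat_cfg) if strat_cfg else US_SCENARIO
    rec_cfg = dict(config.get("reclassification", {}))
    v_full = rec_cfg.get("full_variant", variants[-1])
    v_base = rec_cfg.get("baseline_variant", variants[0])
    band = (reference["age"] >= census.age_band[0]) & \
           (reference["age"] <= census.age_band[1])
    w_band = reference.loc[band, "weight"].to_numpy(dtype=float)

    strat = risk_distribution(pred.loc[band, f"risk_{v_full}"].to_numpy(),
                              census, weights=w_band)
    payload = strat.to_dict()
    payload["manifest_hash"] = mhash
    _write_json(outdir / "stratification.json", payload)
    results["stratification"] = strat

    rec = reclassify(pred.loc[band, f"risk_{v_base}"].to_numpy(),
                     pred.loc[band, f"risk_{v_full}"].to_numpy(),
                     census, weights=w_band)
    payload = rec.to_dict()
    payload["manifest_hash"] = mhash
    _write_json(outdir / "reclassification.json", payload)
    results["reclassification"] = rec

    # --- manifest with output checksums ---
    checksums = {p.name: _sha256(p) for p in sorted(outdir.glob("*.csv"))
                 + sorted(outdir.glob("*.json")) if p.name != "manifest.json"}
    manifest = RunManifest(subcommand="pipeline", config=config, seed=seed,
                           version=__version__, timestamp=manifest.timestamp,
                           checksums=checksums)
    _write_json(outdir / "manifest.json", manifest.to_dict())
    return results
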