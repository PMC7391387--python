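"""End-to-end pipeline: registry -> incidence -> probabilities -> projections.

Configuration comes from an optional YAML file with CLI flags taking
precedence; every implicitly applied default is logged.  Outputs are plain
CSV plus a JSON manifest (config echo, input checksums, package version)
so a rerun on identical inputs is byte-identical.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import yaml

from . import __version__
from . import tableio
from .frax import RiskProfile, probability_table
from .incidence import ascertainment_breakdown, band_incidence, crude_incidence
from .projections import project_counts
from .registry import apply_eligibility_filters, deduplicate
from .synthetic import STUDY_WINDOW

log = logging.getLogger("osteorisk")

#: Defaults mirror the source study: 95% intervals, registry from age 40,
#: projections from age 50, truncation at 110.
DEFAULTS = dict(alpha=0.05, min_age=40, projection_min_age=50, terminal_age=110.0, relative_risk=1.0)


@dataclass
class RunConfig:
    cases: Optional[str] = None
    population: Optional[str] = None
    mortality: Optional[str] = None
    ratios: Optional[str] = None
    pyramids: Optional[str] = None
    out_dir: str = "osteorisk_out"
    alpha: float = DEFAULTS["alpha"]
    min_age: int = DEFAULTS["min_age"]
    projection_min_age: int = DEFAULTS["projection_min_age"]
    terminal_age: float = DEFAULTS["terminal_age"]
    relative_risk: float = DEFAULTS["relative_risk"]
    ages: List[float] = field(default_factory=lambda: [50.0, 60.0, 70.0, 80.0])
    horizon: float = 10.0
    window_start: str = STUDY_WINDOW[0].isoformat()
    window_end: str = STUDY_WINDOW[1].isoformat()
    seed: int = 0

    @classmethod
    def load(cls, path: Optional[str] = None, **overrides) -> "RunConfig":
        """YAML file values, overridden by explicit keyword arguments."""
        values: Dict = {}
        if path:
            with open(path) as fh:
                loaded = yaml.safe_load(fh) or {}
            unknown = set(loaded) - {f.name for f in dataclasses.fields(cls)}
            if unknown:
                raise ValueError(f"unknown config keys: {sorted(unknown)}")
            values.update(loaded)
        values.update({k: v for k, v in overrides.items() if v is not None})
        cfg = cls(**values)
        for key, default in DEFAULTS.items():
            if getattr(cfg, key) == default:
                log.info("config: %s defaulted to %r", key, default)
        return cfg


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Execute every stage the config has inputs for; returns the artifact dir.

    Stage order: registry filtering, incidence estimation, probability
    table (needs mortality + ratios), projections (needs pyramids).  Any
    stage error aborts naming the stage.  Inputs are never mutated.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not config.cases or not config.population:
        raise ValueError("run_pipeline requires at least 'cases' and 'population' inputs")

    manifest = {
        "package": "osteorisk",
        "version": __version__,
        "config": dataclasses.asdict(config),
        "inputs": {},
        "stages": [],
        "notes": [
            "first fracture is the absorbing event; no post-fracture excess mortality is modelled",
        ],
    }
    for key in ("cases", "population", "mortality", "ratios", "pyramids"):
        p = getattr(config, key)
        if p:
            manifest["inputs"][key] = {"path": str(p), "sha256": _sha256(Path(p))}

    # -- registry stage -------------------------------------------------------
    try:
        raw = tableio.read_cases(config.cases)
        window = (
            dt.date.fromisoformat(config.window_start),
            dt.date.fromisoformat(config.window_end),
        )
        filtered, rep1 = apply_eligibility_filters(raw, window, config.min_age)
        eligible, rep2 = deduplicate(filtered)
        tableio.write_filter_report(rep1, out / "filters.csv", out / "removals.csv")
        tableio.write_filter_report(rep2, out / "dedup.csv", out / "dedup_removals.csv")
    except Exception as exc:  # noqa: BLE001 - stage attribution
        raise StageError("registry", exc) from exc
    manifest["stages"].append({"stage": "registry", "outputs": ["filters.csv", "removals.csv"]})

    # -- incidence stage ------------------------------------------------------
    try:
        pop = tableio.read_population(config.population)
        estimates = band_incidence(eligible, pop, config.alpha)
        crude = crude_incidence(eligible, pop, config.min_age)
        breakdown = ascertainment_breakdown(eligible)
        tableio.write_incidence(estimates, out / "incidence.csv")
        summary = {
            "crude_rate_female_per_100k": crude.rate_f,
            "crude_rate_male_per_100k": crude.rate_m,
            "female_male_ratio": crude.ratio,
            "sources": {s: sh.count for s, sh in breakdown.items()},
        }
        (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    except Exception as exc:  # noqa: BLE001
        raise StageError("incidence", exc) from exc
    manifest["stages"].append({"stage": "incidence", "outputs": ["incidence.csv", "summary.json"]})

    # -- probability stage ----------------------------------------------------
    if config.mortality and config.ratios:
        try:
            from .tables import RateTable

            # hip rates come from the estimated incidence, not a file
            hip_rates = RateTable({e.band: e.rate / 100_000.0 for e in estimates})
            mortality = tableio.read_rate_table(config.mortality)
            ratios = tableio.read_ratio_table(config.ratios)
            profile = RiskProfile(config.relative_risk, label="configured")
            results = probability_table(
                hip_rates,
                ratios,
                mortality,
                config.ages,
                config.horizon,
                profile,
                config.terminal_age,
            )
            tableio.write_probabilities(results, config.relative_risk, out / "probabilities.csv")
        except Exception as exc:  # noqa: BLE001
            raise StageError("frax", exc) from exc
        manifest["stages"].append({"stage": "frax", "outputs": ["probabilities.csv"]})
    elif config.ratios or config.mortality:
        raise StageError(
            "frax", ValueError("probability stage needs both 'mortality' and 'ratios' inputs")
        )

    # -- projection stage -----------------------------------------------------
    if config.pyramids:
        try:
            from .tables import RateTable

            hip_rates = RateTable({e.band: e.rate / 100_000.0 for e in estimates})
            pyramids = tableio.read_pyramids(config.pyramids)
            proj = project_counts(hip_rates, pyramids, config.projection_min_age)
            tableio.write_projections(proj, out / "projections.csv")
        except Exception as exc:  # noqa: BLE001
            raise StageError("projections", exc) from exc
        manifest["stages"].append({"stage": "projections", "outputs": ["projections.csv"]})

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out
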