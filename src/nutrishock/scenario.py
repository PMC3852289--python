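"""Scenario files: one YAML document wiring a whole pipeline run.

Schema (version 1)::

    schema_version: 1
    seed: 0                       # optional, default 0
    rounding: half_away_from_zero # optional
    output_dir: .                 # optional
    population: strata.csv        # path, relative to the scenario file
    elasticities: elasticities.csv  # optional if strata carry an elasticity column
    shock: {driver: income, pct_change: -15}
    response_curve:               # optional temporal_response block
      form: threshold_decay
      epsilon0: 0.57
      p_star: 20
      k: 0.05
    cohort:                       # optional growth-cohort block
      hazard_ratios: [1.0, 1.6, 2.6, 6.0]
      initial_proportions: [0.7, 0.15, 0.1, 0.05]
      rates: {worsen: 0.02, improve: 0.03, baseline_mortality: 0.001, tenure_steps: 1}
      steps: 100

Unknown keys, missing fields and dangling file references raise
:class:`~nutrishock.errors.ScenarioError` naming the offender.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ScenarioError, ValidationError
from .io import read_elasticity_table, read_population
from .response import ResponseCurve
from .reporting import ROUNDING_MODES
from .shock import Shock, StratifiedPopulation

SCHEMA_VERSION = 1
_TOP_KEYS = {
    "schema_version",
    "seed",
    "rounding",
    "output_dir",
    "population",
    "elasticities",
    "shock",
    "response_curve",
    "cohort",
}


@dataclass
class Scenario:
    """A validated, fully resolved scenario."""

    path: Path
    seed: int
    rounding: str
    output_dir: Path
    shock: Shock
    population: StratifiedPopulation
    response_curve: ResponseCurve | None = None
    cohort: dict | None = None

    def scenario_hash(self) -> str:
        import hashlib

        return hashlib.sha256(Path(self.path).read_bytes()).hexdigest()[:12]


def _require(doc: dict, key: str, path) -> object:
    if key not in doc:
        raise ScenarioError(f"{path}: missing required field {key!r}")
    return doc[key]


def load_scenario(path: str | Path) -> Scenario:
    path = Path(path)
    if not path.exists():
        raise ScenarioError(f"scenario file not found: {path}")
    try:
        doc = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ScenarioError(f"{path}: not valid YAML ({exc})") from exc
    if not isinstance(doc, dict):
        raise ScenarioError(f"{path}: scenario must be a YAML mapping, got {type(doc).__name__}")
    unknown = set(doc) - _TOP_KEYS
    if unknown:
        raise ScenarioError(f"{path}: unknown field(s) {sorted(unknown)}")
    version = _require(doc, "schema_version", path)
    if version != SCHEMA_VERSION:
        raise ScenarioError(f"{path}: unrecognized schema_version {version!r} (expected {SCHEMA_VERSION})")

    rounding = doc.get("rounding", "half_away_from_zero")
    if rounding not in ROUNDING_MODES:
        raise ScenarioError(f"{path}: rounding must be one of {ROUNDING_MODES}, got {rounding!r}")
    seed = doc.get("seed", 0)
    if not isinstance(seed, int):
        raise ScenarioError(f"{path}: seed must be an integer, got {seed!r}")

    shock_block = _require(doc, "shock", path)
    if not isinstance(shock_block, dict) or set(shock_block) != {"driver", "pct_change"}:
        raise ScenarioError(f"{path}: shock must be a mapping with keys driver, pct_change")
    try:
        shock = Shock(driver=shock_block["driver"], pct_change=float(shock_block["pct_change"]))
    except (ValidationError, TypeError, ValueError) as exc:
        raise ScenarioError(f"{path}: bad shock block: {exc}") from exc

    pop_path = path.parent / str(_require(doc, "population", path))
    elasticities = None
    if "elasticities" in doc:
        elasticities = read_elasticity_table(path.parent / str(doc["elasticities"]))
    try:
        population = read_population(pop_path, elasticities=elasticities, driver=shock.driver)
    except ValidationError as exc:
        raise ScenarioError(f"{path}: population {pop_path.name}: {exc}") from exc

    curve = None
    if "response_curve" in doc:
        block = doc["response_curve"]
        if not isinstance(block, dict) or "form" not in block:
            raise ScenarioError(f"{path}: response_curve must be a mapping with a 'form' key")
        try:
            curve = ResponseCurve(**block)
        except (ValidationError, TypeError) as exc:
            raise ScenarioError(f"{path}: bad response_curve block: {exc}") from exc

    cohort = None
    if "cohort" in doc:
        cohort = doc["cohort"]
        needed = {"hazard_ratios", "initial_proportions", "rates", "steps"}
        if not isinstance(cohort, dict) or not needed <= set(cohort):
            raise ScenarioError(f"{path}: cohort block must contain {sorted(needed)}")

    return Scenario(
        path=path,
        seed=seed,
        rounding=rounding,
        output_dir=path.parent / str(doc.get("output_dir", ".")),
        shock=shock,
        population=population,
        response_curve=curve,
        cohort=cohort,
    )
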