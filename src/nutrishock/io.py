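"""Readers for the delimited-text interchange formats.

Two table kinds:

* stratum table: ``stratum_id, weight, mean_intake, cv, baseline_prevalence,
  cutpoint_value, cutpoint_semantics`` — per row exactly one of ``cv`` /
  ``baseline_prevalence`` must be present (a prevalence triggers CV
  calibration); all rows must share the cut-point.
* elasticity table: ``nutrient_id, driver, stratum_id, value``.

Delimiter is sniffed (comma or tab).  All prevalence values in files are
proportions, never percentages.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .intake import CutPoint, calibrate_cv, from_mean_cv
from .shock import Elasticity, Stratum, StratifiedPopulation

_STRATUM_REQUIRED = {"stratum_id", "weight", "mean_intake", "cutpoint_value", "cutpoint_semantics"}
_ELASTICITY_REQUIRED = {"nutrient_id", "driver", "stratum_id", "value"}


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"file not found: {path}")
    df = pd.read_csv(path, sep=None, engine="python")
    if df.empty:
        raise ValidationError(f"table is empty: {path}")
    return df


def read_elasticity_table(path: str | Path) -> list[Elasticity]:
    df = _read_table(path)
    missing = _ELASTICITY_REQUIRED - set(df.columns)
    if missing:
        raise ValidationError(f"elasticity file {path} missing columns: {sorted(missing)}")
    dupes = df.duplicated(subset=["nutrient_id", "stratum_id"])
    if dupes.any():
        raise ValidationError(
            f"elasticity file {path} has duplicate (nutrient, stratum) rows: "
            f"{df.loc[dupes, ['nutrient_id', 'stratum_id']].to_dict('records')}"
        )
    return [
        Elasticity(
            value=float(r.value),
            driver=str(r.driver),
            nutrient_id=str(r.nutrient_id),
            stratum_id=str(r.stratum_id),
        )
        for r in df.itertuples()
    ]


def population_from_frame(
    df: pd.DataFrame,
    cut: CutPoint | None = None,
    elasticities: Sequence[Elasticity] | None = None,
    driver: str = "income",
    family: str = "lognormal",
    nutrient_id: str | None = None,
) -> StratifiedPopulation:
    """Build a StratifiedPopulation from a stratum table.

    If the frame carries an ``elasticity`` column it is used directly;
    otherwise ``elasticities`` must supply one entry per ``stratum_id``.
    A missing ``cut`` is built from the table's cutpoint columns.
    """
    df = df.copy()
    has_cv = "cv" in df.columns
    has_prev = "baseline_prevalence" in df.columns
    if not has_cv and not has_prev:
        raise ValidationError("stratum table needs a 'cv' or 'baseline_prevalence' column")

    if cut is None:
        missing = _STRATUM_REQUIRED - set(df.columns)
        if missing:
            raise ValidationError(f"stratum table missing columns: {sorted(missing)}")
        cut_vals = df["cutpoint_value"].unique()
        cut_sems = df["cutpoint_semantics"].unique()
        if len(cut_vals) != 1 or len(cut_sems) != 1:
            raise ValidationError("all strata must share one cut-point (value and semantics)")
        cut = CutPoint(
            threshold=float(cut_vals[0]),
            semantics=str(cut_sems[0]),
            nutrient_id=nutrient_id or "nutrient",
        )

    by_stratum: dict[str, Elasticity] = {}
    if "elasticity" in df.columns:
        for r in df.itertuples():
            by_stratum[str(r.stratum_id)] = Elasticity(
                value=float(r.elasticity), driver=driver, nutrient_id=cut.nutrient_id,
                stratum_id=str(r.stratum_id),
            )
    elif elasticities is not None:
        for e in elasticities:
            by_stratum[e.stratum_id] = e
    else:
        raise ValidationError("no elasticities supplied (column or argument)")

    strata = []
    for r in df.itertuples(index=True):
        sid = str(r.stratum_id)
        cv = getattr(r, "cv", None) if has_cv else None
        prev = getattr(r, "baseline_prevalence", None) if has_prev else None
        cv_given = cv is not None and np.isfinite(cv)
        prev_given = prev is not None and np.isfinite(prev)
        if cv_given == prev_given:
            raise ValidationError(
                f"stratum {sid!r} (row {r.Index}): exactly one of cv / baseline_prevalence "
                "must be given"
            )
        if prev_given:
            cv = calibrate_cv(float(r.mean_intake), cut, float(prev), family=family)
        dist = from_mean_cv(
            float(r.mean_intake), float(cv), family=family, nutrient_id=cut.nutrient_id
        )
        if sid not in by_stratum:
            raise ValidationError(f"no elasticity found for stratum {sid!r}")
        strata.append(
            Stratum(stratum_id=sid, weight=float(r.weight), dist=dist, elasticity=by_stratum[sid])
        )
    return StratifiedPopulation(strata=tuple(strata), cut=cut)


def read_population(
    path: str | Path,
    elasticities: Sequence[Elasticity] | None = None,
    driver: str = "income",
    family: str = "lognormal",
    nutrient_id: str | None = None,
) -> StratifiedPopulation:
    """Read a stratum table file into a StratifiedPopulation."""
    return population_from_frame(
        _read_table(path),
        elasticities=elasticities,
        driver=driver,
        family=family,
        nutrient_id=nutrient_id,
    )


def read_hazard_anchors(path: str | Path):
    """Read an anchor file (columns z_ref, hr) into HazardAnchor objects."""
    from .growth import HazardAnchor

    df = _read_table(path)
    if not {"z_ref", "hr"} <= set(df.columns):
        raise ValidationError(f"anchor file {path} must have columns z_ref, hr")
    return [HazardAnchor(z_ref=float(r.z_ref), hr=float(r.hr)) for r in df.itertuples()]


def read_z_trajectory(path: str | Path):
    """Read a trajectory file (columns age, z) into a ZTrajectory."""
    from .growth import ZTrajectory

    df = _read_table(path)
    if not {"age", "z"} <= set(df.columns):
        raise ValidationError(f"trajectory file {path} must have columns age, z")
    return ZTrajectory(ages=tuple(df["age"]), z=tuple(df["z"]))
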