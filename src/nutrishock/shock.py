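"""Elasticity-driven income/price shock propagation.

An elasticity ε is the percent change in nutrient consumption per one percent
change in a driver (household income, or a food price).  Given a driver shock
of Δ percent, the induced intake change is ε·Δ percent — constant elasticity
over the whole shock magnitude, which is precisely the linearity assumption
the temporal response-curve module exists to relax.

Two model classes mirror the two ways practitioners run such simulations:

* :class:`PooledShockModel` — one elasticity and one intake distribution for
  the whole population ("Method 1").
* :class:`StratifiedShockModel` — stratum-specific elasticities applied to
  stratum-specific intake distributions, e.g. by expenditure quartile
  ("Method 2"), aggregated with population weights.

Both expose ``.fit(shock)`` returning a :class:`ShockResults` carrying
per-stratum rows, the aggregate, a ``summary()`` table and JSON export.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .intake import (
    CutPoint,
    NutrientIntakeDistribution,
    prevalence_below,
    shift_mean,
)
from .reporting import round_half_away

DRIVERS = ("income", "price")


@dataclass(frozen=True)
class Elasticity:
    """Dimensionless %-intake-per-%-driver response coefficient.

    ``annotation`` carries opaque significance marks from published tables
    (e.g. ``*``/``†``); it plays no computational role.
    """

    value: float
    driver: str = "income"
    nutrient_id: str = "nutrient"
    stratum_id: str = "pooled"
    annotation: str | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.value):
            raise ValidationError(f"Elasticity.value must be finite, got {self.value}")
        if self.driver not in DRIVERS:
            raise ValidationError(f"Elasticity.driver must be one of {DRIVERS}, got {self.driver!r}")


@dataclass(frozen=True)
class Shock:
    """A signed percent change in a driver (income or price)."""

    driver: str
    pct_change: float

    def __post_init__(self) -> None:
        if self.driver not in DRIVERS:
            raise ValidationError(f"Shock.driver must be one of {DRIVERS}, got {self.driver!r}")
        if not (self.pct_change > -100.0):
            raise ValidationError(f"Shock.pct_change must be > -100, got {self.pct_change}")


def intake_change(e: Elasticity, s: Shock) -> float:
    """Percent intake change induced by a shock: ε × Δdriver%."""
    if e.driver != s.driver:
        raise ValidationError(
            f"elasticity is with respect to {e.driver!r} but the shock perturbs {s.driver!r}"
        )
    return e.value * s.pct_change


@dataclass(frozen=True)
class Stratum:
    """One population stratum: weight, intake distribution, elasticity."""

    stratum_id: str
    weight: float
    dist: NutrientIntakeDistribution
    elasticity: Elasticity

    def __post_init__(self) -> None:
        if not (self.weight >= 0):
            raise ValidationError(f"Stratum.weight must be >= 0, got {self.weight}")


@dataclass(frozen=True)
class StratifiedPopulation:
    """Ordered strata sharing a nutrient, a driver and a cut-point."""

    strata: tuple[Stratum, ...]
    cut: CutPoint

    def __post_init__(self) -> None:
        if not self.strata:
            raise ValidationError("StratifiedPopulation needs at least one stratum")
        object.__setattr__(self, "strata", tuple(self.strata))
        total = sum(s.weight for s in self.strata)
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"stratum weights must sum to 1 within 1e-9, got {total!r}")
        drivers = {s.elasticity.driver for s in self.strata}
        if len(drivers) != 1:
            raise ValidationError(f"all strata must share one driver, got {sorted(drivers)}")
        nutrients = {s.dist.nutrient_id for s in self.strata}
        if len(nutrients) != 1:
            raise ValidationError(f"all strata must share one nutrient, got {sorted(nutrients)}")

    @property
    def driver(self) -> str:
        return self.strata[0].elasticity.driver


@dataclass(frozen=True)
class ShockRow:
    """One line of a shock report (per stratum, or the aggregate)."""

    stratum_id: str
    weight: float
    baseline_prevalence: float
    elasticity: float | None
    driver_change_pct: float
    intake_change_pct: float
    new_prevalence: float

    @property
    def change_pp(self) -> float:
        """Change in deficiency, in percentage points."""
        return (self.new_prevalence - self.baseline_prevalence) * 100.0


_COLUMNS = [
    "stratum_id",
    "weight",
    "baseline_prevalence",
    "elasticity",
    "driver_change_pct",
    "intake_change_pct",
    "new_prevalence",
    "change_pp",
]


@dataclass
class ShockResults:
    """Fitted shock-propagation results.

    ``rows`` holds per-stratum rows; ``aggregate`` the population row
    (identical to the single row for a pooled model).  Prevalences are stored
    as proportions at full precision; percentages appear only in rendered
    output.
    """

    method: Literal["pooled", "stratified"]
    shock: Shock
    cut: CutPoint
    rows: list[ShockRow]
    aggregate: ShockRow
    aggregation: str = "population"

    def to_frame(self, include_aggregate: bool = True) -> pd.DataFrame:
        rows = list(self.rows) + ([self.aggregate] if include_aggregate else [])
        return pd.DataFrame(
            [
                {
                    "stratum_id": r.stratum_id,
                    "weight": r.weight,
                    "baseline_prevalence": r.baseline_prevalence,
                    "elasticity": r.elasticity,
                    "driver_change_pct": r.driver_change_pct,
                    "intake_change_pct": r.intake_change_pct,
                    "new_prevalence": r.new_prevalence,
                    "change_pp": r.change_pp,
                }
                for r in rows
            ],
            columns=_COLUMNS,
        )

    def to_json_dict(self) -> dict:
        """Full-precision machine-readable twin of the rendered report."""
        def row(r: ShockRow) -> dict:
            return {
                "stratum_id": r.stratum_id,
                "weight": r.weight,
                "baseline_prevalence": r.baseline_prevalence,
                "elasticity": r.elasticity,
                "driver_change_pct": r.driver_change_pct,
                "intake_change_pct": r.intake_change_pct,
                "new_prevalence": r.new_prevalence,
                "change_pp": r.change_pp,
            }

        return {
            "method": self.method,
            "driver": self.shock.driver,
            "shock_pct": self.shock.pct_change,
            "cutpoint": {
                "threshold": self.cut.threshold,
                "semantics": self.cut.semantics,
                "nutrient_id": self.cut.nutrient_id,
            },
            "aggregation": self.aggregation,
            "strata": [row(r) for r in self.rows],
            "aggregate": row(self.aggregate),
        }

    @classmethod
    def from_json_dict(cls, payload: dict) -> "ShockResults":
        """Rebuild results from their machine-readable twin (render round-trip)."""
        def row(d: dict) -> ShockRow:
            return ShockRow(
                stratum_id=d["stratum_id"],
                weight=d["weight"],
                baseline_prevalence=d["baseline_prevalence"],
                elasticity=d["elasticity"],
                driver_change_pct=d["driver_change_pct"],
                intake_change_pct=d["intake_change_pct"],
                new_prevalence=d["new_prevalence"],
            )

        return cls(
            method=payload["method"],
            shock=Shock(driver=payload["driver"], pct_change=payload["shock_pct"]),
            cut=CutPoint(**payload["cutpoint"]),
            rows=[row(d) for d in payload["strata"]],
            aggregate=row(payload["aggregate"]),
            aggregation=payload["aggregation"],
        )

    def summary(self) -> str:
        """Human-readable report; percentages to 1 decimal, half-away rounding."""
        from .reporting import render_report

        return render_report(self)[0]


def _run_one(
    stratum_id: str,
    weight: float,
    dist: NutrientIntakeDistribution,
    cut: CutPoint,
    e: Elasticity,
    s: Shock,
) -> ShockRow:
    delta = intake_change(e, s)
    base = prevalence_below(dist, cut).value
    new = prevalence_below(shift_mean(dist, delta), cut).value
    return ShockRow(
        stratum_id=stratum_id,
        weight=weight,
        baseline_prevalence=base,
        elasticity=e.value,
        driver_change_pct=s.pct_change,
        intake_change_pct=delta,
        new_prevalence=new,
    )


class PooledShockModel:
    """Single-elasticity, single-distribution shock model (Method 1)."""

    def __init__(self, dist: NutrientIntakeDistribution, cut: CutPoint, elasticity: Elasticity):
        self.dist = dist
        self.cut = cut
        self.elasticity = elasticity

    def fit(self, shock: Shock) -> ShockResults:
        row = _run_one("pooled", 1.0, self.dist, self.cut, self.elasticity, shock)
        return ShockResults(
            method="pooled", shock=shock, cut=self.cut, rows=[row], aggregate=row
        )


class StratifiedShockModel:
    """Stratum-specific elasticities on stratum-specific distributions (Method 2).

    Aggregation of intake change and prevalence across strata uses population
    weights by default; ``aggregation="intake"`` weights the intake change by
    each stratum's share of total intake instead (prevalences stay
    population-weighted, as prevalence is a head-count).
    """

    def __init__(self, population: StratifiedPopulation):
        self.population = population

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        cut: CutPoint,
        driver: str = "income",
        family: str = "lognormal",
    ) -> "StratifiedShockModel":
        """Build from a stratum table with columns
        stratum_id, weight, mean_intake, and exactly one of cv / baseline_prevalence.
        """
        from .io import population_from_frame

        return cls(population_from_frame(df, cut=cut, driver=driver, family=family))

    def fit(self, shock: Shock, aggregation: str = "population") -> ShockResults:
        if aggregation not in ("population", "intake"):
            raise ValidationError(f"aggregation must be 'population' or 'intake', got {aggregation!r}")
        pop = self.population
        rows = [
            _run_one(st.stratum_id, st.weight, st.dist, pop.cut, st.elasticity, shock)
            for st in pop.strata
        ]
        w = np.asarray([r.weight for r in rows])
        if aggregation == "intake":
            iw = np.asarray([st.weight * st.dist.mean for st in pop.strata])
            iw = iw / iw.sum()
            agg_delta = float(np.sum(iw * [r.intake_change_pct for r in rows]))
        else:
            agg_delta = float(np.sum(w * [r.intake_change_pct for r in rows]))
        aggregate = ShockRow(
            stratum_id="aggregate",
            weight=1.0,
            baseline_prevalence=float(np.sum(w * [r.baseline_prevalence for r in rows])),
            elasticity=None,
            driver_change_pct=shock.pct_change,
            intake_change_pct=agg_delta,
            new_prevalence=float(np.sum(w * [r.new_prevalence for r in rows])),
        )
        return ShockResults(
            method="stratified",
            shock=shock,
            cut=pop.cut,
            rows=rows,
            aggregate=aggregate,
            aggregation=aggregation,
        )


def run_pooled(
    dist: NutrientIntakeDistribution, cut: CutPoint, e: Elasticity, s: Shock
) -> ShockResults:
    """Functional wrapper over :class:`PooledShockModel`."""
    return PooledShockModel(dist, cut, e).fit(s)


def run_stratified(
    pop: StratifiedPopulation, s: Shock, aggregation: str = "population"
) -> ShockResults:
    """Functional wrapper over :class:`StratifiedShockModel`."""
    return StratifiedShockModel(pop).fit(s, aggregation=aggregation)


def elasticity_table_report(table: Sequence[Elasticity], s: Shock) -> pd.DataFrame:
    """Apply one shock to a table of nutrient elasticities.

    Returns one row per nutrient: elasticity, raw intake change %, and the
    rendered 1-decimal value (round half away from zero).  Duplicate nutrients
    are rejected — the table is per-nutrient by construction.
    """
    seen: set[str] = set()
    records = []
    for e in table:
        if e.nutrient_id in seen:
            raise ValidationError(f"duplicate nutrient in elasticity table: {e.nutrient_id!r}")
        seen.add(e.nutrient_id)
        delta = intake_change(e, s)
        records.append(
            {
                "nutrient_id": e.nutrient_id,
                "elasticity": e.value,
                "annotation": e.annotation,
                "intake_change_pct": delta,
                "intake_change_rendered": round_half_away(delta, 1),
            }
        )
    return pd.DataFrame(
        records,
        columns=["nutrient_id", "elasticity", "annotation", "intake_change_pct", "intake_change_rendered"],
    )
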