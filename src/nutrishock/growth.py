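"""Catch-up growth and risk reversibility: three model structures.

Children recover from growth faltering, but the traditional burden paradigm
assigns everyone in a stunting category the same relative risk of death.  The
three structures here progressively relax that:

**A. Entrant-tracking multi-state cohort model** (:class:`CohortModel`).
A child population is distributed over stunting categories (healthy, mild,
moderate, severe by height-for-age Z-score band).  Each time-step a child may
worsen or improve by at most one category, or die.  The key feature: a new
entrant to a category carries a mortality hazard intermediate between the old
and new category hazards (arithmetic mean by default) for a tenure period,
then assumes the category hazard — a coarse representation of accumulated
risk as time-since-arrival.

**B. Z-score hazard continuum** (:func:`hazard_at_z`).
Categories are dropped; known mortality hazard ratios anchor specific
Z-score locations (conventionally band mid-points) and intermediate locations
take linearly interpolated hazards, consistent with meta-analytic evidence of
monotonically increasing risk with decreasing Z.

**C. Individual trajectory with asymmetric lags** (:func:`risk_trajectory`).
A single child's Z-score path is mapped to a hazard path.  While faltering
the hazard tracks the continuum instantly (no onset lag by default); during
catch-up the accumulated hazard decays toward the continuum value with a
configurable half-life λ (cessation lag):

    r(t + Δ) = h + (r(t) − h) · 2^(−Δ/λ).

So a child revisiting a Z-score on the way up carries a strictly higher
hazard than on the way down — risk accumulation made explicit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

CATEGORY_NAMES = ("healthy", "mild", "moderate", "severe")
#: conventional height-for-age Z-band edges separating the categories
DEFAULT_Z_EDGES = (-1.0, -2.0, -3.0)


@dataclass(frozen=True)
class GrowthCategory:
    """A stunting category: a half-open Z band and its mortality hazard ratio."""

    name: str
    z_lo: float  # inclusive lower edge (-inf for severe)
    z_hi: float  # exclusive upper edge (+inf for healthy)
    hazard_ratio: float

    def __post_init__(self) -> None:
        if self.name not in CATEGORY_NAMES:
            raise ValidationError(f"category name must be one of {CATEGORY_NAMES}, got {self.name!r}")
        if not (self.hazard_ratio >= 1.0) and self.name != "healthy":
            raise ValidationError(f"hazard ratio must be >= 1, got {self.hazard_ratio}")


def make_categories(hazard_ratios: Sequence[float] | dict[str, float]) -> tuple[GrowthCategory, ...]:
    """Build the four ordered categories from hazard ratios (healthy first).

    Hazard ratios must be non-decreasing from healthy (which must be 1) to
    severe; the Z bands partition the line at the conventional −1/−2/−3 edges.
    """
    if isinstance(hazard_ratios, dict):
        hrs = [hazard_ratios[name] for name in CATEGORY_NAMES]
    else:
        hrs = list(hazard_ratios)
    if len(hrs) != 4:
        raise ValidationError(f"need 4 hazard ratios (healthy..severe), got {len(hrs)}")
    if abs(hrs[0] - 1.0) > 1e-12:
        raise ValidationError(f"healthy hazard ratio must be 1, got {hrs[0]}")
    if any(b < a for a, b in zip(hrs, hrs[1:])):
        raise ValidationError(f"hazard ratios must be non-decreasing healthy→severe, got {hrs}")
    e1, e2, e3 = DEFAULT_Z_EDGES
    bands = [(e1, math.inf), (e2, e1), (e3, e2), (-math.inf, e3)]
    return tuple(
        GrowthCategory(name=n, z_lo=lo, z_hi=hi, hazard_ratio=hr)
        for n, (lo, hi), hr in zip(CATEGORY_NAMES, bands, hrs)
    )


@dataclass(frozen=True)
class TransitionRates:
    """Per-step cohort transition probabilities.

    ``worsen`` moves one category toward severe, ``improve`` one toward
    healthy (catch-up); ``baseline_mortality`` is the healthy category's
    per-step death probability, scaled by each compartment's hazard ratio;
    ``tenure_steps`` is how many steps a new entrant spends at the
    intermediate hazard before assuming the category hazard.
    """

    worsen: float
    improve: float
    baseline_mortality: float
    tenure_steps: int = 1

    def __post_init__(self) -> None:
        for name in ("worsen", "improve", "baseline_mortality"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"TransitionRates.{name} must be in [0,1], got {v}")
        if not (isinstance(self.tenure_steps, int) and self.tenure_steps >= 1):
            raise ValidationError(f"tenure_steps must be an integer >= 1, got {self.tenure_steps}")

    def validate_against(self, categories: Sequence[GrowthCategory], entrant_hr: str = "arithmetic") -> None:
        max_hr = max(_entrant_hr_bound(categories, entrant_hr), max(c.hazard_ratio for c in categories))
        if self.worsen + self.improve + max_hr * self.baseline_mortality > 1.0 + 1e-12:
            raise ValidationError(
                "worsen + improve + max(HR) x baseline_mortality must not exceed 1 "
                f"(got {self.worsen + self.improve + max_hr * self.baseline_mortality:.4g})"
            )


def _entrant_hr(hr_origin: float, hr_dest: float, mode: str) -> float:
    if mode == "arithmetic":
        return 0.5 * (hr_origin + hr_dest)
    if mode == "geometric":
        return math.sqrt(hr_origin * hr_dest)
    raise ValidationError(f"entrant_hr must be 'arithmetic' or 'geometric', got {mode!r}")


def _entrant_hr_bound(categories: Sequence[GrowthCategory], mode: str) -> float:
    hrs = [c.hazard_ratio for c in categories]
    return max(
        _entrant_hr(hrs[i], hrs[j], mode)
        for i in range(len(hrs))
        for j in (i - 1, i + 1)
        if 0 <= j < len(hrs)
    )


# ---------------------------------------------------------------------------
# compartment bookkeeping for model A
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Compartment:
    """(category, tenure) cell; entrants also remember origin and age-in-category."""

    cat: int  # index into the category list, 0 = healthy
    origin: int | None = None  # None = established; else origin category index
    age: int = 0  # steps already spent as entrant (established: 0)

    @property
    def established(self) -> bool:
        return self.origin is None


class CompartmentSpace:
    """Enumerates every live compartment for a category set and tenure length."""

    def __init__(self, categories: Sequence[GrowthCategory], tenure_steps: int, entrant_hr: str = "arithmetic"):
        self.categories = tuple(categories)
        self.tenure_steps = tenure_steps
        self.entrant_hr_mode = entrant_hr
        comps: list[Compartment] = []
        n = len(self.categories)
        for c in range(n):
            comps.append(Compartment(cat=c))
            for origin in (c - 1, c + 1):
                if 0 <= origin < n:
                    for age in range(tenure_steps):
                        comps.append(Compartment(cat=c, origin=origin, age=age))
        self.compartments = tuple(comps)
        self.index = {comp: i for i, comp in enumerate(comps)}

    def __len__(self) -> int:
        return len(self.compartments)

    def hazard_ratio(self, comp: Compartment) -> float:
        cat_hr = self.categories[comp.cat].hazard_ratio
        if comp.established:
            return cat_hr
        return _entrant_hr(self.categories[comp.origin].hazard_ratio, cat_hr, self.entrant_hr_mode)


@dataclass
class StateVector:
    """Cohort proportions over compartments plus cumulative deaths.

    ``values`` is aligned with ``space.compartments``; proportions plus
    ``cumulative_deaths`` sum to 1.
    """

    space: CompartmentSpace
    values: np.ndarray
    cumulative_deaths: float = 0.0
    time_step_index: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.space),):
            raise ValidationError(
                f"state vector length {self.values.shape} does not match compartment space "
                f"({len(self.space)})"
            )
        if np.any(self.values < -1e-15):
            raise ValidationError("state proportions must be non-negative")
        total = float(self.values.sum()) + self.cumulative_deaths
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"proportions + cumulative_deaths must sum to 1, got {total!r}")

    @classmethod
    def from_category_proportions(
        cls, space: CompartmentSpace, proportions: Sequence[float]
    ) -> "StateVector":
        """All mass starts established in the given categories."""
        props = np.asarray(proportions, dtype=float)
        if props.shape != (len(space.categories),):
            raise ValidationError("need one proportion per category")
        if abs(props.sum() - 1.0) > 1e-9:
            raise ValidationError(f"category proportions must sum to 1, got {props.sum()!r}")
        values = np.zeros(len(space))
        for c, p in enumerate(props):
            values[space.index[Compartment(cat=c)]] = p
        return cls(space=space, values=values)

    @property
    def total_mass(self) -> float:
        return float(self.values.sum()) + self.cumulative_deaths

    def by_category_tenure(self) -> pd.DataFrame:
        """Aggregate to the (category, tenure in {new_entrant, established}) view."""
        rows = {}
        for comp, v in zip(self.space.compartments, self.values):
            key = (self.space.categories[comp.cat].name, "established" if comp.established else "new_entrant")
            rows[key] = rows.get(key, 0.0) + v
        df = pd.DataFrame(
            [{"category": k[0], "tenure": k[1], "proportion": v} for k, v in sorted(rows.items())]
        )
        return df

    def category_proportions(self) -> np.ndarray:
        out = np.zeros(len(self.space.categories))
        for comp, v in zip(self.space.compartments, self.values):
            out[comp.cat] += v
        return out


def step_cohort(state: StateVector, rates: TransitionRates) -> StateVector:
    """Advance the cohort one time-step by explicit per-compartment flows.

    Competing risks within a step: die (baseline_mortality x compartment HR),
    worsen, improve, or stay.  Movers enter the destination's new-entrant
    compartment; staying entrants age and promote to established after
    ``tenure_steps`` steps.  Stay-mass is computed as the exact complement of
    the outflows, so total mass (live + dead) is conserved to machine
    precision.
    """
    space = state.space
    if rates.tenure_steps != space.tenure_steps:
        raise ValidationError("rates.tenure_steps does not match the state's compartment space")
    rates.validate_against(space.categories, space.entrant_hr_mode)
    n_cat = len(space.categories)
    new = np.zeros_like(state.values)
    deaths = 0.0
    for comp, m in zip(space.compartments, state.values):
        if m == 0.0:
            continue
        hr = space.hazard_ratio(comp)
        d = m * rates.baseline_mortality * hr
        w = m * rates.worsen if comp.cat < n_cat - 1 else 0.0
        i = m * rates.improve if comp.cat > 0 else 0.0
        stay = m - d - w - i
        deaths += d
        if w:
            new[space.index[Compartment(cat=comp.cat + 1, origin=comp.cat, age=0)]] += w
        if i:
            new[space.index[Compartment(cat=comp.cat - 1, origin=comp.cat, age=0)]] += i
        if comp.established:
            new[space.index[comp]] += stay
        else:
            next_age = comp.age + 1
            if next_age >= space.tenure_steps:
                new[space.index[Compartment(cat=comp.cat)]] += stay
            else:
                new[space.index[Compartment(cat=comp.cat, origin=comp.origin, age=next_age)]] += stay
    return StateVector(
        space=space,
        values=new,
        cumulative_deaths=state.cumulative_deaths + deaths,
        time_step_index=state.time_step_index + 1,
    )


def transition_matrix(space: CompartmentSpace, rates: TransitionRates) -> np.ndarray:
    """Column-stochastic one-step matrix over (compartments + absorbing death).

    Independent route to the same dynamics as :func:`step_cohort`: iterating
    the cohort n steps equals applying the n-th matrix power to the initial
    vector (used as a cross-check, and for long-run analysis).
    """
    rates.validate_against(space.categories, space.entrant_hr_mode)
    n = len(space)
    n_cat = len(space.categories)
    M = np.zeros((n + 1, n + 1))
    M[n, n] = 1.0  # death absorbs
    for j, comp in enumerate(space.compartments):
        hr = space.hazard_ratio(comp)
        d = rates.baseline_mortality * hr
        w = rates.worsen if comp.cat < n_cat - 1 else 0.0
        i = rates.improve if comp.cat > 0 else 0.0
        stay = 1.0 - d - w - i
        M[n, j] += d
        if w:
            M[space.index[Compartment(cat=comp.cat + 1, origin=comp.cat, age=0)], j] += w
        if i:
            M[space.index[Compartment(cat=comp.cat - 1, origin=comp.cat, age=0)], j] += i
        if comp.established:
            M[j, j] += stay
        else:
            next_age = comp.age + 1
            if next_age >= space.tenure_steps:
                M[space.index[Compartment(cat=comp.cat)], j] += stay
            else:
                M[space.index[Compartment(cat=comp.cat, origin=comp.origin, age=next_age)], j] += stay
    return M


@dataclass
class CohortResults:
    """History of a cohort simulation: per-step category/tenure proportions."""

    history: pd.DataFrame  # step, category, tenure, proportion
    deaths: pd.Series  # cumulative deaths per step
    final_state: StateVector

    def summary(self) -> str:
        last = self.final_state
        props = last.category_proportions()
        lines = [
            f"cohort simulation: {last.time_step_index} steps, "
            f"{len(last.space.categories)} categories, tenure {last.space.tenure_steps} step(s)",
            f"cumulative deaths: {last.cumulative_deaths:.6f}",
            "final category proportions:",
        ]
        for cat, p in zip(last.space.categories, props):
            lines.append(f"  {cat.name:>8s} (HR {cat.hazard_ratio:g}): {p:.6f}")
        return "\n".join(lines)


class CohortModel:
    """Entrant-tracking multi-state stunting cohort model (structure A)."""

    def __init__(
        self,
        categories: Sequence[GrowthCategory],
        rates: TransitionRates,
        initial_proportions: Sequence[float],
        entrant_hr: str = "arithmetic",
    ):
        self.categories = tuple(categories)
        self.rates = rates
        rates.validate_against(self.categories, entrant_hr)
        self.space = CompartmentSpace(self.categories, rates.tenure_steps, entrant_hr)
        self.initial = StateVector.from_category_proportions(self.space, initial_proportions)

    def simulate(self, n_steps: int, record_every: int = 1) -> CohortResults:
        if n_steps < 1:
            raise ValidationError(f"n_steps must be >= 1, got {n_steps}")
        state = self.initial
        records = []
        deaths = {0: state.cumulative_deaths}

        def record(s: StateVector) -> None:
            df = s.by_category_tenure()
            df.insert(0, "step", s.time_step_index)
            records.append(df)

        record(state)
        for step in range(1, n_steps + 1):
            state = step_cohort(state, self.rates)
            if step % record_every == 0 or step == n_steps:
                record(state)
                deaths[step] = state.cumulative_deaths
        history = pd.concat(records, ignore_index=True)
        return CohortResults(
            history=history,
            deaths=pd.Series(deaths, name="cumulative_deaths"),
            final_state=state,
        )


# ---------------------------------------------------------------------------
# model B: hazard continuum
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HazardAnchor:
    """A known (Z-score, hazard ratio) reference point on the continuum."""

    z_ref: float
    hr: float

    def __post_init__(self) -> None:
        if not (self.hr >= 1.0):
            raise ValidationError(f"HazardAnchor.hr must be >= 1, got {self.hr}")


def _check_anchors(anchors: Sequence[HazardAnchor]) -> tuple[np.ndarray, np.ndarray]:
    if len(anchors) < 2:
        raise ValidationError("need at least 2 hazard anchors")
    z = np.asarray([a.z_ref for a in anchors], dtype=float)
    hr = np.asarray([a.hr for a in anchors], dtype=float)
    order = np.argsort(z)
    z, hr = z[order], hr[order]
    if np.any(np.diff(z) <= 0):
        raise ValidationError("anchor z_ref values must be strictly ordered")
    if np.any(np.diff(hr) > 1e-12):
        raise ValidationError("anchor hazard ratios must be non-increasing in z")
    return z, hr


def hazard_at_z(z, anchors: Sequence[HazardAnchor]):
    """Interpolated hazard ratio at Z-score(s) ``z``.

    Piecewise linear between anchors; flat at the lowest anchor's HR below
    the anchored range, and 1.0 (the healthy reference) above it.
    """
    zs, hrs = _check_anchors(anchors)
    z_arr = np.asarray(z, dtype=float)
    out = np.interp(z_arr, zs, hrs)
    out = np.where(z_arr > zs[-1], 1.0, out)
    if np.ndim(z) == 0:
        return float(out)
    return out


# ---------------------------------------------------------------------------
# model C: individual trajectory with lags
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ZTrajectory:
    """An individual child's (age, Z-score) path; ages strictly increasing (years)."""

    ages: tuple[float, ...]
    z: tuple[float, ...]

    def __post_init__(self) -> None:
        ages = tuple(float(a) for a in self.ages)
        z = tuple(float(v) for v in self.z)
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "z", z)
        if len(ages) != len(z):
            raise ValidationError("ages and z must have equal length")
        if len(ages) < 1:
            raise ValidationError("trajectory must contain at least one point")
        if any(b <= a for a, b in zip(ages, ages[1:])):
            raise ValidationError("trajectory ages must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"age": self.ages, "z": self.z})


@dataclass(frozen=True)
class RiskTrajectory:
    """Hazard-ratio path matched to a Z trajectory."""

    ages: tuple[float, ...]
    hazard: tuple[float, ...]
    hazard_memoryless: tuple[float, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"age": self.ages, "hazard": self.hazard, "hazard_memoryless": self.hazard_memoryless}
        )


def risk_trajectory(
    traj: ZTrajectory,
    anchors: Sequence[HazardAnchor],
    lag_half_life: float,
    adult_ramp: tuple[float, float] | None = None,
    onset_half_life: float = 0.0,
) -> RiskTrajectory:
    """Map a Z-score path to a hazard path with asymmetric lags.

    While Z is non-increasing (faltering) the hazard tracks the continuum
    instantly (``onset_half_life = 0``; a positive value introduces an onset
    lag of the same exponential form).  While Z increases (catch-up) the
    hazard decays toward the continuum value with half-life ``lag_half_life``
    (years).  ``adult_ramp = (onset_age, slope_per_year)`` adds a linear
    late-life susceptibility component after ``onset_age``.

    A child with several faltering/catch-up episodes simply re-enters the
    lagged-decay regime on each catch-up phase.
    """
    if not (lag_half_life > 0):
        raise ValidationError(f"lag_half_life must be > 0, got {lag_half_life}")
    if onset_half_life < 0:
        raise ValidationError(f"onset_half_life must be >= 0, got {onset_half_life}")
    memoryless = [float(hazard_at_z(z, anchors)) for z in traj.z]
    hazard = [memoryless[0]]
    for i in range(1, len(traj.ages)):
        dt = traj.ages[i] - traj.ages[i - 1]
        h = memoryless[i]
        prev = hazard[-1]
        catch_up = traj.z[i] > traj.z[i - 1]
        if catch_up:
            half_life = lag_half_life
        else:
            half_life = onset_half_life
        if half_life > 0:
            r = h + (prev - h) * 2.0 ** (-dt / half_life)
        else:
            r = h
        hazard.append(r)
    if adult_ramp is not None:
        onset_age, slope = adult_ramp
        if slope < 0:
            raise ValidationError(f"adult ramp slope must be >= 0, got {slope}")
        hazard = [
            r + slope * max(0.0, age - onset_age) for r, age in zip(hazard, traj.ages)
        ]
    return RiskTrajectory(
        ages=traj.ages, hazard=tuple(hazard), hazard_memoryless=tuple(memoryless)
    )
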