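"""Population nutrient-intake distributions and cut-point prevalence.

The central object is :class:`NutrientIntakeDistribution`, a parametric
density of daily intake in a population, fully determined by its mean and
coefficient of variation (CV).  Undernourishment and micronutrient-deficiency
prevalence are computed as the mass below a cut-point: a minimum dietary
energy requirement (MDER) for energy, or an estimated average requirement
(EAR) for a micronutrient.  This is the classic FAO-style cut-point
construction; the probability-approach convolution against a requirement
distribution is deliberately out of scope.

The default family is lognormal: with CV = c the log-scale parameters are

    sigma^2 = ln(1 + c^2),     mu = ln(mean) - sigma^2 / 2,

so the analytic mean of the density equals the ``mean`` field exactly.
A normal family is provided for comparison; skew-normal is declared but not
supported.

When the cut-point lies below the mean, prevalence is strictly increasing in
CV, which makes the inverse problem — recovering the CV that reproduces an
observed deficiency prevalence — a bracketed monotone root search
(:func:`calibrate_cv`).  For cut-points at or above the mean the prevalence is
no longer monotone in CV and calibration refuses to guess.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .errors import CalibrationError, ValidationError

SUPPORTED_FAMILIES = ("lognormal", "normal")
#: families named by the construction; skew-normal is recognized but unsupported
DECLARED_FAMILIES = SUPPORTED_FAMILIES + ("skew-normal",)

CUTPOINT_SEMANTICS = ("MDER", "EAR")

#: CV bracket searched by :func:`calibrate_cv`.
CV_BRACKET = (1e-6, 10.0)
#: prevalence tolerance of the calibration root search
CALIBRATION_TOL = 1e-10


@dataclass(frozen=True)
class CutPoint:
    """An intake threshold defining inadequacy.

    ``semantics`` is "MDER" for the energy undernourishment cut-point or
    "EAR" for a micronutrient estimated average requirement.  Units must match
    the distribution it is compared against (kcal/day, µg RAE/day, ...).
    """

    threshold: float
    semantics: str = "EAR"
    nutrient_id: str = "nutrient"

    def __post_init__(self) -> None:
        if not (self.threshold > 0):
            raise ValidationError(f"CutPoint.threshold must be > 0, got {self.threshold}")
        if self.semantics not in CUTPOINT_SEMANTICS:
            raise ValidationError(
                f"CutPoint.semantics must be one of {CUTPOINT_SEMANTICS}, got {self.semantics!r}"
            )


@dataclass(frozen=True)
class PrevalenceEstimate:
    """A proportion below a cut-point, with how it was obtained.

    Stored as a proportion in [0, 1]; rendering as a percentage happens only
    in the reporting layer.
    """

    value: float
    method: str = "analytic"
    n_draws: int | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.value <= 1.0):
            raise ValidationError(f"PrevalenceEstimate.value must be in [0,1], got {self.value}")

    def __float__(self) -> float:
        return self.value


@dataclass(frozen=True)
class NutrientIntakeDistribution:
    """A population intake density defined by (mean, CV, family).

    Parameters
    ----------
    mean : float
        Population mean intake, in intake units per person per day.
    cv : float
        Coefficient of variation (SD / mean), dimensionless.
    family : str
        "lognormal" (default) or "normal".  "skew-normal" is declared in the
        construction but not implemented here.
    nutrient_id : str
        Free-text label carried through reports.
    """

    mean: float
    cv: float
    family: str = "lognormal"
    nutrient_id: str = "nutrient"

    def __post_init__(self) -> None:
        if not (isinstance(self.mean, (int, float)) and self.mean > 0):
            raise ValidationError(f"NutrientIntakeDistribution.mean must be > 0, got {self.mean}")
        if not (isinstance(self.cv, (int, float)) and self.cv > 0):
            raise ValidationError(f"NutrientIntakeDistribution.cv must be > 0, got {self.cv}")
        if self.family == "skew-normal":
            raise ValidationError(
                "family 'skew-normal' is declared by the FAO construction but not "
                "supported by this implementation; use 'lognormal'"
            )
        if self.family not in SUPPORTED_FAMILIES:
            raise ValidationError(
                f"NutrientIntakeDistribution.family must be one of {SUPPORTED_FAMILIES}, "
                f"got {self.family!r}"
            )

    # -- lognormal log-scale parameters ------------------------------------
    @property
    def sigma(self) -> float:
        """Log-scale SD (lognormal family only)."""
        self._require_lognormal()
        return math.sqrt(math.log1p(self.cv**2))

    @property
    def mu(self) -> float:
        """Log-scale location (lognormal family only)."""
        self._require_lognormal()
        return math.log(self.mean) - math.log1p(self.cv**2) / 2.0

    def _require_lognormal(self) -> None:
        if self.family != "lognormal":
            raise ValidationError(f"log-scale parameters undefined for family {self.family!r}")

    @property
    def frozen(self):
        """The scipy frozen distribution backing this object."""
        if self.family == "lognormal":
            return stats.lognorm(s=self.sigma, scale=math.exp(self.mu))
        return stats.norm(loc=self.mean, scale=self.cv * self.mean)

    # -- density interface --------------------------------------------------
    def pdf(self, x):
        return self.frozen.pdf(x)

    def cdf(self, x):
        return self.frozen.cdf(x)

    def ppf(self, q):
        return self.frozen.ppf(q)

    def median(self) -> float:
        return float(self.frozen.median())

    def rvs(self, n: int, seed: int) -> np.ndarray:
        rng = np.random.default_rng(seed)
        return self.frozen.rvs(size=n, random_state=rng)


def from_mean_cv(
    mean: float, cv: float, family: str = "lognormal", nutrient_id: str = "nutrient"
) -> NutrientIntakeDistribution:
    """Build an intake distribution from its population mean and CV."""
    return NutrientIntakeDistribution(mean=mean, cv=cv, family=family, nutrient_id=nutrient_id)


def prevalence_below(
    dist: NutrientIntakeDistribution,
    cut: CutPoint,
    method: str = "analytic",
    n_draws: int | None = None,
    seed: int | None = None,
) -> PrevalenceEstimate:
    """Proportion of the population with intake below the cut-point.

    ``method="analytic"`` evaluates the CDF at the threshold;
    ``method="monte-carlo"`` draws ``n_draws`` intakes with ``seed`` and
    returns the fraction below the threshold.
    """
    if method == "analytic":
        return PrevalenceEstimate(value=float(dist.cdf(cut.threshold)), method="analytic")
    if method == "monte-carlo":
        if n_draws is None or n_draws < 1:
            raise ValidationError("monte-carlo prevalence requires n_draws >= 1")
        if seed is None:
            raise ValidationError("monte-carlo prevalence requires an explicit seed")
        draws = dist.rvs(int(n_draws), seed)
        return PrevalenceEstimate(
            value=float(np.mean(draws < cut.threshold)),
            method="monte-carlo",
            n_draws=int(n_draws),
            seed=seed,
        )
    raise ValidationError(f"unknown prevalence method {method!r}; use 'analytic' or 'monte-carlo'")


def calibrate_cv(
    mean: float,
    cut: CutPoint,
    target_prevalence: float,
    family: str = "lognormal",
) -> float:
    """Recover the CV that reproduces an observed deficiency prevalence.

    Valid only when ``cut.threshold < mean``: there the prevalence is strictly
    increasing in CV from 0 (point mass above the threshold) so the root is
    unique on the bracket.  At or above the mean the prevalence is non-monotone
    in CV and this function raises rather than return an arbitrary root.
    """
    if not (0.0 < target_prevalence < 1.0):
        raise ValidationError(
            f"target_prevalence must be strictly inside (0, 1), got {target_prevalence}; "
            "0 and 1 are unattainable with a finite CV"
        )
    if not (mean > 0):
        raise ValidationError(f"mean must be > 0, got {mean}")
    if cut.threshold >= mean:
        raise ValidationError(
            f"calibration requires threshold < mean (got threshold={cut.threshold}, "
            f"mean={mean}): prevalence is not monotone in CV when the cut-point is at "
            "or above the mean, so the observed prevalence does not identify a unique CV"
        )

    lo, hi = CV_BRACKET

    def objective(cv: float) -> float:
        d = from_mean_cv(mean, cv, family=family)
        return prevalence_below(d, cut).value - target_prevalence

    f_lo, f_hi = objective(lo), objective(hi)
    if not (f_lo < 0.0 < f_hi):
        raise CalibrationError(
            f"target prevalence {target_prevalence} not attainable for mean={mean}, "
            f"threshold={cut.threshold} within cv in [{lo}, {hi}] "
            f"(prevalence range [{f_lo + target_prevalence:.3g}, {f_hi + target_prevalence:.3g}])"
        )
    cv = optimize.brentq(objective, lo, hi, xtol=1e-13, rtol=8.9e-16, maxiter=200)
    if abs(objective(cv)) > CALIBRATION_TOL * 100:
        raise CalibrationError(f"calibration did not converge: residual {objective(cv):.3e}")
    return float(cv)


def shift_mean(
    dist: NutrientIntakeDistribution, intake_change_pct: float
) -> NutrientIntakeDistribution:
    """Shift the distribution by a percent change in mean intake, CV held fixed.

    Holding the CV (distribution shape) invariant under a mean shift is the
    central simplification of cut-point shock modeling: survey data on how
    intake distributions deform under a disturbance are rarely available, so
    the whole density is rescaled with the mean.
    """
    if intake_change_pct <= -100.0:
        raise ValidationError(
            f"intake_change_pct must be > -100 (mean must stay positive), got {intake_change_pct}"
        )
    return replace(dist, mean=dist.mean * (1.0 + intake_change_pct / 100.0))


def mixture_prevalence(
    strata: Sequence[tuple[float, NutrientIntakeDistribution]],
    cut: CutPoint,
    method: str = "analytic",
    n_draws: int | None = None,
    seed: int | None = None,
) -> PrevalenceEstimate:
    """Population prevalence of a stratified population: weighted stratum mix.

    ``strata`` is a sequence of (weight, distribution) pairs; weights must be
    non-negative and sum to 1 within 1e-9.  Note a mixture of lognormals is
    not lognormal: this is exactly why a pooled single-distribution fit and a
    stratified model disagree even at baseline.
    """
    if not strata:
        raise ValidationError("mixture requires at least one stratum")
    weights = np.asarray([w for w, _ in strata], dtype=float)
    if np.any(weights < 0):
        raise ValidationError("stratum weights must be non-negative")
    if abs(weights.sum() - 1.0) > 1e-9:
        raise ValidationError(f"stratum weights must sum to 1 (got {weights.sum()!r})")
    parts = [
        w * prevalence_below(d, cut, method=method, n_draws=n_draws, seed=seed).value
        for w, d in strata
    ]
    return PrevalenceEstimate(value=float(sum(parts)), method=method, n_draws=n_draws, seed=seed)
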