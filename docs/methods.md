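# Methods

This note documents the modeling assumptions, parameter choices and numerical
decisions behind the package, and what the synthetic-data tests do and do not
establish about real data.

## Intake distributions and cut-point prevalence

A population's usual intake of a nutrient is represented by a two-parameter
density: the mean m (intake units/person/day) and the coefficient of
variation c. The default family is lognormal because it is positive-support,
right-skewed as intake surveys typically are, and closed-form in (m, c):
σ² = ln(1 + c²), µ = ln m − σ²/2, which makes the analytic mean equal the
declared mean exactly. A normal family is available for comparison. The
skew-normal family that also appears in the undernourishment literature is
recognized by name but deliberately unimplemented: mean + CV do not pin down
its third parameter, so accepting it silently would hide an unidentified
degree of freedom.

Deficiency prevalence is the CDF at a cut-point (MDER for energy, EAR for a
micronutrient). This is the population cut-point construction only: the full
probability approach, convolving an intake distribution against a
requirement distribution, and usual-intake adjustment for within-person
variance are out of scope.

**CV calibration.** When a stratum's CV is unknown but its baseline
deficiency prevalence is observed, the CV is recovered by inverting the
prevalence in c. For t < m the lognormal prevalence
Φ(ln(t/m)/σ + σ/2) is strictly increasing in σ (both terms increase), so a
bracketed Brent search on c ∈ [10⁻⁶, 10] has a unique root; the search runs
at brentq's full precision and verifies the residual against a 10⁻¹⁰
prevalence tolerance (the bracket endpoint check reports the attainable
prevalence range when the target lies outside it). For t ≥ m the prevalence
is non-monotone in c and the observed prevalence does not identify a CV; this
regime raises an explanatory error rather than returning an arbitrary root.

**Mean shifts.** A shock changes the mean multiplicatively
(m → m·(1 + Δ%/100)) with the CV held fixed. This is the central
simplification of the whole pipeline: sequential surveys that would reveal
how a disturbance deforms the *shape* of an intake distribution rarely
exist, so the density is rescaled with its mean. Every prevalence change the
package reports is conditional on this assumption.

## Shock propagation

An elasticity is treated as constant over the full shock magnitude
(intake change = ε·Δ%); income and price shocks share one code path, with
the semantics carried by the driver label. Nonlinearity in large shocks is
modeled separately by the response curves, not by bending the elasticity.

Stratified runs aggregate with population weights; expenditure quartiles are
population quarters by construction, so equal weights are the default and
reproduce the published worked example (total intake change −23.8%, baseline
deficiency 13.85%, post-shock aggregate 20.025%). An intake-weighted
aggregate for the intake-change column is available behind
`aggregation="intake"` but is not the default.

**Reference inputs and the calibration substitution.** The worked example
uses published income elasticities for vitamin A in rural Mexican households
(pooled 1.47; expenditure quartiles 1.92/1.79/1.29/1.35) and their reported
deficiency prevalences. The original expenditure-stratified intake
distributions were fitted by a method whose details are not available, so
this package *calibrates* each quartile's CV to its reported baseline
deficiency (45.7/8.5/1.1/0.1%) given invented but realistic quartile means —
600/800/1200/1500 µg RAE/day against an EAR cut-point of 500 µg RAE/day, a
gradient straddling the requirement as expenditure-stratified micronutrient
data typically do. Baseline deficiencies are therefore reproduced by
construction; *post-shock* deficiencies are genuine model predictions under
the lognormal/fixed-CV assumptions and are not expected to match the
published post-shock column, which encodes the unavailable distribution
method. Reported aggregates of that column are checked as aggregation
arithmetic, not as predictions.

**Rounding.** Proportions live at full precision everywhere; rendering to
percent (1 decimal) happens only in the reporting layer, rounding half away
from zero. Published tables are not always consistent in their own last
digit (e.g. a computed −20.25 printed as −20.2, 13.85 printed as 13.8);
comparisons against printed values use a ±0.1 band for that reason.

## Temporal response curves

The four forms share a baseline elasticity ε₀ and differ in how the marginal
response behaves as cumulative inflation p grows. The concrete functional
family — exponential decay of the *marginal* elasticity — is this package's
choice for curves that are only described qualitatively in the literature:

- linear: C(p) = 1 − ε₀p/100, floored at c_min (default 0.4 of baseline, an
  explicit stand-in for a population that cannot endure further reduction;
  the floor sets an `at_floor` flag rather than failing).
- threshold_decay: linear until p*, then
  C(p) = 1 − ε₀p*/100 − (ε₀/100k)(1 − e^{−k(p−p*)}).
- immediate_decay: C(p) = 1 − (ε₀/100k)(1 − e^{−kp}).
- rebound: threshold_decay plus r(1 − e^{−k_r(p−p_rebound)}) past p_rebound,
  capped at baseline.

Defaults p* = 20%, k = 0.05/%, r = 0.05, k_r = 0.1/% were chosen once to
make the four curves visually distinct in the demo plot; they are not
empirical estimates. Useful limits: k→0 recovers the linear form (checked at
k = 10⁻⁸ to 10⁻⁶ absolute), k→∞ gives instant full attenuation. The curves
are deterministic in p, not in time; a trajectory is the pointwise image of
an inflation path, memoryless by construction. Because the literature is
explicitly ambiguous about whether recovery is price- or time-triggered, the
trajectory evaluator exposes `rebound_trigger="price"|"time"` instead of
deciding.

## Catch-up growth and risk reversibility

**Categories.** healthy (Z ≥ −1), mild [−2, −1), moderate [−3, −2), severe
(< −3) — the band edges are the anthropometric convention, since the category
names alone do not fix them. Hazard ratios are mandatory user inputs: the
packaged `hazard_anchors_synthetic.csv` is labelled synthetic and only
shaped like published pooled all-cause-mortality estimates (1.0/1.6/2.6/6.0
at band mid-points).

**Cohort model (A).** Per time-step, each compartment faces competing risks:
die (baseline mortality × compartment hazard ratio), worsen one category,
improve one category, or stay; no multi-category jumps, exactly the usual
simplification. The rate budget worsen + improve + max(HR)·m₀ ≤ 1 is
validated up front. New entrants carry HR = arithmetic mean of origin and
destination category HRs ("intermediate" is otherwise unspecified; geometric
mean is available behind a flag) for `tenure_steps` steps, tracked in
origin- and age-indexed sub-compartments so the process stays Markov on an
enlarged state space; whether the intermediate risk should itself decay with
time-in-category rather than promote in one step is unspecified in the
literature, and the single-promotion choice is the simplest faithful one.
Stay-mass is computed as the exact complement of the outflows, so live mass
plus cumulative deaths is conserved to machine precision (observed drift
~2·10⁻¹⁶ after 10⁴ steps). A transition-matrix construction over the same
compartments provides an independent route used as an oracle in tests.

**Hazard continuum (B).** Anchors (z_ref, HR) must be strictly ordered in z
with non-increasing HR; intermediate Z-scores take piecewise-linear
interpolated hazards. Below the lowest anchor the hazard is held flat
(extrapolating a steeper rise would be invention); above the highest anchor
it is the healthy reference 1.0.

**Individual trajectory (C).** While Z is non-increasing the hazard tracks
the continuum instantly (onset lag zero by default, but exposed as
`onset_half_life` because its existence is an open question). During
catch-up the hazard decays toward the continuum value with half-life λ:
r(t+Δ) = h + (r − h)·2^{−Δ/λ}, the standard exponential cessation-lag form —
the literature says only that accumulated risk "declines gradually", so the
half-life parameterization is this package's choice. A child with multiple
faltering/catch-up episodes simply re-enters the lagged-decay regime on each
catch-up phase; no episode memory beyond the current hazard level is kept.
An optional linear adult ramp (onset age, slope/year) represents late-life
chronic-disease susceptibility; calibrating it is out of scope.

## Synthetic data

The survey generator emulates an expenditure-stratified household intake
survey: lognormal expenditure (median 100, CV 0.8 — arbitrary currency
units), quartiles assigned by *empirical* expenditure quantiles (ties broken
by household id, as surveys stratify), quartile-specific lognormal intakes
(defaults: means 600/800/1200/1500 µg RAE/day, CVs 0.55/0.45/0.35/0.30), and
post-shock intake = pre × (1 + ε_q·Δ/100) × mean-one lognormal noise
(σ = 0.02). The mean-one noise (exp(σZ − σ²/2)) keeps intakes positive,
makes the noiseless ratio exact and the %Δ/%Δ elasticity estimator unbiased
to O(σ²); at n = 4000 the generating quartile elasticities are recovered
within ±0.05 (observed max error ≈ 0.007). Default conditions mirror the
stratified worked example: ε = (1.92, 1.79, 1.29, 1.35), income −15%.

The growth-cohort generator is a seeded random walk: starting Z truncated
standard normal on [−1, 2]; ages advance in 0.25-year steps to 5 years;
before age 2 the child falters with per-step probability 0.25 by an
Exponential(0.35) decrement; from age 2 it catches up with probability 0.30
by an Exponential(0.25) increment capped at its starting Z. Because the walk
only falls before age 2, the ever-stunted probability has a closed
binomial–gamma–truncated-normal form used as the test oracle.

What the generators do *not* emulate: measurement error and usual-intake
day-to-day variance, correlated multi-nutrient demand across food groups,
household composition, seasonal effects, non-monotone growth within a phase,
and any feedback from nutrition status to income. Passing the recovery and
pipeline tests therefore shows the machinery is self-consistent under its own
assumptions, not that those assumptions hold in any real survey.

## Problem sizes and tolerances

Monte-Carlo prevalence checks use 10⁶ draws against a 3σ binomial band;
cohort conservation is checked over 10⁴ steps at 10⁻¹² drift; the survey
recovery uses n = 4000 households; response-curve properties are checked on
dense grids (continuity at breakpoints to 10⁻⁶ over h = 10⁻⁷). These sizes
make the full suite run in a few seconds while leaving the stochastic checks
well-powered. Calibration round-trips are asserted at 10⁻⁶ on CV and 10⁻⁸–
10⁻⁶ on prevalence, comfortably inside the root search's 10⁻¹⁰ tolerance.

## Known limitations

- Fixed-CV mean shifts cannot represent disturbances that hit the tails
  harder than the middle — exactly the scenario stratification is meant to
  approximate, and the reason pooled and stratified runs disagree.
- Elasticities are constant in magnitude and instantaneous in time inside
  the shock engine; the response curves are illustrative forms, not fitted
  consumption dynamics.
- The cohort model's rates are stationary inputs; no calibration to cohort
  data is provided.
- Prevalence aggregation across strata assumes strata are closed (no
  migration between quartiles under the shock).
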