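"""Parametric consumption responses to food-price inflation.

Cross-sectional elasticities are estimated from small price variations, so a
constant-elasticity extrapolation over a large inflation episode is usually
too pessimistic: households shift to staples, borrow, sell assets, or receive
transfers, attenuating the marginal response.  This module provides four
stylized consumption-vs-inflation forms, each a deterministic function
C(p) giving consumption as a fraction of baseline at cumulative inflation p
(percent):

``linear``
    C(p) = 1 − ε₀ p / 100, floored at a configurable biological limit
    ``c_min`` (consumption a population cannot drop below).
``threshold_decay``
    Linear up to a threshold p*; beyond it the *marginal* elasticity decays
    exponentially, ε(p) = ε₀ e^{−k (p − p*)}, so

        C(p) = 1 − ε₀ p*/100 − (ε₀ / (100 k)) (1 − e^{−k (p − p*)}),  p > p*.

``immediate_decay``
    The decay starts at the shock's onset:
    C(p) = 1 − (ε₀ / (100 k)) (1 − e^{−k p}).
``rebound``
    Follows ``threshold_decay`` and, past an inflation level ``p_rebound``
    that triggers compensating responses (subsidies, transfers, food aid),
    recovers by r (1 − e^{−k_r (p − p_rebound)}), capped at baseline.

Whether a rebound is really triggered by the price level or simply by elapsed
time is an open empirical question; ``rebound_trigger`` lets the rebound be
keyed to time instead of price when evaluating a trajectory.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

FORMS = ("linear", "threshold_decay", "immediate_decay", "rebound")

# defaults chosen only to make the four demo curves visually distinct
DEFAULT_P_STAR = 20.0
DEFAULT_K = 0.05
DEFAULT_R = 0.05
DEFAULT_K_R = 0.1
DEFAULT_C_MIN = 0.4

_REQUIRED: dict[str, tuple[str, ...]] = {
    "linear": (),
    "threshold_decay": ("p_star", "k"),
    "immediate_decay": ("k",),
    "rebound": ("p_star", "k", "p_rebound", "r", "k_r"),
}


class ConsumptionPoint(NamedTuple):
    """Consumption fraction plus a flag set when the linear floor binds."""

    value: float
    at_floor: bool


@dataclass(frozen=True)
class ResponseCurve:
    """One of the four consumption-response forms.

    Parameters irrelevant to the chosen form must be left None; ε₀ is the
    baseline elasticity (positive for a price rise reducing consumption), in
    % consumption per % inflation.
    """

    form: str
    epsilon0: float
    p_star: float | None = None
    k: float | None = None
    p_rebound: float | None = None
    r: float | None = None
    k_r: float | None = None
    c_min: float = DEFAULT_C_MIN

    def __post_init__(self) -> None:
        if self.form not in FORMS:
            raise ValidationError(f"ResponseCurve.form must be one of {FORMS}, got {self.form!r}")
        if not (self.epsilon0 > 0):
            raise ValidationError(f"epsilon0 must be > 0, got {self.epsilon0}")
        if not (0 < self.c_min < 1):
            raise ValidationError(f"c_min must be in (0, 1), got {self.c_min}")
        required = _REQUIRED[self.form]
        for name in required:
            if getattr(self, name) is None:
                raise ValidationError(f"form {self.form!r} requires parameter {name!r}")
        for name in ("p_star", "k", "p_rebound", "r", "k_r"):
            if name not in required and getattr(self, name) is not None:
                raise ValidationError(
                    f"parameter {name!r} is not used by form {self.form!r}; leave it unset"
                )
        if self.k is not None and not (self.k > 0):
            raise ValidationError(f"decay rate k must be > 0, got {self.k}")
        if self.k_r is not None and not (self.k_r > 0):
            raise ValidationError(f"recovery rate k_r must be > 0, got {self.k_r}")
        if self.p_star is not None and not (self.p_star >= 0):
            raise ValidationError(f"p_star must be >= 0, got {self.p_star}")
        if self.r is not None and not (0 <= self.r < 1):
            raise ValidationError(f"recovery amplitude r must be in [0, 1), got {self.r}")
        if self.p_rebound is not None:
            if not (self.p_rebound >= 0):
                raise ValidationError(f"p_rebound must be >= 0, got {self.p_rebound}")
            if self.p_star is not None and self.p_rebound < self.p_star:
                raise ValidationError("p_rebound must not precede the decay threshold p_star")

    # ------------------------------------------------------------------
    @classmethod
    def linear(cls, epsilon0: float, c_min: float = DEFAULT_C_MIN) -> "ResponseCurve":
        return cls(form="linear", epsilon0=epsilon0, c_min=c_min)

    @classmethod
    def threshold_decay(
        cls, epsilon0: float, p_star: float = DEFAULT_P_STAR, k: float = DEFAULT_K
    ) -> "ResponseCurve":
        return cls(form="threshold_decay", epsilon0=epsilon0, p_star=p_star, k=k)

    @classmethod
    def immediate_decay(cls, epsilon0: float, k: float = DEFAULT_K) -> "ResponseCurve":
        return cls(form="immediate_decay", epsilon0=epsilon0, k=k)

    @classmethod
    def rebound(
        cls,
        epsilon0: float,
        p_star: float = DEFAULT_P_STAR,
        k: float = DEFAULT_K,
        p_rebound: float = 2 * DEFAULT_P_STAR,
        r: float = DEFAULT_R,
        k_r: float = DEFAULT_K_R,
    ) -> "ResponseCurve":
        return cls(
            form="rebound", epsilon0=epsilon0, p_star=p_star, k=k, p_rebound=p_rebound, r=r, k_r=k_r
        )

    # ------------------------------------------------------------------
    def evaluate(self, p: float) -> ConsumptionPoint:
        """Consumption fraction of baseline at cumulative inflation p (%)."""
        if p < 0:
            raise ValidationError(f"inflation p must be >= 0, got {p}")
        eps = self.epsilon0
        if self.form == "linear":
            raw = 1.0 - eps * p / 100.0
            if raw < self.c_min:
                return ConsumptionPoint(self.c_min, True)
            return ConsumptionPoint(raw, False)
        if self.form == "immediate_decay":
            return ConsumptionPoint(1.0 - (eps / (100.0 * self.k)) * (-math.expm1(-self.k * p)), False)
        # threshold_decay backbone, shared with rebound
        if p <= self.p_star:
            base = 1.0 - eps * p / 100.0
        else:
            base = (
                1.0
                - eps * self.p_star / 100.0
                - (eps / (100.0 * self.k)) * (-math.expm1(-self.k * (p - self.p_star)))
            )
        if self.form == "threshold_decay":
            return ConsumptionPoint(base, False)
        # rebound
        if p > self.p_rebound:
            base = min(1.0, base + self.r * (-math.expm1(-self.k_r * (p - self.p_rebound))))
        return ConsumptionPoint(base, False)

    def __call__(self, p) -> float | np.ndarray:
        if np.ndim(p) == 0:
            return self.evaluate(float(p)).value
        return np.array([self.evaluate(float(x)).value for x in np.asarray(p).ravel()]).reshape(
            np.shape(p)
        )


def consumption_relative(curve: ResponseCurve, p: float) -> ConsumptionPoint:
    """Functional wrapper over :meth:`ResponseCurve.evaluate`."""
    return curve.evaluate(p)


def trajectory(
    curve: ResponseCurve,
    inflation_path: Sequence[tuple[float, float]] | pd.DataFrame,
    rebound_trigger: str = "price",
    t_rebound: float | None = None,
) -> pd.DataFrame:
    """Apply a response curve pointwise along an inflation path.

    ``inflation_path`` is a sequence of (time, inflation %) pairs (or a
    DataFrame with columns ``time`` and ``p``) with strictly increasing times
    and non-negative inflation.  The curve is memoryless in p — consumption at
    a time depends only on the inflation at that time — which is a documented
    limitation, not a claim about behaviour.

    For a ``rebound`` curve, ``rebound_trigger="time"`` keys the recovery to
    elapsed time ``t_rebound`` instead of the price level: before ``t_rebound``
    the threshold-decay backbone is used, after it the full rebound form.
    """
    if isinstance(inflation_path, pd.DataFrame):
        pairs = list(zip(inflation_path["time"].to_numpy(), inflation_path["p"].to_numpy()))
    else:
        pairs = [(float(t), float(p)) for t, p in inflation_path]
    if not pairs:
        raise ValidationError("inflation path is empty")
    times = np.array([t for t, _ in pairs])
    if np.any(np.diff(times) <= 0):
        raise ValidationError("inflation path times must be strictly increasing")
    if rebound_trigger not in ("price", "time"):
        raise ValidationError(f"rebound_trigger must be 'price' or 'time', got {rebound_trigger!r}")
    if rebound_trigger == "time" and curve.form == "rebound" and t_rebound is None:
        raise ValidationError("time-triggered rebound requires t_rebound")

    backbone = (
        ResponseCurve.threshold_decay(curve.epsilon0, curve.p_star, curve.k)
        if curve.form == "rebound"
        else curve
    )
    records = []
    for t, p in pairs:
        if curve.form == "rebound" and rebound_trigger == "time":
            point = curve.evaluate(p) if t >= t_rebound else backbone.evaluate(p)
        else:
            point = curve.evaluate(p)
        records.append({"time": t, "p": p, "consumption": point.value, "at_floor": point.at_floor})
    return pd.DataFrame(records, columns=["time", "p", "consumption", "at_floor"])


def curve_table(curve: ResponseCurve, p_max: float = 60.0, step: float = 0.5) -> pd.DataFrame:
    """A (p, C(p)) table on a regular inflation grid, for export or plotting."""
    grid = np.arange(0.0, p_max + step / 2, step)
    points = [curve.evaluate(float(p)) for p in grid]
    return pd.DataFrame(
        {"p": grid, "consumption": [pt.value for pt in points], "at_floor": [pt.at_floor for pt in points]}
    )


def plot_curves(curves: dict[str, ResponseCurve], p_max: float = 60.0, out_path=None):
    """Plot a family of response curves on one axis (demo figure)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    grid = np.linspace(0, p_max, 400)
    for name, curve in curves.items():
        ax.plot(grid, curve(grid), label=name)
    ax.set_xlabel("cumulative food-price inflation, %")
    ax.set_ylabel("consumption (fraction of baseline)")
    ax.legend()
    fig.tight_layout()
    if out_path is not None:
        fig.savefig(out_path, dpi=120)
        plt.close(fig)
    return fig
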