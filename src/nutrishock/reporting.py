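"""Report rendering: proportions in, percentages out.

Files and JSON always carry proportions at full precision; only rendered text
shows percentages.  Rounding is half-away-from-zero to 1 decimal, matching
how published elasticity tables are typically typeset.
"""

from __future__ import annotations

import json
import math
from typing import TYPE_CHECKING

if TYPE_CHECKING:  # pragma: no cover
    from .shock import ShockResults

ROUNDING_MODES = ("half_away_from_zero", "half_even")


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (0.05 -> 0.1, -0.05 -> -0.1)."""
    factor = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def _round(x: float, ndigits: int, mode: str) -> float:
    if mode == "half_away_from_zero":
        return round_half_away(x, ndigits)
    if mode == "half_even":
        return round(x, ndigits)
    raise ValueError(f"unknown rounding mode {mode!r}")


def fmt_pct(x_prop: float, mode: str = "half_away_from_zero") -> str:
    """Format a proportion as a 1-decimal percentage string."""
    return f"{_round(x_prop * 100.0, 1, mode):.1f}"


def fmt_signed(x: float, mode: str = "half_away_from_zero") -> str:
    """Format a signed percent / percentage-point value with explicit sign."""
    v = _round(x, 1, mode)
    return f"{v:+.1f}"


def render_report(result: "ShockResults", rounding: str = "half_away_from_zero") -> tuple[str, dict]:
    """Render a ShockResults to (text table, full-precision JSON dict).

    Column order follows the conventional stratified-shock layout: baseline
    deficiency %, elasticity, driver change %, total change in intake %, new
    deficiency %, change in deficiency (percentage points).
    """
    if rounding not in ROUNDING_MODES:
        raise ValueError(f"rounding must be one of {ROUNDING_MODES}, got {rounding!r}")
    header = [
        "stratum",
        "baseline deficiency, %",
        "elasticity",
        f"change in {result.shock.driver}, %",
        "total change in intake, %",
        "new deficiency, %",
        "change in deficiency (pp)",
    ]
    lines = []
    for r in list(result.rows) + ([result.aggregate] if result.method == "stratified" else []):
        lines.append(
            [
                r.stratum_id,
                fmt_pct(r.baseline_prevalence, rounding),
                "n/a" if r.elasticity is None else f"{r.elasticity:.3g}",
                f"{r.driver_change_pct:g}",
                fmt_signed(r.intake_change_pct, rounding),
                fmt_pct(r.new_prevalence, rounding),
                fmt_signed(r.change_pp, rounding),
            ]
        )
    widths = [max(len(h), *(len(row[i]) for row in lines)) for i, h in enumerate(header)]
    sep = "  "

    def fmt_line(cells):
        return sep.join(c.rjust(w) for c, w in zip(cells, widths))

    text = "\n".join(
        [
            f"shock model: {result.method} ({result.aggregation}-weighted aggregate)",
            fmt_line(header),
            fmt_line(["-" * w for w in widths]),
            *[fmt_line(row) for row in lines],
        ]
    )
    return text, result.to_json_dict()


def write_report(result: "ShockResults", text_path, json_path, rounding: str = "half_away_from_zero") -> None:
    text, payload = render_report(result, rounding)
    with open(text_path, "w") as fh:
        fh.write(text + "\n")
    with open(json_path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")
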