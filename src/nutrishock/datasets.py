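"""Published reference inputs used by the examples and acceptance checks.

These are income-elasticity estimates and vitamin A deficiency prevalences
reported for rural Mexican households in the demand-analysis literature, as
reproduced in secondary sources.  They are *inputs* to the pipeline — the
package does not estimate elasticities from microdata (see
:mod:`nutrishock.synthetic` for the simple %Δ/%Δ recovery on generated
surveys).

Quartiles are expenditure quartiles (expenditure proxies income), quartile 1
the poorest.  Prevalences are stored as proportions.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .shock import Elasticity

#: income elasticities of nutrient intake, whole-sample estimates
INCOME_ELASTICITIES = {
    "calories": (-0.043, "†"),
    "vitamin_a": (1.244, "*"),
    "vitamin_c": (1.040, "*"),
    "iron": (-0.378, "*"),
    "zinc": (-0.184, "*"),
}

#: whole-sample (pooled) income elasticity of vitamin A intake
VITAMIN_A_POOLED_ELASTICITY = 1.47
#: per-expenditure-quartile income elasticities of vitamin A intake, Q1..Q4
VITAMIN_A_QUARTILE_ELASTICITIES = (1.92, 1.79, 1.29, 1.35)

#: reported baseline vitamin A deficiency, pooled and per quartile (proportions)
VITAMIN_A_POOLED_BASELINE_DEFICIENCY = 0.095
VITAMIN_A_QUARTILE_BASELINE_DEFICIENCY = (0.457, 0.085, 0.011, 0.001)
#: reported post-shock (−15% income) deficiency, pooled and per quartile
VITAMIN_A_POOLED_NEW_DEFICIENCY = 0.150
VITAMIN_A_QUARTILE_NEW_DEFICIENCY = (0.610, 0.164, 0.025, 0.002)


def income_elasticity_table(driver: str = "income") -> list[Elasticity]:
    """The five-nutrient income-elasticity table as Elasticity objects."""
    return [
        Elasticity(value=v, driver=driver, nutrient_id=n, stratum_id="pooled", annotation=a)
        for n, (v, a) in INCOME_ELASTICITIES.items()
    ]


def data_path(name: str) -> Path:
    """Path to a packaged data fixture (CSV/YAML under nutrishock/data)."""
    return Path(resources.files("nutrishock").joinpath("data", name))


def vitamin_a_scenario_path() -> Path:
    """The packaged stratified vitamin A income-shock scenario."""
    return data_path("vitamin_a_income_shock.yaml")


def hazard_anchor_example() -> pd.DataFrame:
    """Synthetic example hazard anchors (z_ref, hr) at Z-band mid-points.

    Values are illustrative, shaped like published pooled all-cause-mortality
    hazard ratios for stunting severity bands; they are not measured data.
    """
    return pd.read_csv(data_path("hazard_anchors_synthetic.csv"))
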