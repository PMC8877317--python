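"""Published reference data for the olanzapine polymeric-micelle case study.

The 16-run D-optimal mixture design (P123/P407/TPGS, percent of total) with
its measured particle-size and entrapment-efficiency responses, the mixture
bounds, the verified optimum composition, and the reported in-vivo AUC
values used by the targeting statistics.  Shipping these printed tables lets
the headline analyses run with no external files.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .design import DesignMatrix, MixtureConstraints
from .scheffe import PseudoCoding, ResponseTable

__all__ = [
    "COMPONENTS",
    "mixture_constraints",
    "pseudo_coding",
    "design_table",
    "design_matrix",
    "response_table",
    "OPTIMUM_PCT",
    "OBSERVED_RANGES",
    "EXPERIMENTAL_AT_OPTIMUM",
    "AUC_0_480",
]

COMPONENTS = ("P123", "P407", "TPGS")

# run, P123 %, P407 %, TPGS %, size (nm), PDI, EE (%)
_DESIGN_ROWS = [
    (1, 68.125, 23.125, 8.75, 41.25, 0.12, 76.21),
    (2, 68.125, 24.375, 7.50, 39.11, 0.19, 78.88),
    (3, 60.000, 30.000, 10.00, 40.00, 0.20, 75.55),
    (4, 68.125, 25.625, 6.25, 38.50, 0.19, 80.24),
    (5, 70.000, 22.500, 7.50, 42.10, 0.11, 83.11),
    (6, 65.000, 30.000, 5.00, 37.89, 0.17, 80.51),
    (7, 70.000, 25.000, 5.00, 41.00, 0.13, 83.66),
    (8, 65.000, 25.000, 10.00, 40.50, 0.13, 68.79),
    (9, 70.000, 20.000, 10.00, 47.44, 0.15, 78.20),
    (10, 62.500, 30.000, 7.50, 37.50, 0.19, 79.63),
    (11, 65.000, 25.000, 10.00, 40.45, 0.20, 68.22),
    (12, 70.000, 20.000, 10.00, 47.55, 0.13, 78.00),
    (13, 60.000, 30.000, 10.00, 40.11, 0.12, 75.54),
    (14, 63.125, 28.125, 8.75, 38.10, 0.20, 75.14),
    (15, 65.000, 30.000, 5.00, 39.20, 0.20, 81.22),
    (16, 70.000, 25.000, 5.00, 40.90, 0.19, 86.84),
]

#: selected optimum composition, percent of total
OPTIMUM_PCT = (63.78, 30.0, 6.22)

#: observed response ranges of the 16-run design — default desirability limits
OBSERVED_RANGES = {"size_nm": (37.50, 47.55), "ee_pct": (68.22, 86.84)}

#: measured responses at the optimum (verification batch, mean values)
EXPERIMENTAL_AT_OPTIMUM = {"size_nm": 39.25, "ee_pct": 82.15}

#: reported AUC(0–480 min) values, brain/plasma × intranasal/intravenous
AUC_0_480 = {
    "brain_in": 2067.22,
    "plasma_in": 1359.37,
    "brain_iv": 504.47,
    "plasma_iv": 1776.21,
}


def mixture_constraints() -> MixtureConstraints:
    """P123 60–70%, P407 20–30%, TPGS 5–10%, total 100% (as fractions)."""
    return MixtureConstraints(
        names=COMPONENTS,
        lower=(0.60, 0.20, 0.05),
        upper=(0.70, 0.30, 0.10),
        total=1.0,
    )


def pseudo_coding() -> PseudoCoding:
    return PseudoCoding(lower=(0.60, 0.20, 0.05))


def design_table() -> pd.DataFrame:
    """The full printed design with responses, compositions in percent."""
    return pd.DataFrame(
        _DESIGN_ROWS,
        columns=["run", "P123", "P407", "TPGS", "size_nm", "pdi", "ee_pct"],
    )


def design_matrix() -> DesignMatrix:
    runs = np.array([r[1:4] for r in _DESIGN_ROWS]) / 100.0
    return DesignMatrix(runs=runs, names=COMPONENTS, model_order="scheffe-quadratic")


def response_table(response: str = "size_nm") -> ResponseTable:
    """Design plus one response column (``size_nm`` or ``ee_pct``)."""
    goals = {"size_nm": "minimize", "ee_pct": "maximize"}
    if response not in goals:
        raise KeyError(f"unknown response {response!r}; use 'size_nm' or 'ee_pct'")
    col = {"size_nm": 4, "ee_pct": 6}[response]
    y = np.array([r[col] for r in _DESIGN_ROWS])
    return ResponseTable(
        design=design_matrix(), y=y, response_name=response, qtpp_goal=goals[response]
    )
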