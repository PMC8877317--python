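"""Critical micelle concentration by two-segment breakpoint regression.

Below the CMC an iodine probe sees little hydrophobic environment and
absorbance rises slowly with polymer concentration; above it, solubilized
I₂ makes absorbance climb steeply.  On an absorbance-vs-log10(concentration)
plot this is an elbow: two joined line segments whose knot is the CMC.  The
knot is found by minimizing the total SSE of a continuous hinge model over
interior candidate positions (coarse grid at data midpoints, then a bounded
1-D refinement around the best candidate).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = ["AbsorbanceCurve", "BreakpointFit", "NoBreakpointError", "detect_cmc"]


class NoBreakpointError(ValueError):
    """No interior knot with a positive slope increase improves on a single line."""


@dataclass(frozen=True)
class AbsorbanceCurve:
    """Probe absorbance versus polymer concentration (% w/v)."""

    concentration_pct_wv: np.ndarray
    absorbance: np.ndarray
    replicates: int = 3

    def __post_init__(self) -> None:
        c = np.asarray(self.concentration_pct_wv, float)
        a = np.asarray(self.absorbance, float)
        if len(c) != len(a):
            raise ValueError("concentration and absorbance lengths differ")
        if np.any(c <= 0):
            raise ValueError("concentrations must be strictly positive")
        if np.any(np.diff(c) <= 0):
            raise ValueError("concentrations must be strictly increasing")
        if not np.all(np.isfinite(a)):
            raise ValueError("absorbances must be finite")


@dataclass(frozen=True)
class BreakpointFit:
    cmc_pct_wv: float
    log10_breakpoint: float
    left_slope: float
    right_slope: float
    left_intercept: float
    sse: float
    single_line_sse: float
    stable: bool  # ≥ 3 points on each side of the knot

    @property
    def right_intercept(self) -> float:
        # continuity at the knot
        return (
            self.left_intercept
            + (self.left_slope - self.right_slope) * self.log10_breakpoint
        )


def _hinge_sse(x: np.ndarray, y: np.ndarray, knot: float) -> tuple[float, np.ndarray]:
    """Least-squares fit of y = b0 + b1·x + b2·max(0, x − knot)."""
    X = np.column_stack([np.ones_like(x), x, np.maximum(0.0, x - knot)])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r), beta


def detect_cmc(curve: AbsorbanceCurve, n_refine: int = 50) -> BreakpointFit:
    """Locate the absorbance breakpoint and return the CMC in % w/v.

    The hinge coefficient must be positive (right slope steeper than left):
    a knot that flattens the curve does not mark micellization.
    """
    x = np.log10(np.asarray(curve.concentration_pct_wv, float))
    y = np.asarray(curve.absorbance, float)
    if len(x) < 6:
        raise ValueError("need at least 6 points spanning the putative breakpoint")

    single_sse, single_beta = _hinge_sse(x, y, x[-1] + 1.0)  # hinge never active

    # coarse candidates: midpoints between consecutive log-concentrations
    mids = (x[:-1] + x[1:]) / 2.0
    candidates = mids[1:-1]  # keep ≥ 2 points strictly on each side
    # a knot only counts if the slope increase is numerically meaningful
    slope_tol = 1e-9 * (np.ptp(y) / np.ptp(x) + 1.0)
    best_knot, best_sse = None, np.inf
    for knot in candidates:
        sse, beta = _hinge_sse(x, y, knot)
        if beta[2] > slope_tol and sse < best_sse:
            best_sse, best_knot = sse, knot
    if best_knot is None or single_sse - best_sse <= 1e-10 * np.ptp(y) ** 2:
        raise NoBreakpointError("no interior knot with right slope > left slope")

    # bounded refinement between the neighbouring coarse candidates
    i = int(np.searchsorted(candidates, best_knot))
    lo = candidates[i - 1] if i > 0 else x[1]
    hi = candidates[i + 1] if i + 1 < len(candidates) else x[-2]
    grid = np.linspace(lo, hi, n_refine)
    for knot in grid:
        sse, beta = _hinge_sse(x, y, knot)
        if beta[2] > 0 and sse < best_sse:
            best_sse, best_knot = sse, knot
    res = minimize_scalar(
        lambda k: _hinge_sse(x, y, k)[0], bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-10},
    )
    sse, beta = _hinge_sse(x, y, res.x)
    if beta[2] > 0 and sse <= best_sse:
        best_sse, best_knot = sse, float(res.x)

    _, beta = _hinge_sse(x, y, best_knot)
    n_left = int(np.sum(x <= best_knot))
    n_right = len(x) - n_left
    return BreakpointFit(
        cmc_pct_wv=float(10.0**best_knot),
        log10_breakpoint=float(best_knot),
        left_slope=float(beta[1]),
        right_slope=float(beta[1] + beta[2]),
        left_intercept=float(beta[0]),
        sse=float(best_sse),
        single_line_sse=float(single_sse),
        stable=n_left >= 3 and n_right >= 3,
    )
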