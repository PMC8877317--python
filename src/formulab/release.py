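"""Dissolution-kinetics model fitting: zero-order, first-order, Higuchi.

Cumulative release Q(t) (% of loaded dose) is regressed under each model's
linearizing transform — Q on t (zero order), ln(100 − Q) on t (first order),
Q on √t (Higuchi diffusion) — and the best model is the one with the highest
R² in its own regression space.  T50, the time to 50% release, is solved from
the best model's equation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "ReleaseProfile",
    "ModelFit",
    "KineticFitResult",
    "fit_release_models",
    "t50",
]

MODELS = ("zero-order", "first-order", "higuchi")


@dataclass(frozen=True)
class ReleaseProfile:
    """Cumulative in-vitro release time course."""

    time_h: np.ndarray
    cumulative_pct: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.time_h, float)
        q = np.asarray(self.cumulative_pct, float)
        if len(t) != len(q):
            raise ValueError("time and release arrays must have equal length")
        if np.any(np.diff(t) <= 0) or t[0] < 0:
            raise ValueError("time must be strictly increasing and start at >= 0")
        if np.any(q < -1e-9) or np.any(q > 100 + 1e-9):
            raise ValueError("cumulative release must lie in [0, 100] %")
        if np.any(np.diff(q) < -1e-9):
            raise ValueError("cumulative release must be non-decreasing")


@dataclass(frozen=True)
class ModelFit:
    model: str
    rate: float  # zero: %/h; first: 1/h; higuchi: %/sqrt(h)
    intercept: float
    r2: float
    adj_r2: float
    notes: tuple[str, ...] = ()


@dataclass(frozen=True)
class KineticFitResult:
    fits: dict[str, ModelFit] = field(repr=False)
    best_model: str
    t50_h: float | None

    def __getitem__(self, model: str) -> ModelFit:
        return self.fits[model]


def _linfit(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    res = stats.linregress(x, y)
    r2 = res.rvalue**2
    n = len(x)
    adj = 1 - (1 - r2) * (n - 1) / (n - 2) if n > 2 else np.nan
    return res.slope, res.intercept, r2, adj


def fit_release_models(profile: ReleaseProfile, min_points: int = 4) -> KineticFitResult:
    """Fit all three kinetic models and select the best by R².

    Points at Q = 100 are excluded from the first-order log transform (with a
    note on the fit); all points enter the zero-order and Higuchi fits.
    """
    t = np.asarray(profile.time_h, float)
    q = np.asarray(profile.cumulative_pct, float)
    if len(t) < min_points:
        raise ValueError(f"need at least {min_points} time points")

    fits: dict[str, ModelFit] = {}

    k, b, r2, adj = _linfit(t, q)
    fits["zero-order"] = ModelFit("zero-order", k, b, r2, adj)

    mask = q < 100.0 - 1e-12
    notes: tuple[str, ...] = ()
    if not np.all(mask):
        notes = (f"excluded {int((~mask).sum())} point(s) at Q=100 from log transform",)
    if mask.sum() < 3:
        raise ValueError("too few points below 100% release for the first-order fit")
    slope, b1, r2_1, adj_1 = _linfit(t[mask], np.log(100.0 - q[mask]))
    # first-order rate constant is the negative log-slope
    fits["first-order"] = ModelFit("first-order", -slope, b1, r2_1, adj_1, notes)

    kh, bh, r2_h, adj_h = _linfit(np.sqrt(t), q)
    fits["higuchi"] = ModelFit("higuchi", kh, bh, r2_h, adj_h)

    best = max(MODELS, key=lambda m: fits[m].r2)
    t50_val = _solve_t50(fits[best], horizon=10.0 * t[-1])
    return KineticFitResult(fits=fits, best_model=best, t50_h=t50_val)


def _solve_t50(m: ModelFit, horizon: float) -> float | None:
    if m.model == "zero-order":
        t = (50.0 - m.intercept) / m.rate if m.rate > 0 else np.inf
    elif m.model == "first-order":
        # ln(100 − Q) = intercept − k t ; Q = 50 ⇒ t = (intercept − ln 50)/k
        t = (m.intercept - np.log(50.0)) / m.rate if m.rate > 0 else np.inf
    else:  # higuchi
        t = ((50.0 - m.intercept) / m.rate) ** 2 if m.rate > 0 else np.inf
    if not np.isfinite(t) or t <= 0 or t > horizon:
        return None
    return float(t)


def t50(fit: KineticFitResult) -> float | None:
    """Time (h) for 50% cumulative release under the best-fitting model;
    ``None`` when the model never reaches 50%."""
    return fit.t50_h
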