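"""Derringer–Suich desirability optimization over the constrained simplex.

Each predicted response is mapped to a desirability d ∈ [0, 1] by a linear
ramp between a low and a high limit (direction set by the goal), and the
overall desirability D is the weighted geometric mean.  The optimum
composition maximizes D; the design space maps which feasible compositions
satisfy hard response thresholds (the overlay / "yellow zone" plot of
quality-by-design reports).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .design import MixtureConstraints
from .scheffe import ScheffeFit, from_pseudo, predict, to_pseudo

__all__ = [
    "ResponseGoal",
    "DesirabilitySpec",
    "DesirabilityResult",
    "DesignSpaceMap",
    "desirability",
    "overall_desirability",
    "optimize_composition",
    "design_space",
]


@dataclass(frozen=True)
class ResponseGoal:
    """Goal and ramp limits for one response."""

    name: str
    goal: str  # "minimize" | "maximize"
    low: float
    high: float
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.goal not in ("minimize", "maximize"):
            raise ValueError(f"goal must be minimize or maximize, got {self.goal!r}")
        if not self.low < self.high:
            raise ValueError("low limit must be below high limit")
        if self.weight <= 0:
            raise ValueError("weight must be positive")


@dataclass(frozen=True)
class DesirabilitySpec:
    goals: tuple[ResponseGoal, ...]

    def __post_init__(self) -> None:
        if not self.goals:
            raise ValueError("at least one response goal is required")


@dataclass(frozen=True)
class DesirabilityResult:
    composition: np.ndarray
    d_per_response: dict[str, float]
    D_overall: float
    predictions: dict[str, float]
    feasible_optimum: bool = True


@dataclass(frozen=True)
class DesignSpaceMap:
    grid: pd.DataFrame = field(repr=False)
    thresholds: dict[str, tuple[str, float]]

    @property
    def n_accepted(self) -> int:
        return int(self.grid["accepted"].sum())


def desirability(prediction: float, goal: ResponseGoal) -> float:
    """One-sided linear ramp desirability with the weight as exponent."""
    y, L, U = prediction, goal.low, goal.high
    if goal.goal == "minimize":
        base = 1.0 if y <= L else 0.0 if y >= U else (U - y) / (U - L)
    else:
        base = 0.0 if y <= L else 1.0 if y >= U else (y - L) / (U - L)
    return float(base**goal.weight)


def overall_desirability(d_values: dict[str, float], spec: DesirabilitySpec) -> float:
    """Weighted geometric mean D = (Π d_i^{w_i})^{1/Σw_i}; zero if any d is zero."""
    w = np.array([g.weight for g in spec.goals])
    d = np.array([d_values[g.name] for g in spec.goals])
    if np.any(d <= 0):
        return 0.0
    return float(np.exp(np.sum(w * np.log(d)) / w.sum()))


def _evaluate(
    fits: dict[str, ScheffeFit], spec: DesirabilitySpec, composition: np.ndarray
) -> tuple[dict[str, float], dict[str, float], float]:
    preds = {g.name: predict(fits[g.name], composition) for g in spec.goals}
    # raw ramp value feeds the geometric mean; the weight enters there once
    d = {
        g.name: desirability(preds[g.name], ResponseGoal(g.name, g.goal, g.low, g.high))
        for g in spec.goals
    }
    return preds, d, overall_desirability(d, spec)


def optimize_composition(
    fits: dict[str, ScheffeFit],
    spec: DesirabilitySpec,
    constraints: MixtureConstraints,
    n_starts: int = 16,
    seed: int = 0,
) -> DesirabilityResult:
    """Maximize overall desirability over the constrained simplex.

    Multi-start Nelder–Mead in the q−1 free pseudo coordinates with a
    feasibility penalty; starts are drawn from feasible candidate points plus
    random feasible draws.  The reported D is recomputed at the returned
    composition, never carried over from the optimizer state.
    """
    codings = {f.coding for f in fits.values()}
    if len(codings) != 1:
        raise ValueError("all fits must share one pseudo coding")
    coding = next(iter(codings))
    q = constraints.n_components
    lo = np.asarray(constraints.lower)
    up = np.asarray(constraints.upper)

    def unpack(z: np.ndarray) -> np.ndarray:
        pseudo = np.append(z, 1.0 - z.sum())
        return from_pseudo(pseudo, coding)

    def neg_D(z: np.ndarray) -> float:
        comp = unpack(z)
        viol = float(
            np.sum(np.maximum(lo - comp, 0) + np.maximum(comp - up, 0))
        ) + max(0.0, -(1.0 - z.sum()))
        if viol > 1e-12:
            return viol * 100.0  # infeasible: positive, dominated by any feasible D
        _, _, D = _evaluate(fits, spec, comp)
        return -D

    rng = np.random.default_rng(seed)
    starts = []
    from .design import generate_candidates

    for pt in generate_candidates(constraints).points:
        starts.append(to_pseudo(pt, coding)[: q - 1])
    target = len(starts) + n_starts
    for _ in range(500):
        if len(starts) >= target:
            break
        raw = rng.dirichlet(np.ones(q)) * (up - lo) + lo
        raw = raw / raw.sum() * constraints.total
        if constraints.contains(raw, tol=1e-6):
            starts.append(to_pseudo(raw, coding)[: q - 1])

    best_z, best_val = None, np.inf
    for z0 in starts:
        res = minimize(neg_D, z0, method="Nelder-Mead",
                       options={"xatol": 1e-7, "fatol": 1e-10, "maxiter": 2000})
        if res.fun < best_val:
            best_val, best_z = res.fun, res.x
    assert best_z is not None
    comp = unpack(best_z)
    comp = np.clip(comp, lo, up)
    comp = comp / comp.sum() * constraints.total
    preds, d, D = _evaluate(fits, spec, comp)
    return DesirabilityResult(
        composition=comp,
        d_per_response=d,
        D_overall=D,
        predictions=preds,
        feasible_optimum=D > 0,
    )


def design_space(
    fits: dict[str, ScheffeFit],
    thresholds: dict[str, tuple[str, float]],
    constraints: MixtureConstraints,
    grid_resolution: int = 60,
) -> DesignSpaceMap:
    """Classify a pseudo-simplex grid of feasible compositions against hard
    response thresholds ``{name: ("<=" | ">=", value)}``.

    The returned grid carries compositions, per-response predictions and the
    acceptance flag, ready for contour plotting.
    """
    codings = {f.coding for f in fits.values()}
    if len(codings) != 1:
        raise ValueError("all fits must share one pseudo coding")
    coding = next(iter(codings))
    for name in thresholds:
        if name not in fits:
            raise KeyError(f"threshold for unknown response {name!r}")

    q = constraints.n_components
    if q != 3:
        raise NotImplementedError("design-space mapping is implemented for 3 components")
    ticks = np.linspace(0.0, 1.0, grid_resolution + 1)
    rows = []
    for a in ticks:
        for b in ticks[ticks <= 1.0 - a + 1e-12]:
            comp = from_pseudo(np.array([a, b, 1.0 - a - b]), coding)
            if not constraints.contains(comp, tol=1e-9):
                continue
            rec = {n: float(c) for n, c in zip(constraints.names, comp)}
            ok = True
            for name, (op, val) in thresholds.items():
                pred = predict(fits[name], comp)
                rec[f"pred_{name}"] = pred
                if op == "<=":
                    ok &= pred <= val
                elif op == ">=":
                    ok &= pred >= val
                else:
                    raise ValueError(f"threshold operator must be <= or >=, got {op!r}")
            rec["accepted"] = bool(ok)
            rows.append(rec)
    return DesignSpaceMap(grid=pd.DataFrame(rows), thresholds=dict(thresholds))
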