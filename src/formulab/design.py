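"""Constrained-simplex candidate generation and D-optimal design selection.

A mixture experiment varies the proportions of q components that must sum to
a constant total.  Lower/upper bounds on each proportion carve a convex
polytope out of the simplex; candidate design points are its extreme vertices
together with centroids and axial check blends (McLean–Anderson style).  A
D-optimal subset of n_runs candidates — the design maximizing det(XᵀX) of the
Scheffé model matrix — is then picked by Fedorov point exchange.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MixtureConstraints",
    "CandidateSet",
    "DesignMatrix",
    "InfeasibleRegionError",
    "RankDeficiencyError",
    "generate_candidates",
    "d_optimal_select",
    "scheffe_terms",
    "n_scheffe_terms",
    "design_log_det",
]

_TOL = 1e-9


class InfeasibleRegionError(ValueError):
    """The bound constraints describe an empty mixture region."""


class RankDeficiencyError(ValueError):
    """Too few runs to estimate the requested Scheffé model."""


@dataclass(frozen=True)
class MixtureConstraints:
    """Bounds on component proportions of a constant-sum mixture.

    Proportions are fractions of ``total`` (1.0 for fractional compositions;
    percent tables are divided by 100 on read).
    """

    names: tuple[str, ...]
    lower: tuple[float, ...]
    upper: tuple[float, ...]
    total: float = 1.0

    def __post_init__(self) -> None:
        q = len(self.names)
        if not (len(self.lower) == len(self.upper) == q):
            raise ValueError("names, lower and upper must have equal length")
        lo, up = np.asarray(self.lower, float), np.asarray(self.upper, float)
        if np.any(lo >= up):
            raise InfeasibleRegionError("each lower bound must be < its upper bound")
        if not (lo.sum() < self.total < up.sum()):
            raise InfeasibleRegionError(
                f"need sum(lower) < total < sum(upper); got "
                f"{lo.sum():g} / {self.total:g} / {up.sum():g}"
            )
        # implied-bound check: component i can reach lower_i while the others
        # stay above their own lowers
        for i in range(q):
            if self.total - (lo.sum() - lo[i]) < lo[i] - _TOL:
                raise InfeasibleRegionError(f"region empty at component {self.names[i]}")

    @property
    def n_components(self) -> int:
        return len(self.names)

    def contains(self, point: np.ndarray, tol: float = 1e-8) -> bool:
        """Feasibility by direct bound and sum check."""
        p = np.asarray(point, float)
        return bool(
            np.all(p >= np.asarray(self.lower) - tol)
            and np.all(p <= np.asarray(self.upper) + tol)
            and abs(p.sum() - self.total) <= tol
        )


@dataclass(frozen=True)
class CandidateSet:
    """Feasible design-point candidates with their geometric provenance."""

    points: np.ndarray  # (m, q) compositions, rows sum to total
    provenance: tuple[str, ...]
    constraints: MixtureConstraints

    def __len__(self) -> int:
        return len(self.points)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.points, columns=list(self.constraints.names))
        df["provenance"] = list(self.provenance)
        return df


@dataclass(frozen=True)
class DesignMatrix:
    """An ordered list of runs selected from a candidate set."""

    runs: np.ndarray  # (n_runs, q)
    names: tuple[str, ...]
    model_order: str  # "scheffe-linear" | "scheffe-quadratic"
    log_det: float = field(default=float("nan"), compare=False)

    @property
    def n_runs(self) -> int:
        return len(self.runs)

    @property
    def replicate_policy(self) -> int:
        """Number of runs beyond the count of distinct compositions."""
        distinct = np.unique(np.round(self.runs, 10), axis=0)
        return self.n_runs - len(distinct)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.runs, columns=list(self.names))
        df.insert(0, "run", np.arange(1, self.n_runs + 1))
        return df


def n_scheffe_terms(q: int, model_order: str) -> int:
    if model_order == "scheffe-linear":
        return q
    if model_order == "scheffe-quadratic":
        return q + q * (q - 1) // 2
    raise ValueError(f"unknown model order {model_order!r}")


def scheffe_terms(points: np.ndarray, model_order: str) -> np.ndarray:
    """Scheffé model matrix: component columns, then binary-blend products."""
    pts = np.atleast_2d(np.asarray(points, float))
    cols = [pts[:, i] for i in range(pts.shape[1])]
    if model_order == "scheffe-quadratic":
        for i, j in itertools.combinations(range(pts.shape[1]), 2):
            cols.append(pts[:, i] * pts[:, j])
    elif model_order != "scheffe-linear":
        raise ValueError(f"unknown model order {model_order!r}")
    return np.column_stack(cols)


def _extreme_vertices(c: MixtureConstraints) -> np.ndarray:
    """Enumerate extreme vertices: fix q−1 components at bounds, solve the rest."""
    q = c.n_components
    lo, up = np.asarray(c.lower), np.asarray(c.upper)
    verts: list[np.ndarray] = []
    for free in range(q):
        others = [i for i in range(q) if i != free]
        for combo in itertools.product(*[(lo[i], up[i]) for i in others]):
            v = np.empty(q)
            v[others] = combo
            v[free] = c.total - sum(combo)
            if lo[free] - _TOL <= v[free] <= up[free] + _TOL:
                verts.append(np.clip(v, lo, up))
    if not verts:
        raise InfeasibleRegionError("no extreme vertices found")
    return _dedupe(np.array(verts))


def _dedupe(points: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    out: list[np.ndarray] = []
    for p in points:
        if not any(np.allclose(p, o, atol=tol) for o in out):
            out.append(p)
    return np.array(out)


def generate_candidates(
    constraints: MixtureConstraints, model_order: str = "scheffe-quadratic"
) -> CandidateSet:
    """Build the candidate set: extreme vertices, facet (edge) centroids, the
    overall centroid, and axial check blends.

    Axial blends are midpoints between the overall centroid and every vertex
    and every edge centroid, which is the support needed to reproduce
    published lower-bounded three-component designs.
    """
    verts = _extreme_vertices(constraints)
    points = [("vertex", v) for v in verts]

    q = constraints.n_components
    lo, up = np.asarray(constraints.lower), np.asarray(constraints.upper)
    label = "edge-centroid" if q == 3 else "face-centroid"
    facet_centroids = []
    for i in range(q):
        for bound in (lo[i], up[i]):
            on_facet = verts[np.abs(verts[:, i] - bound) < 1e-8]
            if len(on_facet) >= 2:
                facet_centroids.append(on_facet.mean(axis=0))
    facet_centroids = _dedupe(np.array(facet_centroids)) if facet_centroids else []
    for fc in facet_centroids:
        points.append((label, fc))

    centroid = verts.mean(axis=0)
    points.append(("overall-centroid", centroid))

    for _, p in list(points):
        axial = (centroid + p) / 2.0
        if not np.allclose(axial, centroid):
            points.append(("axial", axial))

    seen: list[np.ndarray] = []
    provenance: list[str] = []
    for tag, p in points:
        if any(np.allclose(p, s, atol=1e-8) for s in seen):
            continue
        if not constraints.contains(p):
            continue
        seen.append(p)
        provenance.append(tag)
    return CandidateSet(np.array(seen), tuple(provenance), constraints)


def _log_det(X: np.ndarray) -> float:
    sign, ld = np.linalg.slogdet(X.T @ X)
    return ld if sign > 0 else -np.inf


def d_optimal_select(
    candidates: CandidateSet,
    n_runs: int,
    model_order: str = "scheffe-quadratic",
    seed: int = 0,
    n_starts: int = 10,
    max_passes: int = 50,
) -> DesignMatrix:
    """Pick an n_runs-point D-optimal design by Fedorov point exchange.

    Selection is with replacement, so replicate runs arise naturally when they
    improve det(XᵀX).  Each random start draws an initial design, then swaps
    design points for candidates whenever the swap increases the determinant,
    until a full pass makes no improvement.  det(XᵀX) is non-decreasing over
    exchange iterations by construction.
    """
    q = candidates.constraints.n_components
    p = n_scheffe_terms(q, model_order)
    if n_runs < p:
        raise RankDeficiencyError(
            f"n_runs={n_runs} is below the {p} terms of the {model_order} model"
        )
    # pseudo coding keeps XᵀX well conditioned for tightly bounded regions
    lo = np.asarray(candidates.constraints.lower)
    span = candidates.constraints.total - lo.sum()
    coded = (candidates.points - lo) / span
    F = scheffe_terms(coded, model_order)

    rng = np.random.default_rng(seed)
    m = len(candidates)
    best_idx: np.ndarray | None = None
    best_ld = -np.inf
    for _ in range(n_starts):
        idx = rng.choice(m, size=n_runs, replace=True)
        ld = _log_det(F[idx])
        for _ in range(max_passes):
            improved = False
            for i in range(n_runs):
                cur = idx[i]
                for j in range(m):
                    if j == cur:
                        continue
                    idx[i] = j
                    trial = _log_det(F[idx])
                    if trial > ld + 1e-12:
                        ld, cur = trial, j
                        improved = True
                    else:
                        idx[i] = cur
            if not improved:
                break
        if ld > best_ld:
            best_ld, best_idx = ld, idx.copy()
    assert best_idx is not None
    if not np.isfinite(best_ld):
        raise RankDeficiencyError("candidate set cannot support the model")
    order = np.lexsort(candidates.points[best_idx].T[::-1])
    return DesignMatrix(
        runs=candidates.points[best_idx][order],
        names=candidates.constraints.names,
        model_order=model_order,
        log_det=best_ld,
    )


def design_log_det(
    runs: np.ndarray, constraints: MixtureConstraints, model_order: str = "scheffe-quadratic"
) -> float:
    """log det(XᵀX) of an arbitrary design under the same pseudo coding used
    by :func:`d_optimal_select` — for benchmarking designs against each other."""
    lo = np.asarray(constraints.lower)
    span = constraints.total - lo.sum()
    return _log_det(scheffe_terms((np.asarray(runs, float) - lo) / span, model_order))
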