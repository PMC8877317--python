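"""Synthetic-data generators with known ground truth for every pipeline stage.

Each generator emulates one measured input of the formulation study —
mixture responses on a design, cumulative release curves, iodine-probe
absorbance sweeps, and two-route concentration–time profiles — so that every
estimator in the package can be exercised against a recoverable truth.
Noise models: additive Gaussian for responses and absorbance, multiplicative
log-normal for concentrations (which must stay positive).  All generators
are deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cmc import AbsorbanceCurve
from .design import DesignMatrix, scheffe_terms
from .pk import ConcentrationTimeProfile
from .release import ReleaseProfile
from .scheffe import PseudoCoding, ResponseTable, to_pseudo

__all__ = [
    "SurfaceTruth",
    "PKTruth",
    "gen_mixture_responses",
    "gen_release_profile",
    "gen_absorbance_curve",
    "gen_pk_profiles",
    "DEFAULT_SIZE_COEFFS",
    "DEFAULT_EE_COEFFS",
]

#: published quadratic coefficient vectors (pseudo coding) used as defaults
DEFAULT_SIZE_COEFFS = (49.91, 42.96, 88.44, -30.24, -68.56, -80.96)
DEFAULT_EE_COEFFS = (105.52, 93.43, -5.04, -74.19, 42.05, 67.93)


@dataclass(frozen=True)
class SurfaceTruth:
    """Ground-truth Scheffé surface (pseudo coding) for response generation."""

    coefficients: tuple[float, ...] = DEFAULT_SIZE_COEFFS
    noise_sd: float = 0.0
    coding: PseudoCoding = field(default_factory=lambda: PseudoCoding((0.60, 0.20, 0.05)))
    response_name: str = "size_nm"
    qtpp_goal: str = "minimize"


def gen_mixture_responses(
    design: DesignMatrix, truth: SurfaceTruth, seed: int = 0
) -> ResponseTable:
    """y = Scheffé(composition; truth coefficients) + N(0, sd²)."""
    rng = np.random.default_rng(seed)
    P = to_pseudo(design.runs, truth.coding)
    X = scheffe_terms(P, "scheffe-quadratic")
    y = X @ np.asarray(truth.coefficients, float)
    if truth.noise_sd > 0:
        y = y + rng.normal(0.0, truth.noise_sd, size=len(y))
    return ResponseTable(
        design=design, y=y, response_name=truth.response_name, qtpp_goal=truth.qtpp_goal
    )


def gen_release_profile(
    model: str = "higuchi",
    k: float = 20.0,
    intercept: float = 0.0,
    times_h: np.ndarray | None = None,
    noise_pct: float = 0.0,
    seed: int = 0,
) -> ReleaseProfile:
    """Cumulative release from one kinetic law, clipped to [0, 100] and made
    non-decreasing by a running maximum (noise cannot un-release drug)."""
    t = np.asarray(
        times_h if times_h is not None else [0.5, 1, 2, 3, 4, 6, 8, 12, 18, 24], float
    )
    if model == "zero-order":
        q = intercept + k * t
    elif model == "first-order":
        # ln(100 − Q) = intercept' − k t with intercept' = ln(100 − intercept)
        q = 100.0 - (100.0 - intercept) * np.exp(-k * t)
    elif model == "higuchi":
        q = intercept + k * np.sqrt(t)
    else:
        raise ValueError(f"unknown release model {model!r}")
    if np.any(q > 100.0 + 1e-9) or np.any(q < -1e-9):
        raise ValueError("truth parameters drive release outside [0, 100] %")
    if noise_pct > 0:
        rng = np.random.default_rng(seed)
        q = q + rng.normal(0.0, noise_pct, size=len(q))
    q = np.maximum.accumulate(np.clip(q, 0.0, 100.0))
    return ReleaseProfile(time_h=t, cumulative_pct=q)


def gen_absorbance_curve(
    breakpoint_pct_wv: float = 0.001326,
    left_slope: float = 0.02,
    right_slope: float = 0.55,
    baseline: float = 0.10,
    grid: np.ndarray | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> AbsorbanceCurve:
    """Two-segment piecewise-linear absorbance in log10(concentration).

    Default breakpoint 0.001326% w/v; slopes in absorbance per decade.
    """
    conc = np.asarray(
        grid if grid is not None else np.logspace(-5, -1, 17), float
    )
    bp = np.log10(breakpoint_pct_wv)
    if not conc[0] < breakpoint_pct_wv < conc[-1]:
        raise ValueError("breakpoint must lie inside the concentration grid")
    x = np.log10(conc)
    a = baseline + left_slope * (x - x[0])
    a = a + (right_slope - left_slope) * np.maximum(0.0, x - bp)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        a = a + rng.normal(0.0, noise_sd, size=len(a))
    return AbsorbanceCurve(concentration_pct_wv=conc, absorbance=a)


@dataclass(frozen=True)
class PKTruth:
    """Two-route, two-matrix concentration–time ground truth.

    IV plasma is mono-exponential; intranasal plasma is a Bateman curve
    (first-order absorption and elimination).  Brain profiles are
    route-specific scalings of the corresponding plasma curve — the
    systemic, BBB-crossing contribution — and the intranasal brain curve
    carries an additional direct-transport Bateman term for the olfactory
    pathway.  Amplitudes are calibrated via closed-form AUC integrals so the
    noiseless AUC(0–480 min) summaries land near the reported in-vivo values
    (inferred calibration — the underlying curves were never published).
    With equal brain partition scalers and no direct term the two routes
    have identical brain/plasma exposure ratios, i.e. DTE = 100%.
    """

    iv_c0: float = 525.7  # ng/mL
    iv_ke: float = 0.26  # 1/h
    in_ka: float = 7.5  # 1/h
    in_ke: float = 0.19  # 1/h
    in_lag_h: float = 0.0
    bioavailable_fraction: float = 0.7653
    brain_partition_iv: float = 0.284  # brain/plasma AUC ratio, IV route
    brain_partition_in: float = 0.284  # systemic share of the IN brain curve
    direct_auc_h: float = 1681.1  # ng·h/mL direct-transport AUC over 0–480 min
    direct_ke: float = 0.168  # 1/h, terminal decay of the direct term
    schedule_min: tuple[float, ...] = (5, 10, 15, 30, 45, 60, 120, 180, 240, 360, 480)
    noise_cv: float = 0.0

    def __post_init__(self) -> None:
        for name in ("iv_c0", "iv_ke", "in_ka", "in_ke", "brain_partition_iv",
                     "brain_partition_in", "direct_ke"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if abs(self.in_ka - self.in_ke) < 1e-9:
            raise ValueError("absorption and elimination rates must differ")
        if self.direct_auc_h < 0:
            raise ValueError("direct_auc_h must be non-negative")


def _bateman_unit(ka: float, ke: float, t_h: np.ndarray) -> np.ndarray:
    """ka/(ka−ke)·(e^(−ke t) − e^(−ka t)) — unit-amplitude Bateman curve."""
    return ka / (ka - ke) * (np.exp(-ke * t_h) - np.exp(-ka * t_h))


def _bateman_auc_h(ka: float, ke: float, T_h: float) -> float:
    """∫₀ᵀ of the unit Bateman curve, closed form."""
    return ka / (ka - ke) * (
        (1 - np.exp(-ke * T_h)) / ke - (1 - np.exp(-ka * T_h)) / ka
    )


def gen_pk_profiles(
    truth: PKTruth = PKTruth(), seed: int = 0
) -> dict[str, ConcentrationTimeProfile]:
    """Four profiles keyed ``plasma_iv``, ``plasma_in``, ``brain_iv``,
    ``brain_in``; noise is multiplicative log-normal with the stated CV."""
    rng = np.random.default_rng(seed)
    t_min = np.asarray(truth.schedule_min, float)
    t_h = t_min / 60.0
    T = t_min[-1] / 60.0

    curves: dict[str, np.ndarray] = {}
    curves["plasma_iv"] = truth.iv_c0 * np.exp(-truth.iv_ke * t_h)

    tl = np.maximum(0.0, t_h - truth.in_lag_h)
    # amplitude chosen so the analytic AUC(0–T) ratio equals the bioavailable
    # fraction exactly (equal doses both routes)
    auc_iv_T = truth.iv_c0 / truth.iv_ke * (1 - np.exp(-truth.iv_ke * T))
    in_amp = (
        truth.bioavailable_fraction
        * auc_iv_T
        / _bateman_auc_h(truth.in_ka, truth.in_ke, T)
    )
    curves["plasma_in"] = in_amp * _bateman_unit(truth.in_ka, truth.in_ke, tl)

    curves["brain_iv"] = truth.brain_partition_iv * curves["plasma_iv"]

    # systemic share of the IN brain curve mirrors the BBB partition; the
    # direct olfactory term rides on top with its own amplitude and decay
    direct = 0.0
    if truth.direct_auc_h > 0:
        d_amp = truth.direct_auc_h / _bateman_auc_h(truth.in_ka, truth.direct_ke, T)
        direct = d_amp * _bateman_unit(truth.in_ka, truth.direct_ke, tl)
    curves["brain_in"] = truth.brain_partition_in * curves["plasma_in"] + direct

    out: dict[str, ConcentrationTimeProfile] = {}
    for key, c_h in curves.items():
        c = c_h.copy()
        if truth.noise_cv > 0:
            sigma = np.sqrt(np.log(1 + truth.noise_cv**2))
            c = c * rng.lognormal(-0.5 * sigma**2, sigma, size=len(c))
        matrix, route = key.split("_")
        out[key] = ConcentrationTimeProfile(
            time_min=t_min,
            conc_ng_ml=c,
            route="intranasal" if route == "in" else "iv",
            matrix=matrix,
            label=key,
        )
    return out
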