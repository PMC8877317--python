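"""Non-compartmental pharmacokinetics and nose-to-brain targeting statistics.

NCA summarizes a concentration–time profile without a compartmental model:
Cmax/Tmax read off the data, AUC by the linear trapezoid, the terminal
elimination constant Ke from a log-linear fit of the last points, and the
extrapolated tail C_last/Ke completing AUC to infinity.  Targeting metrics
compare brain and plasma exposure between intranasal and intravenous
routes:

    DTE% = 100 · (AUC_brain/AUC_plasma)_in / (AUC_brain/AUC_plasma)_iv
    DTP% = 100 · (B_in − Bx)/B_in,  Bx = (B_iv/P_iv) · P_in

where Bx is the brain exposure expected from systemic circulation alone, so
DTP% is the fraction of intranasal brain exposure delivered by the direct
nose-to-brain pathway.  The two are algebraically locked together:
DTP% = 100·(1 − 100/DTE%).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "ConcentrationTimeProfile",
    "NCAResult",
    "TargetingMetrics",
    "TerminalPhaseError",
    "nca",
    "absolute_bioavailability",
    "targeting_metrics",
]


class TerminalPhaseError(ValueError):
    """Terminal points unusable for a log-linear elimination fit."""


@dataclass(frozen=True)
class ConcentrationTimeProfile:
    """Sampled drug concentrations for one route and matrix."""

    time_min: np.ndarray
    conc_ng_ml: np.ndarray
    route: str = "iv"  # iv | intranasal
    matrix: str = "plasma"  # plasma | brain
    label: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.time_min, float)
        c = np.asarray(self.conc_ng_ml, float)
        if len(t) != len(c):
            raise ValueError("time and concentration lengths differ")
        if len(t) < 3:
            raise ValueError("need at least 3 samples")
        if t[0] < 0 or np.any(np.diff(t) <= 0):
            raise ValueError("times must be non-negative and strictly increasing")
        if np.any(c < 0):
            raise ValueError("concentrations must be non-negative")
        if not np.any(c > 0):
            raise ValueError("profile is all zero")


@dataclass(frozen=True)
class NCAResult:
    cmax_ng_ml: float
    tmax_min: float
    auc_last: float  # ng·min/mL over the observed window
    auc_inf: float  # ng·min/mL
    aumc_inf: float  # ng·min²/mL
    mrt_h: float
    ke_per_h: float
    n_terminal_points: int
    terminal_r2: float

    @property
    def auc_last_ng_h_ml(self) -> float:
        return self.auc_last / 60.0

    @property
    def auc_inf_ng_h_ml(self) -> float:
        return self.auc_inf / 60.0


@dataclass(frozen=True)
class TargetingMetrics:
    F_pct: float | None
    DTE_pct: float
    DTP_pct: float
    Bx: float  # brain AUC attributable to systemic circulation


def _trapz(t: np.ndarray, c: np.ndarray) -> tuple[float, float]:
    auc = float(np.trapezoid(c, t))
    aumc = float(np.trapezoid(t * c, t))
    return auc, aumc


def nca(
    profile: ConcentrationTimeProfile,
    terminal_points: int = 3,
    auc_method: str = "linear",
    extrapolate: bool = True,
) -> NCAResult:
    """Non-compartmental summary of one profile.

    ``terminal_points`` final samples (all positive) feed the log-linear
    elimination fit; the log-trapezoid AUC is available behind
    ``auc_method="log-linear"`` for monotone declining tails.  With
    ``extrapolate=False`` only the observed-window quantities (Cmax, Tmax,
    AUC_0_last) are computed and the terminal-phase fields are NaN — for
    short profiles without a usable elimination phase.
    """
    t = np.asarray(profile.time_min, float)
    c = np.asarray(profile.conc_ng_ml, float)
    if terminal_points < 3:
        raise ValueError("terminal fit needs at least 3 points")

    imax = int(np.argmax(c))
    cmax, tmax = float(c[imax]), float(t[imax])

    if auc_method == "linear":
        auc_last, aumc_last = _trapz(t, c)
    elif auc_method == "log-linear":
        auc_last = aumc_last = 0.0
        for i in range(len(t) - 1):
            dt = t[i + 1] - t[i]
            c0, c1 = c[i], c[i + 1]
            if c1 < c0 and c1 > 0 and c0 > 0:  # log rule on the decline
                k = np.log(c0 / c1) / dt
                auc_last += (c0 - c1) / k
                aumc_last += (t[i] * c0 - t[i + 1] * c1) / k + (c0 - c1) / k**2
            else:
                auc_last += 0.5 * (c0 + c1) * dt
                aumc_last += 0.5 * (t[i] * c0 + t[i + 1] * c1) * dt
    else:
        raise ValueError(f"unknown AUC method {auc_method!r}")

    if not extrapolate:
        return NCAResult(
            cmax_ng_ml=cmax, tmax_min=tmax, auc_last=float(auc_last),
            auc_inf=float("nan"), aumc_inf=float("nan"), mrt_h=float("nan"),
            ke_per_h=float("nan"), n_terminal_points=0, terminal_r2=float("nan"),
        )

    tail_t, tail_c = t[-terminal_points:], c[-terminal_points:]
    if np.any(tail_c <= 0):
        raise TerminalPhaseError("terminal concentrations must be positive")
    fit = stats.linregress(tail_t, np.log(tail_c))
    ke_per_min = -fit.slope
    if ke_per_min <= 0:
        raise TerminalPhaseError("terminal slope is non-negative; Ke undefined")

    c_last, t_last = float(c[-1]), float(t[-1])
    auc_inf = auc_last + c_last / ke_per_min
    aumc_inf = aumc_last + t_last * c_last / ke_per_min + c_last / ke_per_min**2
    mrt_min = aumc_inf / auc_inf
    return NCAResult(
        cmax_ng_ml=cmax,
        tmax_min=tmax,
        auc_last=float(auc_last),
        auc_inf=float(auc_inf),
        aumc_inf=float(aumc_inf),
        mrt_h=float(mrt_min / 60.0),
        ke_per_h=float(ke_per_min * 60.0),
        n_terminal_points=terminal_points,
        terminal_r2=float(fit.rvalue**2),
    )


def absolute_bioavailability(
    auc_in_plasma: float, auc_iv_plasma: float, dose_ratio: float = 1.0
) -> float:
    """F% = 100 · (AUC_in/AUC_iv) · dose_ratio, with dose_ratio = D_iv/D_in
    scaling when the two routes used different doses."""
    if auc_in_plasma <= 0 or auc_iv_plasma <= 0:
        raise ValueError("AUCs must be positive")
    return 100.0 * (auc_in_plasma / auc_iv_plasma) * dose_ratio


def targeting_metrics(
    brain_in: float, plasma_in: float, brain_iv: float, plasma_iv: float
) -> TargetingMetrics:
    """Nose-to-brain targeting statistics from four same-window AUCs.

    Any consistent AUC unit works — the metrics are ratios.
    """
    aucs = (brain_in, plasma_in, brain_iv, plasma_iv)
    if any(a <= 0 for a in aucs):
        raise ValueError("all four AUCs must be positive")
    dte = 100.0 * (brain_in / plasma_in) / (brain_iv / plasma_iv)
    bx = (brain_iv / plasma_iv) * plasma_in
    dtp = 100.0 * (brain_in - bx) / brain_in
    return TargetingMetrics(
        F_pct=absolute_bioavailability(plasma_in, plasma_iv),
        DTE_pct=float(dte),
        DTP_pct=float(dtp),
        Bx=float(bx),
    )
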