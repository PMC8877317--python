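"""Scheffé polynomial response-surface fitting in L-pseudo-component coding.

Mixture polynomials have no intercept: the constant is absorbed by the
constant-sum constraint.  With active lower bounds the fit is done in
L-pseudo components, x′_i = (x_i − L_i)/(1 − ΣL), which map the bounded
region onto the unit simplex and keep coefficients on a comparable scale.
Diagnostics follow response-surface convention: R², adjusted and predicted
R² (via PRESS), and adequate precision (a signal-to-noise ratio, > 4 being
the usual adequacy bar).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .design import DesignMatrix, n_scheffe_terms, scheffe_terms

__all__ = [
    "PseudoCoding",
    "ResponseTable",
    "ScheffeFit",
    "CodingDomainError",
    "SingularFitError",
    "LeverageError",
    "to_pseudo",
    "from_pseudo",
    "fit_scheffe",
    "select_model",
    "predict",
    "press_and_predicted_r2",
    "adequate_precision",
    "entrapment_metrics",
]


class CodingDomainError(ValueError):
    """Composition outside the domain of the pseudo-component transform."""


class SingularFitError(ValueError):
    """Model matrix is rank deficient."""


class LeverageError(ValueError):
    """A run with leverage 1 makes leave-one-out prediction undefined."""


@dataclass(frozen=True)
class PseudoCoding:
    """L-pseudo-component transform defined by the component lower bounds."""

    lower: tuple[float, ...]
    total: float = 1.0

    def __post_init__(self) -> None:
        if self.span <= 0:
            raise ValueError("sum of lower bounds must be below the total")

    @property
    def span(self) -> float:
        return self.total - float(np.sum(self.lower))


def to_pseudo(composition: np.ndarray, coding: PseudoCoding) -> np.ndarray:
    """x′_i = (x_i − L_i)/(total − ΣL); componentwise, vectorized over rows."""
    x = np.asarray(composition, float)
    lo = np.asarray(coding.lower, float)
    if np.any(x < lo - 1e-9):
        raise CodingDomainError(
            f"composition {x} has a component below its lower bound {lo}"
        )
    return (x - lo) / coding.span


def from_pseudo(pseudo: np.ndarray, coding: PseudoCoding) -> np.ndarray:
    return np.asarray(pseudo, float) * coding.span + np.asarray(coding.lower, float)


@dataclass(frozen=True)
class ResponseTable:
    """A design matrix paired with one measured response column."""

    design: DesignMatrix
    y: np.ndarray
    response_name: str = "y"
    qtpp_goal: str = "minimize"  # minimize | maximize

    def __post_init__(self) -> None:
        y = np.asarray(self.y, float)
        if len(y) != self.design.n_runs:
            raise ValueError("response length must equal the number of runs")
        if not np.all(np.isfinite(y)):
            raise ValueError("responses must be finite")


@dataclass(frozen=True)
class ScheffeFit:
    """Fitted Scheffé model with ANOVA and response-surface diagnostics."""

    coefficients: np.ndarray
    term_names: tuple[str, ...]
    model_order: str
    coding: PseudoCoding
    residuals: np.ndarray
    leverages: np.ndarray
    anova: dict[str, float]
    r2: float
    adj_r2: float
    pred_r2: float
    press: float
    adequate_precision: float
    design_points: np.ndarray  # pseudo-coded
    y: np.ndarray

    @property
    def n_terms(self) -> int:
        return len(self.coefficients)

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"term": list(self.term_names), "coefficient": self.coefficients}
        )


def _term_names(names: tuple[str, ...], model_order: str) -> tuple[str, ...]:
    out = list(names)
    if model_order == "scheffe-quadratic":
        q = len(names)
        for i in range(q):
            for j in range(i + 1, q):
                out.append(f"{names[i]}*{names[j]}")
    return tuple(out)


def fit_scheffe(
    table: ResponseTable,
    coding: PseudoCoding,
    model_order: str = "scheffe-quadratic",
) -> ScheffeFit:
    """Ordinary least squares, no intercept, on the Scheffé terms in pseudo coding.

    The ANOVA uses the mixture convention: total SS is corrected for the mean
    and the model carries p − 1 degrees of freedom, the constant-sum
    constraint absorbing the remaining one.
    """
    q = table.design.runs.shape[1]
    p = n_scheffe_terms(q, model_order)
    n = table.design.n_runs
    if n < p:
        raise SingularFitError(f"{n} runs cannot estimate {p} terms")
    P = to_pseudo(table.design.runs, coding)
    X = scheffe_terms(P, model_order)
    if np.linalg.matrix_rank(X) < p:
        raise SingularFitError("Scheffé model matrix is rank deficient")
    y = np.asarray(table.y, float)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    yhat = X @ beta
    resid = y - yhat

    # hat diagonal for PRESS and leverage diagnostics
    Q, _ = np.linalg.qr(X)
    h = np.sum(Q * Q, axis=1)

    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    df_model, df_res = p - 1, n - p
    ss_model = ss_tot - ss_res
    ms_res = ss_res / df_res if df_res > 0 else np.nan
    f_stat = (ss_model / df_model) / ms_res if df_res > 0 and ms_res > 0 else np.inf
    p_val = float(stats.f.sf(f_stat, df_model, df_res)) if np.isfinite(f_stat) else 0.0

    r2 = 1.0 - ss_res / ss_tot
    adj_r2 = 1.0 - (ss_res / df_res) / (ss_tot / (n - 1)) if df_res > 0 else np.nan

    if np.any(h >= 1.0 - 1e-10):
        press = np.nan
        pred_r2 = np.nan
    else:
        press = float(np.sum((resid / (1.0 - h)) ** 2))
        pred_r2 = 1.0 - press / ss_tot

    if df_res > 0 and ss_res > 1e-12 * max(ss_tot, 1e-300):
        ap = float((yhat.max() - yhat.min()) / np.sqrt(p * ms_res / n))
    else:
        ap = np.inf  # zero residual variance: perfect fit

    return ScheffeFit(
        coefficients=beta,
        term_names=_term_names(table.design.names, model_order),
        model_order=model_order,
        coding=coding,
        residuals=resid,
        leverages=h,
        anova={
            "ss_model": ss_model,
            "ss_residual": ss_res,
            "ss_total": ss_tot,
            "df_model": df_model,
            "df_residual": df_res,
            "F": float(f_stat),
            "p": p_val,
        },
        r2=r2,
        adj_r2=adj_r2,
        pred_r2=pred_r2,
        press=press,
        adequate_precision=ap,
        design_points=P,
        y=y,
    )


def select_model(table: ResponseTable, coding: PseudoCoding) -> ScheffeFit:
    """Fit linear and quadratic Scheffé models and pick by the usual criteria:
    adjusted-vs-predicted R² gap below 0.2, then lowest PRESS; quadratic on ties."""
    fits = {
        order: fit_scheffe(table, coding, order)
        for order in ("scheffe-linear", "scheffe-quadratic")
    }
    ok = {
        o: f
        for o, f in fits.items()
        if np.isfinite(f.pred_r2) and (f.adj_r2 - f.pred_r2) < 0.2
    }
    pool = ok or fits
    best = min(
        pool.items(),
        key=lambda kv: (kv[1].press if np.isfinite(kv[1].press) else np.inf,
                        kv[0] != "scheffe-quadratic"),
    )
    return best[1]


def predict(fit: ScheffeFit, composition: np.ndarray) -> float | np.ndarray:
    """Evaluate the Scheffé polynomial at raw composition(s) (fractions of total)."""
    x = np.asarray(composition, float)
    single = x.ndim == 1
    P = to_pseudo(np.atleast_2d(x), fit.coding)
    out = scheffe_terms(P, fit.model_order) @ fit.coefficients
    return float(out[0]) if single else out


def press_and_predicted_r2(fit: ScheffeFit) -> tuple[float, float]:
    """PRESS = Σ (e_i/(1−h_ii))² and predicted R² = 1 − PRESS/SS_total."""
    if np.any(fit.leverages >= 1.0 - 1e-10):
        bad = int(np.argmax(fit.leverages))
        raise LeverageError(f"run {bad + 1} has leverage 1; LOO prediction undefined")
    return fit.press, fit.pred_r2


def adequate_precision(fit: ScheffeFit) -> float:
    """(max ŷ − min ŷ over the design) / sqrt(p·MSE/n); +inf for a perfect fit."""
    return fit.adequate_precision


def entrapment_metrics(
    loaded_mass: float, initial_mass: float, micelle_mass: float
) -> tuple[float, float]:
    """Entrapment efficiency and drug loading, both in percent.

    EE% = 100·loaded/initial; DL% = 100·loaded/carrier mass.
    """
    if initial_mass <= 0 or micelle_mass <= 0 or loaded_mass < 0:
        raise ValueError("masses must be positive (loaded may be zero)")
    if loaded_mass > initial_mass * (1 + 1e-12):
        raise ValueError("mass balance violated: loaded exceeds initially added")
    return 100.0 * loaded_mass / initial_mass, 100.0 * loaded_mass / micelle_mass
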