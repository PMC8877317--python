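"""End-to-end pipelines: formulation optimization and in-vivo targeting.

`run_formulation_pipeline` chains design → Scheffé fits → diagnostics →
desirability optimum → design space → verification block;
`run_invivo_pipeline` chains per-profile NCA → targeting metrics.  Both
consume a validated configuration (YAML file or plain dict) and return a
JSON-serializable report in which every number is produced by a library
operation — the report layer only formats.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import datasets
from .design import DesignMatrix, MixtureConstraints
from .desirability import (
    DesirabilitySpec,
    ResponseGoal,
    design_space,
    optimize_composition,
)
from .pk import ConcentrationTimeProfile, nca, targeting_metrics
from .scheffe import PseudoCoding, ResponseTable, fit_scheffe, predict

__all__ = [
    "PipelineConfig",
    "ConfigError",
    "load_config",
    "read_design_csv",
    "read_profiles_csv",
    "run_formulation_pipeline",
    "run_invivo_pipeline",
]


class ConfigError(ValueError):
    """Configuration failed schema validation."""


@dataclass(frozen=True)
class PipelineConfig:
    """Validated pipeline settings; file paths may be None when the bundled
    published tables are used instead."""

    design_csv: Path | None = None
    profiles_csv: Path | None = None
    names: tuple[str, ...] = datasets.COMPONENTS
    lower: tuple[float, ...] = (0.60, 0.20, 0.05)
    upper: tuple[float, ...] = (0.70, 0.30, 0.10)
    total: float = 1.0
    responses: dict[str, str] = field(
        default_factory=lambda: {"size_nm": "minimize", "ee_pct": "maximize"}
    )
    limits: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(datasets.OBSERVED_RANGES)
    )
    thresholds: dict[str, tuple[str, float]] = field(default_factory=dict)
    experimental: dict[str, float] = field(default_factory=dict)
    terminal_points: int = 3
    auc_method: str = "linear"
    seed: int = 0

    def constraints(self) -> MixtureConstraints:
        return MixtureConstraints(self.names, self.lower, self.upper, self.total)

    def coding(self) -> PseudoCoding:
        return PseudoCoding(self.lower, self.total)


def load_config(source: str | Path | dict[str, Any]) -> PipelineConfig:
    """Build a validated config from a YAML file path or a plain mapping."""
    if isinstance(source, (str, Path)):
        raw = yaml.safe_load(Path(source).read_text())
    else:
        raw = dict(source)
    if not isinstance(raw, dict):
        raise ConfigError("configuration must be a mapping")
    kwargs: dict[str, Any] = {}
    for key in ("design_csv", "profiles_csv"):
        if raw.get(key) is not None:
            p = Path(raw[key])
            if not p.exists():
                raise ConfigError(f"{key} path does not exist: {p}")
            kwargs[key] = p
    for key in ("names", "lower", "upper"):
        if key in raw:
            kwargs[key] = tuple(raw[key])
    for key in ("total", "terminal_points", "auc_method", "seed", "responses",
                "experimental"):
        if key in raw:
            kwargs[key] = raw[key]
    if "limits" in raw:
        kwargs["limits"] = {k: tuple(v) for k, v in raw["limits"].items()}
    if "thresholds" in raw:
        kwargs["thresholds"] = {k: (v[0], float(v[1])) for k, v in raw["thresholds"].items()}
    try:
        cfg = PipelineConfig(**kwargs)
        cfg.constraints()  # validates bounds
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc
    if cfg.terminal_points < 3:
        raise ConfigError("terminal_points must be >= 3")
    for goal in cfg.responses.values():
        if goal not in ("minimize", "maximize"):
            raise ConfigError(f"response goal must be minimize/maximize, got {goal!r}")
    return cfg


def read_design_csv(path: Path, cfg: PipelineConfig) -> pd.DataFrame:
    """Design + responses table; component columns in percent are rescaled to
    fractions when they sum to ~100."""
    df = pd.read_csv(path)
    missing = [c for c in cfg.names if c not in df.columns]
    if missing:
        raise ConfigError(f"design file missing component columns {missing}")
    comp = df[list(cfg.names)].to_numpy(float)
    if np.allclose(comp.sum(axis=1), 100.0 * cfg.total, rtol=1e-3):
        df[list(cfg.names)] = comp / 100.0
    return df


def _response_tables(cfg: PipelineConfig) -> dict[str, ResponseTable]:
    if cfg.design_csv is None:
        return {name: datasets.response_table(name) for name in cfg.responses}
    df = read_design_csv(cfg.design_csv, cfg)
    runs = df[list(cfg.names)].to_numpy(float)
    design = DesignMatrix(runs=runs, names=cfg.names, model_order="scheffe-quadratic")
    tables = {}
    for name, goal in cfg.responses.items():
        if name not in df.columns:
            raise ConfigError(f"design file missing response column {name!r}")
        y = df[name].to_numpy(float)
        if len(y) == 0:
            raise ConfigError("design file has no rows")
        tables[name] = ResponseTable(design, y, name, goal)
    return tables


def run_formulation_pipeline(config: PipelineConfig | dict | str | Path) -> dict:
    """Fit every configured response, optimize desirability, map the design
    space, and verify predictions against experimental values when given."""
    cfg = config if isinstance(config, PipelineConfig) else load_config(config)
    coding = cfg.coding()
    constraints = cfg.constraints()
    tables = _response_tables(cfg)

    fits = {name: fit_scheffe(tbl, coding) for name, tbl in tables.items()}
    goals = []
    for name, goal in cfg.responses.items():
        low, high = cfg.limits.get(
            name, (float(np.min(tables[name].y)), float(np.max(tables[name].y)))
        )
        goals.append(ResponseGoal(name, goal, low, high))
    spec = DesirabilitySpec(tuple(goals))
    optimum = optimize_composition(fits, spec, constraints, seed=cfg.seed)

    report: dict[str, Any] = {
        "models": {
            name: {
                "terms": list(f.term_names),
                "coefficients": [float(b) for b in f.coefficients],
                "anova": {k: float(v) for k, v in f.anova.items()},
                "r2": f.r2,
                "adj_r2": f.adj_r2,
                "pred_r2": f.pred_r2,
                "press": f.press,
                "adequate_precision": f.adequate_precision,
            }
            for name, f in fits.items()
        },
        "optimum": {
            "composition_pct": [float(100 * v) for v in optimum.composition],
            "predictions": {k: float(v) for k, v in optimum.predictions.items()},
            "d_per_response": {k: float(v) for k, v in optimum.d_per_response.items()},
            "D_overall": float(optimum.D_overall),
        },
    }
    if cfg.thresholds:
        ds = design_space(fits, cfg.thresholds, constraints)
        report["design_space"] = {
            "n_grid": int(len(ds.grid)),
            "n_accepted": ds.n_accepted,
            "thresholds": {k: list(v) for k, v in ds.thresholds.items()},
        }
    if cfg.experimental:
        comp = optimum.composition
        block = {}
        for name, exp_val in cfg.experimental.items():
            pred = predict(fits[name], comp)
            block[name] = {
                "experimental": float(exp_val),
                "predicted": round(float(pred), 2),
                "pct_prediction_error": round(100.0 * abs(exp_val - pred) / exp_val, 2),
            }
        report["verification"] = block
    return report


def read_profiles_csv(path: Path) -> dict[str, ConcentrationTimeProfile]:
    """Long-format profiles: time_min, concentration_ng_ml, route, matrix."""
    df = pd.read_csv(path)
    required = {"time_min", "concentration_ng_ml", "route", "matrix"}
    if not required.issubset(df.columns):
        raise ConfigError(f"profiles file must have columns {sorted(required)}")
    out = {}
    for (matrix, route), grp in df.groupby(["matrix", "route"]):
        grp = grp.sort_values("time_min")
        key = f"{matrix}_{'in' if route == 'intranasal' else route}"
        out[key] = ConcentrationTimeProfile(
            time_min=grp["time_min"].to_numpy(float),
            conc_ng_ml=grp["concentration_ng_ml"].to_numpy(float),
            route=str(route),
            matrix=str(matrix),
            label=key,
        )
    return out


def run_invivo_pipeline(
    config: PipelineConfig | dict | str | Path,
    profiles: dict[str, ConcentrationTimeProfile] | None = None,
    aucs: dict[str, float] | None = None,
) -> dict:
    """NCA on the four route×matrix profiles plus targeting metrics.

    ``aucs`` (keys brain_in/plasma_in/brain_iv/plasma_iv) bypasses NCA for
    the targeting block — the pass-through mode for published AUC tables.
    """
    cfg = config if isinstance(config, PipelineConfig) else load_config(config)
    report: dict[str, Any] = {}
    if aucs is None:
        if profiles is None:
            if cfg.profiles_csv is None:
                raise ConfigError("need profiles, a profiles_csv path, or aucs")
            profiles = read_profiles_csv(cfg.profiles_csv)
        needed = {"plasma_iv", "plasma_in", "brain_iv", "brain_in"}
        missing = needed - set(profiles)
        if missing:
            raise ConfigError(f"missing profiles: {sorted(missing)}")
        results = {
            key: nca(p, cfg.terminal_points, cfg.auc_method)
            for key, p in profiles.items()
        }
        report["nca"] = {
            key: {
                "cmax_ng_ml": r.cmax_ng_ml,
                "tmax_min": r.tmax_min,
                "auc_last_ng_min_ml": r.auc_last,
                "auc_last_ng_h_ml": r.auc_last_ng_h_ml,
                "auc_inf_ng_min_ml": r.auc_inf,
                "auc_inf_ng_h_ml": r.auc_inf_ng_h_ml,
                "mrt_h": r.mrt_h,
                "ke_per_h": r.ke_per_h,
            }
            for key, r in results.items()
        }
        aucs = {key: results[key].auc_last for key in results}
    tm = targeting_metrics(
        aucs["brain_in"], aucs["plasma_in"], aucs["brain_iv"], aucs["plasma_iv"]
    )
    identity = 100.0 * (1.0 - 100.0 / tm.DTE_pct)
    assert abs(tm.DTP_pct - identity) < 1e-9, "DTP/DTE identity violated"
    report["targeting"] = {
        "F_pct": tm.F_pct,
        "DTE_pct": tm.DTE_pct,
        "DTP_pct": tm.DTP_pct,
        "Bx": tm.Bx,
        "dtp_dte_identity_residual": tm.DTP_pct - identity,
    }
    return report
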