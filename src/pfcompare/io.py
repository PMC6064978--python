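"""File I/O: the CSV data format, model-spec configs, and JSON reports.

Data files are delimited text with header ``condition,level,k,n`` and one
row per (condition, level) cell. Condition identifiers are arbitrary
strings mapped to 0-based indices in order of first appearance.

Model-spec configs are JSON or YAML:

    {"shape": "logistic", "n_conditions": 2,
     "alpha": {"mode": "fixed", "values": [0, 0]},
     "beta": {"mode": "unconstrained"},
     "gamma": {"mode": "fixed", "values": 0.02},
     "lambda": {"mode": "fixed", "values": 0.02}}

Matrix mode: {"mode": "matrix", "rows": [[1, 1], [1, -1]]}. Custom mode
names a registered family, e.g. {"mode": "custom",
"family": "exp_decay_learning", "theta_init": [0, 2, 0.5]}; arbitrary
callables are only accepted programmatically, never from files.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .data import ConditionData, Dataset
from .exceptions import ConfigurationError, DataError, SpecificationError
from .models import CUSTOM_FAMILIES, ModelSpec, ParamConstraint
from .simulate import ConditionDesign, ExperimentDesign

DATA_COLUMNS = ("condition", "level", "k", "n")


def read_dataset(path) -> Dataset:
    """Read a Dataset from a CSV file with header condition,level,k,n."""
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise DataError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in DATA_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing column(s) {missing}; header must be "
                        f"{','.join(DATA_COLUMNS)}")

    for col in ("level", "k", "n"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if df[col].isna().any() or len(bad):
            row = int((bad if len(bad) else df.index[df[col].isna()])[0]) + 2
            raise DataError(f"{path}: non-numeric or missing {col!r} at row {row}")
        df[col] = coerced

    for idx, row in df.iterrows():
        line = int(idx) + 2  # header is line 1
        if row["n"] <= 0:
            raise DataError(f"{path}: n must be positive at row {line}")
        if not (0 <= row["k"] <= row["n"]):
            raise DataError(f"{path}: k must satisfy 0 <= k <= n at row {line}")

    dup = df.duplicated(subset=["condition", "level"])
    if dup.any():
        raise DataError(
            f"{path}: duplicate (condition, level) cell at row {int(df.index[dup][0]) + 2}"
        )

    labels = list(dict.fromkeys(df["condition"].astype(str)))
    conditions = []
    for label in labels:
        sub = df[df["condition"].astype(str) == label]
        conditions.append(
            ConditionData(
                sub["level"].to_numpy(float),
                sub["k"].to_numpy(int),
                sub["n"].to_numpy(int),
            )
        )
    return Dataset(conditions, labels)


def write_dataset(data: Dataset, path) -> None:
    """Write a Dataset to CSV; round-trips through :func:`read_dataset`."""
    rows = []
    for label, cond in zip(data.labels, data.conditions):
        for level, k, n in zip(cond.levels, cond.k, cond.n):
            rows.append({"condition": label, "level": level, "k": int(k), "n": int(n)})
    pd.DataFrame(rows, columns=list(DATA_COLUMNS)).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Model-spec configs
# ---------------------------------------------------------------------------

def _constraint_from_config(cfg: dict, n_conditions: int) -> ParamConstraint:
    if not isinstance(cfg, dict) or "mode" not in cfg:
        raise SpecificationError(f"constraint config must be a mapping with 'mode': {cfg!r}")
    mode = cfg["mode"]
    if mode == "fixed":
        if "values" not in cfg:
            raise SpecificationError("fixed constraint requires 'values'")
        return ParamConstraint.fixed(cfg["values"])
    if mode == "constrained":
        return ParamConstraint.constrained()
    if mode == "unconstrained":
        return ParamConstraint.unconstrained()
    if mode == "matrix":
        if "rows" not in cfg:
            raise SpecificationError("matrix constraint requires 'rows'")
        return ParamConstraint.from_matrix(cfg["rows"])
    if mode == "custom":
        family = cfg.get("family")
        if family not in CUSTOM_FAMILIES:
            raise ConfigurationError(
                f"unknown custom family {family!r}; "
                f"available: {sorted(CUSTOM_FAMILIES)}"
            )
        mapper = CUSTOM_FAMILIES[family](cfg.get("n_sessions", n_conditions))
        return ParamConstraint.custom(
            mapper, cfg["theta_init"], cfg.get("theta_free")
        )
    raise ConfigurationError(f"unknown constraint mode {mode!r}")


def load_model_spec(path_or_dict, n_conditions: Optional[int] = None) -> ModelSpec:
    """Build a ModelSpec from a JSON/YAML file or an equivalent dict."""
    if isinstance(path_or_dict, (str, Path)):
        with open(path_or_dict) as fh:
            cfg = yaml.safe_load(fh)
    else:
        cfg = dict(path_or_dict)
    if n_conditions is None:
        n_conditions = cfg.get("n_conditions")
    if n_conditions is None:
        raise SpecificationError("model config must state n_conditions")
    constraints = {}
    for key in ("alpha", "beta", "gamma", "lambda"):
        if key not in cfg:
            raise SpecificationError(f"model config missing constraint for {key!r}")
        constraints[key] = _constraint_from_config(cfg[key], n_conditions)
    return ModelSpec(
        shape=cfg.get("shape", "logistic"),
        n_conditions=int(n_conditions),
        alpha=constraints["alpha"],
        beta=constraints["beta"],
        gamma=constraints["gamma"],
        lambda_=constraints["lambda"],
    )


def load_design(path_or_dict) -> ExperimentDesign:
    """Design spec: {"conditions": [{"levels": [...], "n": 50}, ...]}."""
    if isinstance(path_or_dict, (str, Path)):
        with open(path_or_dict) as fh:
            cfg = yaml.safe_load(fh)
    else:
        cfg = dict(path_or_dict)
    conds = [
        ConditionDesign(np.asarray(c["levels"], float), c.get("n", c.get("trials", 50)))
        for c in cfg["conditions"]
    ]
    return ExperimentDesign(conds)


# ---------------------------------------------------------------------------
# JSON reports
# ---------------------------------------------------------------------------

class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, np.integer):
            return int(obj)
        if isinstance(obj, np.floating):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        return super().default(obj)


def fit_result_to_dict(fit) -> dict:
    return {
        "theta_hat": None if fit.theta_hat is None else np.asarray(fit.theta_hat),
        "native_params": fit.native_params,
        "log_likelihood": fit.log_likelihood,
        "k_free": fit.k_free,
        "converged": fit.converged,
        "n_restarts_used": fit.n_restarts_used,
        "warnings": fit.warnings,
    }


def comparison_result_to_dict(res, include_samples: bool = False) -> dict:
    out = {
        "tlr": res.tlr,
        "df": res.df,
        "p_chi2": res.p_chi2,
        "p_mc": res.p_mc,
        "n_mc": res.n_mc,
        "n_failed_fits": res.n_failed_fits,
        "warnings": res.warnings,
        "fuller": fit_result_to_dict(res.fuller) if res.fuller else None,
        "lesser": fit_result_to_dict(res.lesser) if res.lesser else None,
    }
    if include_samples and res.tlr_samples is not None:
        out["tlr_samples"] = res.tlr_samples
    return out


def write_report(payload: dict, path) -> None:
    """Serialize a report to JSON with full double precision."""
    with open(path, "w") as fh:
        json.dump(payload, fh, cls=_NumpyEncoder, indent=2)
        fh.write("\n")
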