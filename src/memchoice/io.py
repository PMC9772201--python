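"""On-disk interchange formats.

All tabular data are plain CSV with fixed, documented headers; all
structured results are JSON; configs are YAML. Every written table
gets a JSON sidecar recording the root seed and a hash of the config
that produced it, so any stage can be re-run in isolation.

Trial CSV schema (the single interchange format consumed by the
screening, inference and ddm stages)::

    participant_id, trial_index, left_item, right_item, pair_type,
    delta_value, delta_mem, abs_delta_value, abs_delta_mem, sum_mem,
    choice (left|right|none), rt_ms (milliseconds; empty if no response)
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "TRIAL_COLUMNS",
    "config_hash",
    "write_table",
    "load_external_trials",
    "dump_json",
    "consistency_to_json",
    "model_fit_to_json",
]

TRIAL_COLUMNS = [
    "participant_id",
    "trial_index",
    "left_item",
    "right_item",
    "pair_type",
    "delta_value",
    "delta_mem",
    "abs_delta_value",
    "abs_delta_mem",
    "sum_mem",
    "choice",
    "rt_ms",
]

REQUIRED_TRIAL_COLUMNS = [
    "participant_id",
    "left_item",
    "right_item",
    "delta_value",
    "delta_mem",
    "choice",
    "rt_ms",
]

RECOGNITION_COLUMNS = ["participant_id", "trial_index", "item_id", "role", "pressed"]


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    if isinstance(obj, pd.Series):
        return obj.to_dict()
    return obj


def config_hash(config) -> str:
    """Stable short hash of a config dataclass/dict (YAML-canonical)."""
    text = yaml.safe_dump(_to_plain(config), sort_keys=True)
    return hashlib.sha256(text.encode()).hexdigest()[:16]


def write_table(df: pd.DataFrame, path: str | Path, seed: int, config=None) -> Path:
    """CSV + JSON provenance sidecar (seed and config hash)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    sidecar = {"seed": int(seed), "rows": int(len(df))}
    if config is not None:
        sidecar["config_hash"] = config_hash(config)
    path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(sidecar, indent=1))
    return path


def load_external_trials(path: str | Path) -> pd.DataFrame:
    """Load a trial CSV, validating the interchange schema.

    Missing required columns raise a named error; the absolute and sum
    covariates are recomputed if absent; extra columns are preserved.
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial file {path} missing required columns: {missing}")
    if "abs_delta_value" not in df.columns:
        df["abs_delta_value"] = df["delta_value"].abs()
    if "abs_delta_mem" not in df.columns:
        df["abs_delta_mem"] = df["delta_mem"].abs()
    bad = set(df["choice"].unique()) - {"left", "right", "none"}
    if bad:
        raise ValueError(f"trial file {path} has invalid choice values: {sorted(bad)}")
    has_rt = df["choice"] != "none"
    if df.loc[has_rt, "rt_ms"].isna().any():
        raise ValueError(f"trial file {path}: responded trials must carry rt_ms")
    return df


def dump_json(obj, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(_to_plain(obj), indent=1, allow_nan=True))
    return path


def consistency_to_json(result, path: str | Path) -> Path:
    """ConsistencyResult -> JSON including the full null distribution."""
    return dump_json(
        {
            "mean_rho": result.mean_rho,
            "p_value": result.p_value,
            "n_iterations": result.n_iterations,
            "rhos": result.rhos,
            "null_rhos": result.null_rhos,
        },
        path,
    )


def model_fit_to_json(fit, path: str | Path) -> Path:
    """ModelFit -> JSON (coefficients, CIs, ORs, LRT p, diagnostics)."""
    return dump_json(
        {
            "kind": fit.kind,
            "response": fit.spec.response,
            "fixed_effects": list(fit.spec.fixed_effects),
            "trial_filter": fit.spec.trial_filter,
            "coefficients": fit.table,
            "loglik": fit.loglik,
            "n_trials": fit.n_trials,
            "n_participants": fit.n_participants,
            "converged": fit.converged,
            "notes": fit.notes,
        },
        path,
    )
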