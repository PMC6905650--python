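"""Readers, writers, configuration and structured logging.

Cohort data travel as tidy CSV with one row per mouse (terminal harvest):
``mouse_id, facility, bmt_age_days, obs_age_days, count_naive, count_tcm,
count_tem, chi_naive, chi_tcm, chi_tem, chi_dp1``.  Donor fractions are
stored un-normalised; normalisation by the mouse's DP1 thymocyte chimerism
happens when a fitting table is extracted.  Long-format measurement CSVs
(``mouse_id, facility, age_days, value, measurement``) feed the source
descriptor fits.  Parameters and descriptors serialise to JSON with explicit
units; run events append to JSON-lines logs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .config import CohortConfig
from .inference import FitData, FitResult
from .models import (
    AgeDepParams,
    HomogeneousParams,
    ResistantParams,
    TwoPhaseParams,
)
from .simulate import COHORT_COLUMNS
from .sources import SourceDescriptor

__all__ = [
    "read_cohort_csv",
    "write_cohort_csv",
    "extract_subset",
    "read_measurements_csv",
    "params_to_dict",
    "params_from_dict",
    "save_fit_json",
    "load_fit_json",
    "save_descriptor_json",
    "load_descriptor_json",
    "load_run_config",
    "log_event",
]

logger = logging.getLogger("memfate")

MEASUREMENTS = (
    "naive_count", "tcm_count", "tem_count",
    "chimerism_naive", "chimerism_tcm", "chimerism_tem", "chimerism_dp1",
)

_PARAM_CLASSES = {
    "homogeneous": HomogeneousParams,
    "two_phase": TwoPhaseParams,
    "age_dep": AgeDepParams,
    "resistant": ResistantParams,
}

_UNITS = {"rates": "per_day", "sizes": "cells", "ages": "days"}


def read_cohort_csv(path) -> pd.DataFrame:
    """Read and validate a cohort CSV; invalid rows are dropped and counted.

    A row is excluded when its DP1 chimerism is missing or non-positive,
    when every subset count is missing, or when any reported count is
    non-positive.  Exclusions are logged, not fatal.
    """
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort CSV {path} is missing columns: {missing}")
    n0 = len(df)
    count_cols = ["count_naive", "count_tcm", "count_tem"]
    bad_counts = (df[count_cols] <= 0).any(axis=1)
    no_counts = df[count_cols].isna().all(axis=1)
    bad_dp1 = df["chi_dp1"].isna() | (df["chi_dp1"] <= 0)
    keep = ~(bad_counts | no_counts | bad_dp1)
    dropped = int((~keep).sum())
    if dropped:
        logger.warning("read_cohort_csv: excluded %d of %d rows (non-positive "
                       "counts or missing DP1 chimerism)", dropped, n0)
    if n0 == 0:
        logger.warning("read_cohort_csv: %s contains no data rows", path)
    return df[keep].reset_index(drop=True)


def write_cohort_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=[c for c in COHORT_COLUMNS if c in df.columns])


def extract_subset(df: pd.DataFrame, subset: str, cfg: CohortConfig) -> FitData:
    """Build the per-subset fitting table (one transformed pair per mouse).

    Normalises the subset donor fraction by each mouse's DP1 chimerism and
    drops rows without the needed measurements or observed earlier than the
    post-BMT stabilisation lag.
    """
    if subset not in ("tcm", "tem"):
        raise ValueError("subset must be 'tcm' or 'tem'")
    cols = [f"count_{subset}", f"chi_{subset}", "chi_dp1"]
    ok = df[cols].notna().all(axis=1) & (df[f"count_{subset}"] > 0) & (df["chi_dp1"] > 0)
    sub = df[ok]
    if len(sub) < len(df):
        logger.info("extract_subset(%s): %d rows lack usable measurements", subset, len(df) - len(sub))
    if sub.empty:
        raise ValueError(f"no usable {subset} records in cohort")
    chi_norm = sub[f"chi_{subset}"].to_numpy() / sub["chi_dp1"].to_numpy()
    data = FitData.from_counts(
        sub["bmt_age_days"].to_numpy(), sub["obs_age_days"].to_numpy(),
        sub[f"count_{subset}"].to_numpy(), chi_norm,
        mouse_id=sub["mouse_id"].to_numpy(),
    )
    data, _ = data.filter_post_bmt(cfg)
    return data


def read_measurements_csv(path) -> pd.DataFrame:
    """Long-format measurement table used by the source-descriptor fits."""
    df = pd.read_csv(path)
    required = ["mouse_id", "facility", "age_days", "value", "measurement"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"measurement CSV {path} is missing columns: {missing}")
    unknown = set(df["measurement"]) - set(MEASUREMENTS)
    if unknown:
        raise ValueError(f"unknown measurement kinds: {sorted(unknown)}")
    return df


# ---------------------------------------------------------------------------
# JSON serialisation


def params_to_dict(model: str, params) -> dict:
    d = dataclasses.asdict(params)
    return {
        "model": model,
        "params": {k: v for k, v in d.items()},
        "units": dict(_UNITS),
    }


def params_from_dict(d: dict):
    cls = _PARAM_CLASSES[d["model"]]
    fields = {f.name for f in dataclasses.fields(cls)}
    return cls(**{k: v for k, v in d["params"].items() if k in fields})


def save_fit_json(fit: FitResult, path) -> None:
    payload = fit.to_dict()
    Path(path).write_text(json.dumps(payload, indent=2))


def load_fit_json(path) -> dict:
    d = json.loads(Path(path).read_text())
    d["params_obj"] = params_from_dict({"model": d["model"], "params": d["params"]})
    return d


def save_descriptor_json(desc: SourceDescriptor, path) -> None:
    Path(path).write_text(json.dumps(desc.to_dict(), indent=2))


def load_descriptor_json(path) -> SourceDescriptor:
    return SourceDescriptor.from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# run configuration (YAML) and structured logs


_RUN_DEFAULTS = {
    "models": ["homogeneous", "two_phase", "age_dep", "resistant"],
    "sources": ["naive", "tcm"],
    "n_starts": 20,
    "seed": 1,
    "n_boot": 1000,
    "method": "grid",
}


def load_run_config(path) -> dict:
    """YAML run configuration merged over defaults; week fields convert to days."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("run config must be a YAML mapping")
    cfg = dict(_RUN_DEFAULTS)
    cfg.update(raw)
    for key in list(cfg):
        if key.endswith("_weeks"):
            cfg[key.replace("_weeks", "_days")] = float(cfg.pop(key)) * 7.0
    unknown_models = set(cfg["models"]) - set(_PARAM_CLASSES)
    if unknown_models:
        raise ValueError(f"run config lists unknown models: {sorted(unknown_models)}")
    return cfg


def log_event(log_path, event: str, **fields) -> None:
    """Append one JSON line describing a pipeline event."""
    rec = {"time": datetime.now(timezone.utc).isoformat(), "event": event}
    rec.update(fields)

    def _default(o):
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        return str(o)

    with open(log_path, "a") as fh:
        fh.write(json.dumps(rec, default=_default) + "\n")
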