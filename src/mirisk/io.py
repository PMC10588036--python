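"""Reading and writing cohort tables and machine-readable outputs.

Cohorts travel as comma-separated text with a header row, UTF-8, "." decimal;
structured results as JSON.  ``read_cohort`` applies an optional schema that
renames columns and maps coded event labels (e.g. yes/no) to 0/1; cells that
fail numeric parsing become missing values, with per-column counts returned
alongside the cohort.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .cohort import RESERVED_COLUMNS, SurvivalCohort
from .errors import ValidationError


@dataclass
class CohortSchema:
    time_col: str = "time"
    event_col: str = "event"
    id_col: str = "subject_id"
    arm_col: str | None = "arm"
    #: value -> {0,1} mapping for coded event columns
    event_map: dict[Any, int] | None = None
    covariates: list[str] = field(default_factory=list)


def read_cohort(path, schema: CohortSchema | None = None) -> tuple[SurvivalCohort, dict]:
    """Load a delimited cohort table; returns (cohort, parse report)."""
    schema = schema or CohortSchema()
    raw = pd.read_csv(path)
    for col, name in ((schema.time_col, "time"), (schema.event_col, "event")):
        if col not in raw.columns:
            raise ValidationError(f"mandatory column '{col}' ({name}) missing")
    df = pd.DataFrame()
    if schema.id_col in raw.columns:
        df["subject_id"] = raw[schema.id_col].astype(str)
    else:
        df["subject_id"] = [f"S{i + 1:04d}" for i in range(len(raw))]
    df["time"] = pd.to_numeric(raw[schema.time_col], errors="coerce")
    ev = raw[schema.event_col]
    if schema.event_map:
        ev = ev.map(schema.event_map)
    df["event"] = pd.to_numeric(ev, errors="coerce")
    if schema.arm_col and schema.arm_col in raw.columns:
        df["arm"] = raw[schema.arm_col].astype(str)
    covs = schema.covariates or [
        c
        for c in raw.columns
        if c not in (schema.time_col, schema.event_col, schema.id_col, schema.arm_col)
    ]
    unparseable: dict[str, int] = {}
    for c in covs:
        if c not in raw.columns:
            raise ValidationError(f"declared covariate '{c}' missing from file")
        parsed = pd.to_numeric(raw[c], errors="coerce")
        n_bad = int(parsed.isna().sum() - raw[c].isna().sum())
        if n_bad:
            unparseable[c] = n_bad
        df[c] = parsed
    bad_time = df["time"].notna() & (df["time"] <= 0)
    if bad_time.any():
        rows = df.loc[bad_time, "subject_id"].tolist()
        raise ValidationError(f"non-positive follow-up times for subjects {rows[:10]}")
    cohort = SurvivalCohort(df, covariate_names=list(covs))
    return cohort, {"n_rows": len(df), "unparseable_cells": unparseable}


def write_cohort(cohort: SurvivalCohort, path) -> None:
    cohort.data.to_csv(path, index=False)


def write_json(obj, path) -> None:
    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, tuple):
            return list(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=default)


def preprocess(cohort: SurvivalCohort, log_columns: list[str]) -> SurvivalCohort:
    """Derive natural-log analysis columns (log_<name>) for skewed markers."""
    out = cohort
    for name in log_columns:
        if name not in out.data.columns:
            raise ValidationError(f"cannot log-transform missing column '{name}'")
        v = out.data[name].to_numpy(dtype=float)
        if np.any(v[np.isfinite(v)] <= 0):
            raise ValidationError(f"column '{name}' has non-positive values")
        out = out.with_column(f"log_{name}", np.log(v))
    return out
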