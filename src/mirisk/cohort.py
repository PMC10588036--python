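"""The patient-level survival cohort container.

A :class:`SurvivalCohort` wraps a pandas DataFrame with one row per subject:
``subject_id``, follow-up ``time`` in years, ``event`` (0/1), an optional
``arm`` label, and named numeric covariates (binary ones coded 0/1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

RESERVED_COLUMNS = ("subject_id", "time", "event", "arm")


@dataclass
class SurvivalCohort:
    data: pd.DataFrame
    covariate_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        df = self.data
        for col in ("subject_id", "time", "event"):
            if col not in df.columns:
                raise ValidationError(f"cohort is missing mandatory column '{col}'")
        if df["subject_id"].duplicated().any():
            dupes = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
            raise ValidationError(f"duplicated subject ids: {dupes[:5]}")
        t = df["time"].to_numpy(dtype=float)
        bad = np.nonzero(~np.isfinite(t) | (t <= 0))[0]
        if bad.size:
            rows = df["subject_id"].iloc[bad[:10]].tolist()
            raise ValidationError(
                f"follow-up times must be finite and > 0; offending subjects: {rows}"
            )
        ev = df["event"].to_numpy()
        if not np.isin(ev[~pd.isna(ev)], (0, 1)).all():
            raise ValidationError("event indicator must be coded 0/1")
        if not self.covariate_names:
            self.covariate_names = [
                c for c in df.columns if c not in RESERVED_COLUMNS
            ]
        if len(set(self.covariate_names)) != len(self.covariate_names):
            raise ValidationError("covariate names must be unique")
        missing = [c for c in self.covariate_names if c not in df.columns]
        if missing:
            raise ValidationError(f"declared covariates absent from table: {missing}")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def time(self) -> np.ndarray:
        return self.data["time"].to_numpy(dtype=float)

    @property
    def event(self) -> np.ndarray:
        return self.data["event"].to_numpy(dtype=int)

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    @property
    def event_fraction(self) -> float:
        return float(self.event.mean())

    @property
    def person_years(self) -> float:
        return float(self.time.sum())

    def subset(self, mask: np.ndarray) -> "SurvivalCohort":
        return SurvivalCohort(
            self.data.loc[np.asarray(mask)].reset_index(drop=True),
            list(self.covariate_names),
        )

    def with_column(self, name: str, values: np.ndarray) -> "SurvivalCohort":
        df = self.data.copy()
        df[name] = values
        names = list(self.covariate_names)
        if name not in names and name not in RESERVED_COLUMNS:
            names.append(name)
        return SurvivalCohort(df, names)
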