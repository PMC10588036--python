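"""Incremental prognostic value of a circulating marker on top of clinical models.

The nested clinical models follow the established prognostic factor set for
this population:

* model 1 — treatment arm (ASV), age, sex;
* model 2 — model 1 plus SBP < 120 mmHg, diabetes, diuretic use, cardiac
  device, 6-min walk distance and atrial fibrillation;
* model 3 — model 2 plus log(NT-proBNP).

``mirna_association`` adds a log-transformed miRNA level to a model and
reports its adjusted hazard ratio per one log-unit (optionally per SD).
``cnri_idi`` quantifies reclassification at a fixed horizon (2 years by
default) with IPCW estimators of the continuous net reclassification
improvement and the integrated discrimination improvement; confidence
intervals come from subject-level bootstrap resampling with full model
refits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import SurvivalCohort
from .cox import CoxModelFit, fit_cox
from .errors import ConfigurationError, ValidationError
from .risk_metrics import _censoring_survival

#: nested clinical covariate sets keyed by model id
MODEL_COVARIATES: dict[int, list[str]] = {
    1: ["asv", "age", "male"],
    2: [
        "asv", "age", "male",
        "sbp_lt_120", "diabetes", "diuretic",
        "cardiac_device", "walk_distance", "atrial_fibrillation",
    ],
    3: [
        "asv", "age", "male",
        "sbp_lt_120", "diabetes", "diuretic",
        "cardiac_device", "walk_distance", "atrial_fibrillation",
        "log_nt_probnp",
    ],
}


@dataclass
class ModelSpec:
    model_id: int
    covariates: list[str]

    @classmethod
    def standard(cls, model_id: int) -> "ModelSpec":
        if model_id not in MODEL_COVARIATES:
            raise ConfigurationError("model id must be 1, 2 or 3")
        return cls(model_id, list(MODEL_COVARIATES[model_id]))


def _frame(cohort) -> pd.DataFrame:
    return cohort.data if isinstance(cohort, SurvivalCohort) else cohort


def mirna_association(
    cohort,
    mirna_log_column: str,
    model: int | ModelSpec | None = None,
    arm: str | None = None,
    per_sd: bool = False,
) -> CoxModelFit:
    """Cox HR of a log-scale miRNA level, crude or adjusted per nested model.

    ``arm`` restricts the fit to one treatment group ('control' or 'ASV').
    The HR is per one log-unit increase, or per SD of the analysed sample
    when ``per_sd`` is set.
    """
    df = _frame(cohort)
    if arm is not None:
        if "arm" not in df.columns:
            raise ValidationError("cohort has no 'arm' column for subgroup fits")
        df = df[df["arm"] == arm]
        if len(df) == 0:
            raise ValidationError(f"no subjects in arm '{arm}'")
    if model is None:
        covs: list[str] = []
    elif isinstance(model, ModelSpec):
        covs = list(model.covariates)
    else:
        covs = list(MODEL_COVARIATES[int(model)])
    if arm is not None:
        # within one arm the treatment indicator is constant: drop it
        covs = [c for c in covs if df[c].nunique(dropna=True) > 1]
    df = df.copy()
    col = mirna_log_column
    if per_sd:
        col = f"{mirna_log_column}_per_sd"
        v = df[mirna_log_column].to_numpy(dtype=float)
        df[col] = v / np.nanstd(v, ddof=1)
    return fit_cox(df, covs + [col])


# ---------------------------------------------------------------------------
# reclassification at a horizon
# ---------------------------------------------------------------------------

@dataclass
class ReclassificationResult:
    horizon: float
    cnri: float
    cnri_ci: tuple[float, float]
    cnri_p: float
    idi: float
    idi_ci: tuple[float, float]
    idi_p: float
    n_resample: int
    seed: int
    n: int
    n_events_by_horizon: int


def _ipcw_cnri_idi(p_base, p_aug, time, event, horizon):
    """Point estimates of IPCW continuous NRI and IDI at the horizon."""
    cases = (time <= horizon) & (event == 1)
    controls = time > horizon
    if cases.sum() == 0 or controls.sum() == 0:
        raise ValidationError("no cases or no controls at the horizon")
    G = _censoring_survival(time, event)
    w_case = 1.0 / G(time[cases], side="left")
    w_ctrl = np.full(int(controls.sum()), 1.0 / float(G(np.array([horizon]))[0]))

    def wmean(w, x):
        return float((w * x).sum() / w.sum())

    up_case = wmean(w_case, (p_aug[cases] > p_base[cases]).astype(float))
    dn_case = wmean(w_case, (p_aug[cases] < p_base[cases]).astype(float))
    up_ctrl = wmean(w_ctrl, (p_aug[controls] > p_base[controls]).astype(float))
    dn_ctrl = wmean(w_ctrl, (p_aug[controls] < p_base[controls]).astype(float))
    cnri = (up_case - dn_case) + (dn_ctrl - up_ctrl)
    idi = (wmean(w_case, p_aug[cases]) - wmean(w_ctrl, p_aug[controls])) - (
        wmean(w_case, p_base[cases]) - wmean(w_ctrl, p_base[controls])
    )
    return cnri, idi


def cnri_idi(
    cohort,
    base_covariates: list[str],
    augmented_covariates: list[str],
    horizon: float = 2.0,
    n_resample: int = 300,
    seed: int = 0,
) -> ReclassificationResult:
    """Continuous NRI and IDI of the augmented over the base model at a horizon.

    Both Cox models are fitted on the complete cases of the augmented
    covariate set (so the comparison is on identical subjects); predicted
    event probabilities at the horizon come from each model's Breslow
    baseline.  CIs and p-values come from percentile bootstrap over subjects
    with both models refitted in every replicate.
    """
    if not set(base_covariates) <= set(augmented_covariates):
        raise ConfigurationError("base model must be nested in the augmented model")
    df = _frame(cohort)
    cols = ["time", "event"] + list(augmented_covariates)
    sub = df[cols].dropna().reset_index(drop=True)
    time = sub["time"].to_numpy(dtype=float)
    event = sub["event"].to_numpy(dtype=float)
    if horizon > time.max():
        raise ValidationError("horizon lies beyond the last observed time")

    def estimate(frame):
        t = frame["time"].to_numpy(dtype=float)
        e = frame["event"].to_numpy(dtype=float)
        fb = fit_cox(frame, list(base_covariates))
        fa = fit_cox(frame, list(augmented_covariates))
        pb = fb.predict_event_probability(
            frame[list(base_covariates)].to_numpy(dtype=float), horizon
        )
        pa = fa.predict_event_probability(
            frame[list(augmented_covariates)].to_numpy(dtype=float), horizon
        )
        return _ipcw_cnri_idi(pb, pa, t, e, horizon)

    cnri, idi = estimate(sub)
    rng = np.random.default_rng(seed)
    n = len(sub)
    boots = []
    for _ in range(n_resample):
        idx = rng.integers(0, n, n)
        try:
            boots.append(estimate(sub.iloc[idx].reset_index(drop=True)))
        except (ValidationError, np.linalg.LinAlgError):
            continue
    if boots:
        arr = np.asarray(boots, dtype=float)
        cnri_ci = tuple(np.percentile(arr[:, 0], [2.5, 97.5]))
        idi_ci = tuple(np.percentile(arr[:, 1], [2.5, 97.5]))

        def pval(point, sample):
            sd = sample.std(ddof=1)
            if sd == 0:
                return 1.0
            return float(2 * stats.norm.sf(abs(point) / sd))

        cnri_p = pval(cnri, arr[:, 0])
        idi_p = pval(idi, arr[:, 1])
    else:
        cnri_ci = idi_ci = (float("nan"), float("nan"))
        cnri_p = idi_p = float("nan")
    return ReclassificationResult(
        horizon=float(horizon),
        cnri=float(cnri),
        cnri_ci=(float(cnri_ci[0]), float(cnri_ci[1])),
        cnri_p=cnri_p,
        idi=float(idi),
        idi_ci=(float(idi_ci[0]), float(idi_ci[1])),
        idi_p=idi_p,
        n_resample=int(n_resample),
        seed=int(seed),
        n=n,
        n_events_by_horizon=int(((time <= horizon) & (event == 1)).sum()),
    )
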