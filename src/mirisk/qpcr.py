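"""RT-qPCR relative quantification and the candidate-selection filters.

Relative miRNA level RQ = N0(target) / N0(reference miRNA), where N0 values
are initial concentrations in arbitrary fluorescence units exported from
amplification-curve software; miR-486-5p is the internal standard.  Levels
are log-transformed (natural log) before statistical analysis.

Screening keeps transcripts showing at least a 1.25-fold difference between
cases and controls at a two-sided rank-sum p < 0.1; validation additionally
requires detection in at least 80% of samples.  Fold changes are computed on
arithmetic means of the linear-scale values by default (``scale="log"``
switches to means of logs, i.e. a geometric-mean ratio).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort_stats import wilcoxon_rank_sum
from .errors import NumericalError, ValidationError


def relative_quantity(n0_target, n0_reference):
    """RQ = N0(target) / N0(reference); elementwise on arrays."""
    t = np.asarray(n0_target, dtype=float)
    r = np.asarray(n0_reference, dtype=float)
    if np.any(r <= 0):
        raise NumericalError("reference N0 must be strictly positive")
    if np.any(t < 0):
        raise ValidationError("target N0 must be nonnegative")
    out = t / r
    return float(out) if out.ndim == 0 else out


def log_transform(rq_values):
    """Natural log of relative quantities; zero/negative values are rejected
    with the offending sample positions listed."""
    v = np.asarray(rq_values, dtype=float)
    bad = np.nonzero(~(np.atleast_1d(v) > 0))[0]
    if bad.size:
        raise ValidationError(
            f"non-loggable (<= 0) relative quantities at positions {bad.tolist()[:10]}"
        )
    out = np.log(v)
    return float(out) if out.ndim == 0 else out


@dataclass
class CandidateSelection:
    transcript: str
    fold_change: float          # larger-mean / smaller-mean, always >= 1
    direction: str              # "up" (cases > controls) or "down"
    p_value: float
    detection_fraction: float
    passes: bool


@dataclass
class ExpressionMatrix:
    """samples x transcripts nonnegative expression with case/control labels.

    ``detected`` marks reliably measured cells; it defaults to value > 0.
    """

    values: pd.DataFrame
    group: np.ndarray           # 1 = case, 0 = control per sample (row)
    detected: pd.DataFrame | None = None

    def __post_init__(self):
        if (self.values.to_numpy(dtype=float) < 0).any():
            raise ValidationError("expression values must be nonnegative")
        self.group = np.asarray(self.group)
        if not np.isin(self.group, (0, 1)).all():
            raise ValidationError("group labels must be 0/1")
        if len(self.group) != len(self.values):
            raise ValidationError("one group label per sample required")
        if self.values.columns.duplicated().any():
            raise ValidationError("transcript names must be unique")
        if self.detected is None:
            self.detected = self.values > 0
        if self.detected.shape != self.values.shape:
            raise ValidationError("detected mask must match matrix shape")

    def detection_fraction(self, transcript: str) -> float:
        return float(self.detected[transcript].mean())


def screen_candidates(
    matrix: ExpressionMatrix,
    fc_threshold: float = 1.25,
    p_threshold: float = 0.1,
    scale: str = "linear",
) -> list[CandidateSelection]:
    """Differential-expression screen: pass iff FC >= threshold AND p < threshold.

    FC is the ratio of group means (linear scale by default), reported as the
    larger/smaller mean with the direction stored separately; p is the
    two-sided Wilcoxon rank-sum p-value.
    """
    cases = matrix.group == 1
    controls = matrix.group == 0
    if cases.sum() < 2 or controls.sum() < 2:
        raise ValidationError("need at least two samples per group")
    out = []
    for tr in matrix.values.columns:
        col = matrix.values[tr].to_numpy(dtype=float)
        vc, vn = col[cases], col[controls]
        if scale == "log":
            eps = np.nextafter(0, 1)
            mc, mn = np.exp(np.mean(np.log(np.maximum(vc, eps)))), np.exp(
                np.mean(np.log(np.maximum(vn, eps)))
            )
        else:
            mc, mn = vc.mean(), vn.mean()
        if mc == 0 and mn == 0:
            fc, direction = 1.0, "none"
        elif mc >= mn:
            fc, direction = (np.inf if mn == 0 else mc / mn), "up"
        else:
            fc, direction = (np.inf if mc == 0 else mn / mc), "down"
        p = wilcoxon_rank_sum(vc, vn)
        out.append(
            CandidateSelection(
                transcript=str(tr),
                fold_change=float(fc),
                direction=direction,
                p_value=p,
                detection_fraction=matrix.detection_fraction(tr),
                passes=bool(fc >= fc_threshold and p < p_threshold),
            )
        )
    return out


def detection_filter(matrix: ExpressionMatrix, min_fraction: float = 0.8) -> list[str]:
    """Transcripts detected in at least ``min_fraction`` of samples."""
    if not (0.0 <= min_fraction <= 1.0):
        raise ValidationError("min_fraction must be in [0, 1]")
    return [
        str(tr)
        for tr in matrix.values.columns
        if matrix.detection_fraction(tr) >= min_fraction
    ]


def median_split(values) -> np.ndarray:
    """Binary split at the sample median: 0 = low (<= median, ties low), 1 = high."""
    v = np.asarray(values, dtype=float)
    v_ok = v[np.isfinite(v)]
    if v_ok.size < 2:
        raise ValidationError("need at least two finite values for a median split")
    if np.unique(v_ok).size == 1:
        raise NumericalError("median split degenerate: all values identical")
    med = float(np.median(v_ok))
    out = np.where(v <= med, 0, 1)
    out = np.where(np.isfinite(v), out, -1)
    return out
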