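"""Descriptive and exact nonparametric statistics for baseline tables.

Fisher's exact test (two-sided, minimum-likelihood rule), the Wilcoxon
rank-sum test (exact enumeration for small tie-free samples, tie- and
continuity-corrected normal approximation otherwise) and Spearman rank
correlation, plus a baseline-characteristics table builder in the style of
clinical-trial Table 1s: continuous variables as mean +/- SD and
median (Q1-Q3) with a Wilcoxon p, categorical as n (%) with a Fisher p,
available N reported per variable (missing values dropped listwise per
variable, no multiplicity adjustment).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import NumericalError, ValidationError


@dataclass
class ContingencyTable2x2:
    """Counts: rows = group, columns = outcome."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        for v in (self.a, self.b, self.c, self.d):
            if v < 0 or int(v) != v:
                raise ValidationError("2x2 counts must be nonnegative integers")
        if self.a + self.b + self.c + self.d == 0:
            raise ValidationError("2x2 table is empty")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p: sum of hypergeometric probabilities of all
    same-margin tables no more likely than the observed one."""
    arr = table.as_array() if isinstance(table, ContingencyTable2x2) else np.asarray(table)
    if arr.shape != (2, 2):
        raise ValidationError("expected a 2x2 table")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        warnings.warn("empty margin in 2x2 table: p-value is 1 by convention")
        return 1.0
    return float(stats.fisher_exact(arr, alternative="two-sided")[1])


def wilcoxon_rank_sum(x, y) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact enumeration when the pooled sample has at most 20 tie-free
    observations; otherwise the normal approximation with tie correction and
    continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[np.isfinite(x)]
    y = y[np.isfinite(y)]
    if x.size < 1 or y.size < 1:
        raise ValidationError("both samples must contain at least one observation")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (pooled.size <= 20 and no_ties) else "asymptotic"
    return float(
        stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue
    )


def spearman_rho(x, y) -> float:
    """Spearman rank correlation: Pearson correlation of mid-ranks."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValidationError("need equal-length 1-d samples of size >= 3")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise NumericalError("rank correlation undefined: zero rank variance")
    return float(stats.spearmanr(x, y).statistic)


# ---------------------------------------------------------------------------
# baseline table
# ---------------------------------------------------------------------------

@dataclass
class GroupComparison:
    variable: str
    kind: str                      # "continuous" | "categorical"
    n_by_group: tuple[int, int]
    summary_by_group: tuple[str, str]
    test: str
    p_value: float
    counts: tuple[int, int] | None = None  # positives per group, categorical only


def _fmt_continuous(v: np.ndarray) -> str:
    # type-7 (linear-interpolation) quartiles, the R default
    q1, med, q3 = np.quantile(v, [0.25, 0.5, 0.75])
    return f"{v.mean():.1f} ± {v.std(ddof=1):.1f} / {med:.1f} ({q1:.1f}-{q3:.1f})"


def _is_binary(v: np.ndarray) -> bool:
    u = np.unique(v[np.isfinite(v)])
    return u.size <= 2 and np.isin(u, (0.0, 1.0)).all()


def baseline_table(
    data: pd.DataFrame,
    group_variable: str,
    variables: list[str] | None = None,
) -> list[GroupComparison]:
    """Compare every variable between the two levels of ``group_variable``."""
    if group_variable not in data.columns:
        raise ValidationError(f"group variable '{group_variable}' not in table")
    g = data[group_variable]
    levels = sorted(pd.unique(g.dropna()))
    if len(levels) != 2:
        raise ValidationError(
            f"group variable must be binary; found levels {levels}"
        )
    masks = [(g == lev).to_numpy() for lev in levels]
    if any(m.sum() == 0 for m in masks):
        raise ValidationError("a group has zero subjects")
    if variables is None:
        variables = [
            c for c in data.columns
            if c not in (group_variable, "subject_id", "arm")
            and pd.api.types.is_numeric_dtype(data[c])
        ]
    rows: list[GroupComparison] = []
    for var in variables:
        col = data[var].to_numpy(dtype=float)
        vals = [col[m] for m in masks]
        vals = [v[np.isfinite(v)] for v in vals]
        ns = (len(vals[0]), len(vals[1]))
        if min(ns) == 0:
            continue  # nothing observed in a group: no comparison possible
        if _is_binary(col):
            pos = (int(vals[0].sum()), int(vals[1].sum()))
            tab = ContingencyTable2x2(
                pos[0], ns[0] - pos[0], pos[1], ns[1] - pos[1]
            )
            p = fisher_exact_2x2(tab)
            summ = tuple(
                f"{k} ({100.0 * k / n:.1f}%)" for k, n in zip(pos, ns)
            )
            rows.append(
                GroupComparison(var, "categorical", ns, summ, "fisher", p, pos)
            )
        else:
            p = wilcoxon_rank_sum(vals[0], vals[1])
            summ = tuple(_fmt_continuous(v) for v in vals)
            rows.append(
                GroupComparison(var, "continuous", ns, summ, "wilcoxon", p)
            )
    return rows


def baseline_table_frame(rows: list[GroupComparison]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "variable": [r.variable for r in rows],
            "kind": [r.kind for r in rows],
            "n_group0": [r.n_by_group[0] for r in rows],
            "n_group1": [r.n_by_group[1] for r in rows],
            "group0": [r.summary_by_group[0] for r in rows],
            "group1": [r.summary_by_group[1] for r in rows],
            "test": [r.test for r in rows],
            "p_value": [r.p_value for r in rows],
        }
    )
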