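"""Survival CART with hazard-ratio splitting and bagged variable selection.

Each candidate split dichotomises a node at a cutoff ("<= goes left") and is
scored by the univariate Cox fit of the right-vs-left indicator within the
node: the split statistic is the Wald chi-square of the indicator's log hazard
ratio (equivalently a standardised HR; likelihood-ratio and logrank score
statistics are available as alternatives).  Raw |HR| is deliberately not the
criterion — it degenerates towards tiny extreme child nodes, whereas the Wald
statistic is monotone in |log HR| at fixed precision.

A node is split by the admissible candidate maximising the statistic, provided
its p-value — Bonferroni-adjusted for the number of admissible candidates
examined at the node — stays below ``alpha_split``.  The familywise adjustment
is what makes the stopping rule honest: without it, the best of hundreds of
correlated Wald tests splits pure-noise nodes almost surely.  Growth stops on
depth, child-size/child-event minima, or failure of that test; there is no
cost-complexity pruning.

Bagging (bootstrap resamples of the cohort, one tree per resample) estimates
per-variable selection frequencies for variable screening and an out-of-bag
integrated AUC of the ordinal node risk for honest error measurement.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .cohort import SurvivalCohort
from .cox import BinarySplitCoxScorer
from .errors import ConfigurationError, ValidationError


# ---------------------------------------------------------------------------
# parameters and result types
# ---------------------------------------------------------------------------

@dataclass
class TreeParams:
    """Growth controls.

    alpha_split is a familywise per-node significance level (see module
    docstring); max_candidates thins candidate cutoffs to an evenly spaced
    subset of the exhaustive midpoint list (None = exhaustive).
    """

    max_depth: int = 3
    min_node_n: int = 30
    min_node_events: int = 10
    alpha_split: float = 0.05
    statistic: str = "wald"            # wald | lrt | logrank
    multiplicity: str = "bonferroni"   # bonferroni | none
    max_candidates: int | None = 50

    def __post_init__(self):
        if self.statistic not in ("wald", "lrt", "logrank"):
            raise ConfigurationError(f"unknown split statistic '{self.statistic}'")
        if self.multiplicity not in ("bonferroni", "none"):
            raise ConfigurationError(f"unknown multiplicity rule '{self.multiplicity}'")
        if not (0 < self.alpha_split <= 1):
            raise ConfigurationError("alpha_split must be in (0, 1]")
        if self.max_depth < 0 or self.min_node_n < 2 or self.min_node_events < 1:
            raise ConfigurationError("invalid tree size constraints")


@dataclass
class SplitCandidate:
    variable: str
    cutoff: float
    log_hr: float = np.nan
    se: float = np.nan
    wald_z2: float = np.nan
    statistic: float = np.nan          # value of the configured statistic
    p_value: float = np.nan
    left_n: int = 0
    left_events: int = 0
    right_n: int = 0
    right_events: int = 0
    admissible: bool = True
    reason: str = ""


@dataclass
class TreeNode:
    node_id: int
    depth: int
    parent: int | None
    member_index: np.ndarray           # positional row indices into the cohort
    n: int
    events: int
    split: SplitCandidate | None = None
    left: int | None = None
    right: int | None = None
    #: adjusted p-value of the chosen split (None for terminal nodes)
    split_p_adjusted: float | None = None

    @property
    def is_terminal(self) -> bool:
        return self.split is None


# ---------------------------------------------------------------------------
# split search
# ---------------------------------------------------------------------------

def _candidate_cutoffs(values: np.ndarray, max_candidates: int | None) -> np.ndarray:
    u = np.unique(values[np.isfinite(values)])
    if u.size < 2:
        return np.empty(0)
    mids = (u[:-1] + u[1:]) / 2.0
    if max_candidates is not None and mids.size > max_candidates:
        idx = np.unique(
            np.round(np.linspace(0, mids.size - 1, max_candidates)).astype(int)
        )
        mids = mids[idx]
    return mids


def enumerate_splits(
    subset: pd.DataFrame,
    variable: str,
    params: TreeParams | None = None,
) -> list[SplitCandidate]:
    """All candidate cutoffs of one variable within a node, admissibility-marked.

    Cutoffs are midpoints between consecutive distinct observed values (a
    binary variable yields exactly one).  A candidate is admissible when both
    children satisfy the minimum size and minimum event count.
    """
    params = params or TreeParams()
    if variable not in subset.columns:
        raise ValidationError(f"variable '{variable}' not in cohort")
    v = subset[variable].to_numpy(dtype=float)
    ok = np.isfinite(v)
    ev = subset["event"].to_numpy(dtype=float)
    out = []
    for cut in _candidate_cutoffs(v, params.max_candidates):
        left = ok & (v <= cut)
        right = ok & (v > cut)
        cand = SplitCandidate(
            variable=variable,
            cutoff=float(cut),
            left_n=int(left.sum()),
            left_events=int(ev[left].sum()),
            right_n=int(right.sum()),
            right_events=int(ev[right].sum()),
        )
        if min(cand.left_n, cand.right_n) < params.min_node_n:
            cand.admissible, cand.reason = False, "child below min_node_n"
        elif min(cand.left_events, cand.right_events) < params.min_node_events:
            cand.admissible, cand.reason = False, "child below min_node_events"
        out.append(cand)
    return out


def score_split(
    subset: pd.DataFrame,
    candidate: SplitCandidate,
    params: TreeParams | None = None,
    scorer: BinarySplitCoxScorer | None = None,
) -> SplitCandidate:
    """Univariate Cox fit of the right-side indicator; fills the statistic.

    Rows with a missing value of the split variable are excluded from the fit.
    Non-convergence (separation) marks the candidate inadmissible, not fatal.
    """
    params = params or TreeParams()
    v = subset[candidate.variable].to_numpy(dtype=float)
    ok = np.isfinite(v)
    if scorer is None or not ok.all():
        scorer = BinarySplitCoxScorer(
            subset["time"].to_numpy(dtype=float)[ok],
            subset["event"].to_numpy()[ok],
        )
        x = (v[ok] > candidate.cutoff).astype(float)
    else:
        x = (v > candidate.cutoff).astype(float)
    res = scorer.score(x)
    if not res.converged:
        candidate.admissible = False
        candidate.reason = candidate.reason or "Cox fit did not converge"
        candidate.p_value = 1.0
        return candidate
    candidate.log_hr = res.beta
    candidate.se = res.se
    candidate.wald_z2 = res.wald_z2
    if params.statistic == "wald":
        stat = res.wald_z2
        p = res.p_value
    elif params.statistic == "lrt":
        stat = 2.0 * (res.loglik - res.loglik_null)
        from scipy import stats as _st

        p = float(_st.chi2.sf(max(stat, 0.0), 1))
    else:  # logrank score test
        stat = res.score_z2
        from scipy import stats as _st

        p = float(_st.chi2.sf(stat, 1))
    candidate.statistic = float(stat)
    candidate.p_value = p
    return candidate


def best_split(
    subset: pd.DataFrame,
    variables: list[str],
    params: TreeParams | None = None,
) -> tuple[SplitCandidate | None, float | None]:
    """The admissible candidate maximising the split statistic, or None.

    Returns (candidate, adjusted p).  The split is accepted only if the
    adjusted p-value is below ``alpha_split``.  Ties on the statistic break by
    smaller p, then variable name, then smaller cutoff (all deterministic
    under row reordering).
    """
    params = params or TreeParams()
    complete = np.isfinite(
        subset[variables].to_numpy(dtype=float)
    ).all(axis=1) if variables else np.ones(len(subset), dtype=bool)
    scorer_full = None
    if complete.all():
        scorer_full = BinarySplitCoxScorer(
            subset["time"].to_numpy(dtype=float), subset["event"].to_numpy()
        )
    best: SplitCandidate | None = None
    best_key = None
    n_tested = 0
    for var in sorted(variables):
        for cand in enumerate_splits(subset, var, params):
            if not cand.admissible:
                continue
            cand = score_split(subset, cand, params, scorer=scorer_full)
            if not cand.admissible:
                continue
            n_tested += 1
            # maximise the statistic; break ties by smaller p, then variable
            # name, then smaller cutoff
            key = (-cand.statistic, cand.p_value, cand.variable, cand.cutoff)
            if best_key is None or key < best_key:
                best, best_key = cand, key
    if best is None:
        return None, None
    if params.multiplicity == "bonferroni":
        p_adj = min(1.0, best.p_value * n_tested)
    else:
        p_adj = best.p_value
    if p_adj >= params.alpha_split:
        return None, p_adj
    return best, p_adj


# ---------------------------------------------------------------------------
# the tree
# ---------------------------------------------------------------------------

@dataclass
class HazardTree:
    nodes: dict[int, TreeNode]
    variables: list[str]
    params: TreeParams
    n: int
    seed: int | None = None
    warnings: list[str] = field(default_factory=list)

    def terminal_nodes(self) -> list[TreeNode]:
        return [nd for nd in self.nodes.values() if nd.is_terminal]

    @property
    def n_terminal(self) -> int:
        return len(self.terminal_nodes())

    @property
    def depth(self) -> int:
        return max(nd.depth for nd in self.nodes.values())

    def split_variables(self) -> list[str]:
        return sorted(
            {nd.split.variable for nd in self.nodes.values() if not nd.is_terminal}
        )

    # -- prediction -------------------------------------------------------
    def assign_frame(self, data: pd.DataFrame) -> np.ndarray:
        """Terminal node id per row; -1 where a split variable is missing."""
        n = len(data)
        out = np.full(n, -1, dtype=int)
        at = {1: np.arange(n)}
        order = sorted(self.nodes)
        for nid in order:
            nd = self.nodes[nid]
            idx = at.pop(nid, np.empty(0, dtype=int))
            if idx.size == 0:
                continue
            if nd.is_terminal:
                out[idx] = nid
                continue
            v = data[nd.split.variable].to_numpy(dtype=float)[idx]
            ok = np.isfinite(v)
            left = idx[ok & (v <= nd.split.cutoff)]
            right = idx[ok & (v > nd.split.cutoff)]
            at[nd.left] = np.concatenate([at.get(nd.left, np.empty(0, int)), left])
            at[nd.right] = np.concatenate([at.get(nd.right, np.empty(0, int)), right])
        return out

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        nodes = {}
        for nid, nd in self.nodes.items():
            d = {
                "node_id": nd.node_id,
                "depth": nd.depth,
                "parent": nd.parent,
                "n": nd.n,
                "events": nd.events,
                "left": nd.left,
                "right": nd.right,
                "split_p_adjusted": nd.split_p_adjusted,
                "split": None if nd.split is None else asdict(nd.split),
            }
            nodes[str(nid)] = d
        return {
            "variables": self.variables,
            "params": asdict(self.params),
            "n": self.n,
            "seed": self.seed,
            "warnings": self.warnings,
            "nodes": nodes,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "HazardTree":
        nodes = {}
        for k, nd in d["nodes"].items():
            split = None
            if nd["split"] is not None:
                split = SplitCandidate(**nd["split"])
            nodes[int(k)] = TreeNode(
                node_id=nd["node_id"],
                depth=nd["depth"],
                parent=nd["parent"],
                member_index=np.empty(0, dtype=int),
                n=nd["n"],
                events=nd["events"],
                split=split,
                left=nd["left"],
                right=nd["right"],
                split_p_adjusted=nd["split_p_adjusted"],
            )
        return cls(
            nodes=nodes,
            variables=d["variables"],
            params=TreeParams(**d["params"]),
            n=d["n"],
            seed=d.get("seed"),
            warnings=d.get("warnings", []),
        )

    @classmethod
    def from_json(cls, path) -> "HazardTree":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def render(self) -> str:
        """Human-readable indented rendering."""
        lines: list[str] = []

        def walk(nid: int, indent: int, label: str):
            nd = self.nodes[nid]
            pad = "  " * indent
            if nd.is_terminal:
                lines.append(
                    f"{pad}{label}node {nid} [terminal] n={nd.n} events={nd.events}"
                )
            else:
                s = nd.split
                lines.append(
                    f"{pad}{label}node {nid} n={nd.n} events={nd.events} | "
                    f"split {s.variable} <= {s.cutoff:.4g} "
                    f"(HR={np.exp(s.log_hr):.3g}, p_adj={nd.split_p_adjusted:.2g})"
                )
                walk(nd.left, indent + 1, "L: ")
                walk(nd.right, indent + 1, "R: ")

        walk(1, 0, "")
        return "\n".join(lines)


def grow_tree(
    cohort: SurvivalCohort | pd.DataFrame,
    variables: list[str],
    params: TreeParams | None = None,
    seed: int | None = None,
) -> HazardTree:
    """Grow the hazard-ratio CART by recursive best_split, breadth-first ids."""
    import warnings as _warnings

    params = params or TreeParams()
    df = cohort.data if isinstance(cohort, SurvivalCohort) else cohort
    df = df.reset_index(drop=True)
    if len(df) == 0:
        raise ValidationError("empty cohort")
    for v in variables:
        if v not in df.columns:
            raise ConfigurationError(f"tree variable '{v}' not in cohort")
    warns: list[str] = []
    if len(df) < 2 * params.min_node_n:
        msg = "cohort smaller than twice min_node_n: returning a root-only tree"
        _warnings.warn(msg)
        warns.append(msg)
        root = TreeNode(
            1, 0, None, np.arange(len(df)), len(df), int(df["event"].sum())
        )
        return HazardTree({1: root}, list(variables), params, len(df), seed, warns)

    ev = df["event"].to_numpy(dtype=float)
    nodes: dict[int, TreeNode] = {}
    root = TreeNode(1, 0, None, np.arange(len(df)), len(df), int(ev.sum()))
    nodes[1] = root
    queue = [1]
    next_id = 2
    while queue:
        nid = queue.pop(0)
        nd = nodes[nid]
        if nd.depth >= params.max_depth:
            continue
        if nd.n < 2 * params.min_node_n or nd.events < 2 * params.min_node_events:
            continue
        sub = df.iloc[nd.member_index]
        cand, p_adj = best_split(sub, variables, params)
        if cand is None:
            continue
        v = sub[cand.variable].to_numpy(dtype=float)
        ok = np.isfinite(v)
        if not ok.all():
            warns.append(
                f"node {nid}: {int((~ok).sum())} subjects missing "
                f"'{cand.variable}' excluded from children"
            )
        left_idx = nd.member_index[ok & (v <= cand.cutoff)]
        right_idx = nd.member_index[ok & (v > cand.cutoff)]
        nd.split = cand
        nd.split_p_adjusted = p_adj
        nd.left, nd.right = next_id, next_id + 1
        nodes[next_id] = TreeNode(
            next_id, nd.depth + 1, nid, left_idx, len(left_idx),
            int(ev[left_idx].sum()),
        )
        nodes[next_id + 1] = TreeNode(
            next_id + 1, nd.depth + 1, nid, right_idx, len(right_idx),
            int(ev[right_idx].sum()),
        )
        queue += [next_id, next_id + 1]
        next_id += 2
    return HazardTree(nodes, list(variables), params, len(df), seed, warns)


def assign_node(tree: HazardTree, covariate_row) -> int:
    """Route one covariate row (mapping) to its terminal node id.

    Raises :class:`ValidationError` if a split variable is absent (no
    surrogate splits are attempted).
    """
    nd = tree.nodes[1]
    while not nd.is_terminal:
        v = nd.split.variable
        val = covariate_row.get(v) if hasattr(covariate_row, "get") else covariate_row[v]
        if val is None or (isinstance(val, float) and np.isnan(val)):
            raise ValidationError(
                f"cannot assign: split variable '{v}' missing from row"
            )
        nd = tree.nodes[nd.left if val <= nd.split.cutoff else nd.right]
    return nd.node_id


def tree_from_nested(nested: dict, variables: list[str] | None = None) -> HazardTree:
    """Build a HazardTree from a nested split dict (planted-truth format).

    The dict is either a leaf (no 'variable' key) or
    ``{"variable": v, "cutoff": c, "left": ..., "right": ...}``; '<= goes
    left'.  Node statistics are left empty — the result is meant for routing
    and evaluation, e.g. scoring recovery against a known simulation truth.
    """
    nodes: dict[int, TreeNode] = {}
    queue = [(1, 0, None, nested)]
    next_id = 2
    while queue:
        nid, depth, parent, sub = queue.pop(0)
        nd = TreeNode(nid, depth, parent, np.empty(0, dtype=int), 0, 0)
        if "variable" in sub:
            nd.split = SplitCandidate(variable=sub["variable"], cutoff=float(sub["cutoff"]))
            nd.left, nd.right = next_id, next_id + 1
            queue.append((next_id, depth + 1, nid, sub["left"]))
            queue.append((next_id + 1, depth + 1, nid, sub["right"]))
            next_id += 2
        nodes[nid] = nd
    if variables is None:
        variables = sorted(
            {nd.split.variable for nd in nodes.values() if nd.split is not None}
        )
    depth = max(nd.depth for nd in nodes.values())
    return HazardTree(nodes, variables, TreeParams(max_depth=max(depth, 1)), 0)


# ---------------------------------------------------------------------------
# bagging
# ---------------------------------------------------------------------------

@dataclass
class BaggingReport:
    B: int
    selection_frequency: dict[str, float]
    retained: list[str]
    oob_iauc_mean: float
    oob_iauc_sd: float
    n_oob_evaluated: int
    retention_threshold: float
    seed: int

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)


def bagging_select(
    cohort: SurvivalCohort | pd.DataFrame,
    variables: list[str],
    B: int = 1000,
    params: TreeParams | None = None,
    seed: int = 0,
    retention_threshold: float = 0.5,
    iauc_window: tuple[float, float] = (0.25, 5.0),
) -> BaggingReport:
    """Bootstrap-aggregated variable selection and out-of-bag error.

    For each of ``B`` resamples (with replacement, size n) a tree is grown;
    a variable is 'selected' when it appears in any split of that tree.  The
    out-of-bag subjects are routed through the tree and the integrated
    cumulative/dynamic AUC of their ordinal node risk (node rank by training
    incidence rate) measures honest discrimination; the report carries its
    mean +/- SD over iterations.
    """
    from .risk_metrics import iauc  # local import to avoid a module cycle

    if B < 1:
        raise ConfigurationError("B must be >= 1")
    params = params or TreeParams()
    df = (cohort.data if isinstance(cohort, SurvivalCohort) else cohort).reset_index(
        drop=True
    )
    n = len(df)
    rng = np.random.default_rng(seed)
    counts = {v: 0 for v in variables}
    oob_iaucs: list[float] = []
    for _ in range(B):
        idx = rng.integers(0, n, n)
        boot = df.iloc[idx].reset_index(drop=True)
        tree = grow_tree(boot, variables, params)
        for v in tree.split_variables():
            counts[v] += 1
        oob_mask = np.ones(n, dtype=bool)
        oob_mask[np.unique(idx)] = False
        if oob_mask.sum() < 10:
            continue
        # ordinal node risk learned on the resample
        assignments = tree.assign_frame(boot)
        t_b = boot["time"].to_numpy(dtype=float)
        e_b = boot["event"].to_numpy(dtype=float)
        rates = {}
        for nd in tree.terminal_nodes():
            m = assignments == nd.node_id
            py = t_b[m].sum()
            rates[nd.node_id] = e_b[m].sum() / py if py > 0 else 0.0
        order = sorted(rates, key=lambda k: rates[k])
        rank_of = {nid: r for r, nid in enumerate(order)}
        oob = df.loc[oob_mask]
        oob_nodes = tree.assign_frame(oob.reset_index(drop=True))
        routed = oob_nodes >= 0
        if routed.sum() < 10:
            continue
        marker = np.array([rank_of[nid] for nid in oob_nodes[routed]], dtype=float)
        try:
            res = iauc(
                marker,
                oob["time"].to_numpy(dtype=float)[routed],
                oob["event"].to_numpy()[routed],
                t0=iauc_window[0],
                t1=iauc_window[1],
                n_boot=0,
            )
            oob_iaucs.append(res.iauc)
        except Exception:
            continue
    freqs = {v: counts[v] / B for v in variables}
    retained = [v for v in variables if freqs[v] >= retention_threshold]
    arr = np.array(oob_iaucs, dtype=float)
    return BaggingReport(
        B=int(B),
        selection_frequency=freqs,
        retained=retained,
        oob_iauc_mean=float(arr.mean()) if arr.size else float("nan"),
        oob_iauc_sd=float(arr.std(ddof=1)) if arr.size > 1 else float("nan"),
        n_oob_evaluated=int(arr.size),
        retention_threshold=float(retention_threshold),
        seed=int(seed),
    )
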