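"""Node-level and tree-level risk quantification.

Absolute risk per terminal node is summarised by the incidence rate
IR_i = 100 * events_i / person-years_i; relative risk by the hazard ratio of
each node against the lowest-incidence (reference) node from a single Cox fit
on node-indicator covariates.  Tree-level dispersion of risk is the
incidence-rate variation index

    IRV = (1/N) * sum_i  n_i * |IR_i - IR|

with IR the pooled population rate, and discrimination of the ordinal node
risk is the integrated cumulative/dynamic AUC over a follow-up window
(default 3 months to 5 years): cases at time t are subjects with an event by
t, controls those still event-free after t, weighted by the inverse of the
censoring-distribution Kaplan-Meier (a naive unweighted estimator is kept for
cross-checks).  AUC(t) values on the event-time grid are averaged with
weights proportional to the Kaplan-Meier event mass in the window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import SurvivalCohort
from .cox import fit_cox
from .errors import NumericalError, ValidationError
from .tree import HazardTree


def _time_event(cohort, event=None):
    if isinstance(cohort, SurvivalCohort):
        return cohort.time, cohort.event.astype(float)
    if isinstance(cohort, pd.DataFrame):
        return (
            cohort["time"].to_numpy(dtype=float),
            cohort["event"].to_numpy(dtype=float),
        )
    return np.asarray(cohort, dtype=float), np.asarray(event, dtype=float)


# ---------------------------------------------------------------------------
# incidence rates and the IRV index
# ---------------------------------------------------------------------------

def incidence_rate(events: float, person_years: float) -> float:
    """Events per 100 patient-years of observed follow-up."""
    if person_years <= 0:
        raise NumericalError("incidence rate undefined: person_years must be > 0")
    return 100.0 * events / person_years


@dataclass
class NodeSummary:
    node_id: int
    n: int
    events: int
    person_years: float
    incidence_rate: float
    hr: float = 1.0
    hr_lo: float = np.nan
    hr_hi: float = np.nan
    rank: int = 1                 # ordinal risk, 1 = lowest incidence rate
    is_reference: bool = False
    hr_estimable: bool = True


def node_summaries(tree: HazardTree, cohort) -> list[NodeSummary]:
    """Per-terminal-node IR and HR versus the lowest-incidence reference node.

    HRs come from one Cox fit on terminal-node indicator covariates (reference
    omitted).  Nodes without events keep IR = 0 and are flagged non-estimable
    for the HR (their subjects are excluded from that fit).
    """
    df = (cohort.data if isinstance(cohort, SurvivalCohort) else cohort).reset_index(
        drop=True
    )
    t, e = _time_event(df)
    assigned = tree.assign_frame(df)
    if (assigned < 0).any():
        raise ValidationError(
            f"{int((assigned < 0).sum())} subjects could not be assigned to a "
            "terminal node (missing split variables)"
        )
    summaries: list[NodeSummary] = []
    for nd in tree.terminal_nodes():
        m = assigned == nd.node_id
        py = float(t[m].sum())
        ev = int(e[m].sum())
        summaries.append(
            NodeSummary(
                node_id=nd.node_id,
                n=int(m.sum()),
                events=ev,
                person_years=py,
                incidence_rate=incidence_rate(ev, py) if py > 0 else 0.0,
            )
        )
    summaries.sort(key=lambda s: (s.incidence_rate, s.node_id))
    for r, s in enumerate(summaries, start=1):
        s.rank = r
    summaries[0].is_reference = True
    ref_id = summaries[0].node_id

    estimable = [s for s in summaries if s.events > 0 or s.node_id == ref_id]
    dropped = {s.node_id for s in summaries} - {s.node_id for s in estimable}
    for s in summaries:
        if s.node_id in dropped:
            s.hr_estimable = False
            s.hr = np.nan
    if len(estimable) > 1:
        keep = np.isin(assigned, [s.node_id for s in estimable])
        sub = pd.DataFrame({"time": t[keep], "event": e[keep]})
        names = []
        for s in estimable:
            if s.node_id == ref_id:
                continue
            name = f"node_{s.node_id}"
            sub[name] = (assigned[keep] == s.node_id).astype(float)
            names.append((s.node_id, name))
        fit = fit_cox(sub, [nm for _, nm in names])
        ci = fit.confidence_intervals()
        for j, (nid, _) in enumerate(names):
            s = next(x for x in summaries if x.node_id == nid)
            s.hr = float(np.exp(fit.coef[j]))
            s.hr_lo, s.hr_hi = float(ci[j, 0]), float(ci[j, 1])
            if not fit.converged:
                s.hr_estimable = False
    summaries.sort(key=lambda s: s.node_id)
    return summaries


def irv(
    summaries: list[NodeSummary],
    overall_ir: float | None = None,
    N: int | None = None,
) -> float:
    """Incidence-rate variation index, in events per 100 patient-years.

    The overall IR defaults to the pooled events / person-years of all nodes
    (the population rate), not the n-weighted mean of node IRs.
    """
    n_total = sum(s.n for s in summaries)
    if N is None:
        N = n_total
    if N == 0:
        raise ValidationError("IRV undefined for an empty population")
    if N != n_total:
        raise ValidationError("node sizes do not sum to N")
    if overall_ir is None:
        overall_ir = incidence_rate(
            sum(s.events for s in summaries), sum(s.person_years for s in summaries)
        )
    return float(
        sum(s.n * abs(s.incidence_rate - overall_ir) for s in summaries) / N
    )


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

@dataclass
class KMCurve:
    times: np.ndarray             # unique event times, ascending
    survival: np.ndarray          # S(t) just after each time
    at_risk: np.ndarray
    n_events: np.ndarray
    censor_times: np.ndarray

    def survival_at(self, t) -> np.ndarray:
        """Right-continuous step evaluation of S."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        if self.times.size == 0:
            out = np.ones_like(t)
        else:
            idx = np.searchsorted(self.times, t, side="right") - 1
            out = np.where(idx < 0, 1.0, self.survival[np.clip(idx, 0, None)])
        return out if out.size > 1 else float(out[0])

    def event_mass(self) -> np.ndarray:
        """KM jump sizes S(t-) - S(t) at each event time."""
        prev = np.concatenate([[1.0], self.survival[:-1]])
        return prev - self.survival


def km_curve(time, event) -> KMCurve:
    """Product-limit estimator (events precede censorings at tied times)."""
    from lifelines import KaplanMeierFitter

    t, e = _time_event(time, event)
    if t.size == 0:
        raise ValidationError("empty sample")
    kmf = KaplanMeierFitter().fit(t, e)
    tab = kmf.event_table
    evt = tab[tab["observed"] > 0]
    times = evt.index.to_numpy(dtype=float)
    surv = kmf.survival_function_at_times(times).to_numpy(dtype=float)
    return KMCurve(
        times=times,
        survival=surv,
        at_risk=evt["at_risk"].to_numpy(dtype=int),
        n_events=evt["observed"].to_numpy(dtype=int),
        censor_times=np.sort(t[e == 0]),
    )


def _censoring_survival(time, event):
    """Kaplan-Meier of the censoring distribution (roles reversed).

    Returns an evaluator G(t, side): side='left' gives the left limit G(t-)
    used to weight cases at their own event time.
    """
    t, e = _time_event(time, event)
    order = np.argsort(t, kind="stable")
    ts, cs = t[order], 1.0 - e[order]
    uniq, start = np.unique(ts, return_index=True)
    n = ts.size
    at_risk = n - start
    n_cens = np.add.reduceat(cs, start)
    G = np.cumprod(1.0 - n_cens / at_risk)

    def evaluate(x, side="right"):
        x = np.atleast_1d(np.asarray(x, dtype=float))
        if side == "left":
            idx = np.searchsorted(uniq, x, side="left") - 1
        else:
            idx = np.searchsorted(uniq, x, side="right") - 1
        out = np.where(idx < 0, 1.0, G[np.clip(idx, 0, None)])
        return out

    return evaluate


# ---------------------------------------------------------------------------
# cumulative/dynamic AUC and its integral
# ---------------------------------------------------------------------------

def cd_auc(marker, time, event=None, t: float = None, ipcw: bool = True) -> float:
    """Cumulative/dynamic AUC at horizon ``t``.

    Cases: event time <= t; dynamic controls: observed time > t.  With
    ``ipcw`` (default) cases are weighted 1/G(T_i-) and controls 1/G(t),
    where G is the censoring-distribution Kaplan-Meier; tied marker values
    contribute one half.
    """
    tt, ee = _time_event(time, event)
    marker = np.asarray(marker, dtype=float)
    if marker.shape != tt.shape:
        raise ValidationError("one marker value per subject required")
    if t is None:
        raise ValidationError("a horizon t is required")
    cases = (tt <= t) & (ee == 1)
    controls = tt > t
    if cases.sum() == 0 or controls.sum() == 0:
        raise NumericalError(f"AUC({t}) undefined: no cases or no controls")
    if ipcw:
        G = _censoring_survival(tt, ee)
        w_case = 1.0 / G(tt[cases], side="left")
        w_ctrl = np.full(int(controls.sum()), 1.0 / float(G(np.array([t]))[0]))
    else:
        w_case = np.ones(int(cases.sum()))
        w_ctrl = np.ones(int(controls.sum()))
    mc = marker[cases][:, None]
    mk = marker[controls][None, :]
    wins = (mc > mk) + 0.5 * (mc == mk)
    W = w_case[:, None] * w_ctrl[None, :]
    return float((wins * W).sum() / W.sum())


@dataclass
class IaucResult:
    iauc: float
    ci_low: float
    ci_high: float
    t0: float
    t1: float
    auc_times: np.ndarray = field(default_factory=lambda: np.zeros(0))
    auc_values: np.ndarray = field(default_factory=lambda: np.zeros(0))
    weights: np.ndarray = field(default_factory=lambda: np.zeros(0))
    n_boot: int = 0
    seed: int = 0


def _iauc_point(marker, tt, ee, t0, t1, ipcw, weighting):
    km = km_curve(tt, ee)
    mask = (km.times >= t0) & (km.times <= t1)
    grid = km.times[mask]
    if grid.size == 0:
        raise NumericalError("no events inside the integration window")
    aucs, weights, used = [], [], []
    mass = km.event_mass()[mask]
    for tau, m in zip(grid, mass):
        try:
            a = cd_auc(marker, tt, ee, t=float(tau), ipcw=ipcw)
        except NumericalError:
            continue
        aucs.append(a)
        weights.append(m)
        used.append(tau)
    if not aucs:
        raise NumericalError("AUC(t) undefined everywhere in the window")
    aucs = np.array(aucs)
    used = np.array(used)
    if weighting == "km":
        w = np.array(weights, dtype=float)
        if w.sum() == 0:
            w = np.ones_like(w)
        w = w / w.sum()
        val = float((w * aucs).sum())
    elif weighting == "uniform":
        if used.size == 1:
            w = np.ones(1)
            val = float(aucs[0])
        else:
            val = float(np.trapezoid(aucs, used) / (used[-1] - used[0]))
            w = np.full(used.size, 1.0 / used.size)
    else:
        raise ValidationError(f"unknown weighting '{weighting}'")
    return val, used, aucs, w


def iauc(
    marker,
    time,
    event=None,
    t0: float = 0.25,
    t1: float = 5.0,
    ipcw: bool = True,
    weighting: str = "km",
    n_boot: int = 200,
    seed: int = 0,
) -> IaucResult:
    """Integrated cumulative/dynamic AUC over [t0, t1] with bootstrap 95% CI.

    AUC(t) is evaluated on the event-time grid inside the window and averaged
    with weights proportional to the Kaplan-Meier event mass (``weighting=
    'uniform'`` integrates by trapezoid in t instead).  ``n_boot=0`` skips
    the subject-level bootstrap CI.
    """
    tt, ee = _time_event(time, event)
    marker = np.asarray(marker, dtype=float)
    if not (0 <= t0 < t1):
        raise ValidationError("need 0 <= t0 < t1")
    val, used, aucs, w = _iauc_point(marker, tt, ee, t0, t1, ipcw, weighting)
    lo = hi = float("nan")
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        n = tt.size
        boots = []
        for _ in range(n_boot):
            idx = rng.integers(0, n, n)
            try:
                b, *_ = _iauc_point(marker[idx], tt[idx], ee[idx], t0, t1, ipcw, weighting)
                boots.append(b)
            except NumericalError:
                continue
        if boots:
            lo, hi = np.percentile(boots, [2.5, 97.5])
    return IaucResult(
        iauc=val, ci_low=float(lo), ci_high=float(hi), t0=t0, t1=t1,
        auc_times=used, auc_values=aucs, weights=w, n_boot=n_boot, seed=seed,
    )


# ---------------------------------------------------------------------------
# risk bands
# ---------------------------------------------------------------------------

BAND_NAMES = ("low", "intermediate", "high", "very high")


@dataclass
class RiskBanding:
    assignment: dict[int, str]
    edges: tuple[float, ...]
    band_names: tuple[str, ...]


def risk_bands(
    summaries: list[NodeSummary], band_edges: tuple[float, ...] = (2.0, 5.0, 10.0)
) -> RiskBanding:
    """Map terminal nodes to ordered risk bands by their HR vs the reference.

    Default edges (2, 5, 10) give four bands; the reference node is always in
    the lowest band.  Band assignment is monotone in HR.
    """
    edges = tuple(sorted(band_edges))
    if list(edges) != list(band_edges):
        raise ValidationError("band edges must be increasing")
    names = (
        BAND_NAMES
        if len(edges) == 3
        else tuple(f"band_{i + 1}" for i in range(len(edges) + 1))
    )
    assignment: dict[int, str] = {}
    for s in summaries:
        if s.is_reference:
            assignment[s.node_id] = names[0]
            continue
        if not s.hr_estimable or not np.isfinite(s.hr):
            assignment[s.node_id] = "unclassified"
            continue
        k = int(np.searchsorted(np.asarray(edges), s.hr, side="right"))
        assignment[s.node_id] = names[k]
    return RiskBanding(assignment=assignment, edges=edges, band_names=names)


# ---------------------------------------------------------------------------
# one-call tree evaluation
# ---------------------------------------------------------------------------

@dataclass
class TreeMetrics:
    N: int
    f: int
    overall_ir: float
    irv: float
    iauc: IaucResult
    summaries: list[NodeSummary]
    banding: RiskBanding


def tree_metrics(
    tree: HazardTree,
    cohort,
    t0: float = 0.25,
    t1: float = 5.0,
    ipcw: bool = True,
    n_boot: int = 200,
    seed: int = 0,
    band_edges: tuple[float, ...] = (2.0, 5.0, 10.0),
) -> TreeMetrics:
    """Node summaries, IRV, ordinal-risk iAUC and risk bands in one pass."""
    df = (cohort.data if isinstance(cohort, SurvivalCohort) else cohort).reset_index(
        drop=True
    )
    t, e = _time_event(df)
    summaries = node_summaries(tree, df)
    overall = incidence_rate(int(e.sum()), float(t.sum()))
    assigned = tree.assign_frame(df)
    rank_of = {s.node_id: s.rank for s in summaries}
    marker = np.array([rank_of[nid] for nid in assigned], dtype=float)
    if len(set(rank_of.values())) > 1:
        ia = iauc(marker, t, e, t0=t0, t1=t1, ipcw=ipcw, n_boot=n_boot, seed=seed)
    else:
        ia = IaucResult(float("nan"), float("nan"), float("nan"), t0, t1)
    return TreeMetrics(
        N=len(df),
        f=len(summaries),
        overall_ir=overall,
        irv=irv(summaries, overall),
        iauc=ia,
        summaries=summaries,
        banding=risk_bands(summaries, band_edges),
    )


def node_summary_frame(summaries: list[NodeSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "node_id": [s.node_id for s in summaries],
            "n": [s.n for s in summaries],
            "events": [s.events for s in summaries],
            "person_years": [s.person_years for s in summaries],
            "incidence_rate": [s.incidence_rate for s in summaries],
            "HR": [s.hr for s in summaries],
            "HR_lo95": [s.hr_lo for s in summaries],
            "HR_hi95": [s.hr_hi for s in summaries],
            "rank": [s.rank for s in summaries],
            "reference": [s.is_reference for s in summaries],
        }
    )
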