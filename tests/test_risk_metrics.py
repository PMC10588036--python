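"""Incidence rates, IRV, Kaplan-Meier, time-dependent AUC and risk bands."""

import numpy as np
import pandas as pd
import pytest

from mirisk import (
    CohortSpec,
    CovariateSpec,
    NumericalError,
    SimulationTruth,
    cd_auc,
    generate_cohort,
    iauc,
    incidence_rate,
    irv,
    km_curve,
    node_summaries,
    risk_bands,
    tree_from_nested,
    tree_metrics,
)
from mirisk.risk_metrics import NodeSummary

from conftest import make_exponential_cohort


def four_leaf_setup(n=4000, seed=7):
    """Planted 4-leaf truth with hazards 0.05/0.15/0.35/0.70 per year."""
    spec = CohortSpec(
        n_subjects=n,
        covariates=[
            CovariateSpec("x1", "normal", {"mean": 0.0, "sd": 1.0}),
            CovariateSpec("x2", "normal", {"mean": 0.0, "sd": 1.0}),
        ],
    )
    nested = {
        "variable": "x1", "cutoff": 0.0,
        "left": {
            "variable": "x2", "cutoff": 0.0,
            "left": {"leaf": "a", "hazard": 0.05},
            "right": {"leaf": "b", "hazard": 0.15},
        },
        "right": {
            "variable": "x2", "cutoff": 0.0,
            "left": {"leaf": "c", "hazard": 0.35},
            "right": {"leaf": "d", "hazard": 0.70},
        },
    }
    truth = SimulationTruth(nested, admin_censoring=(0.5, 5.5), dropout_rate=0.02)
    cohort, _ = generate_cohort(spec, truth, seed)
    return cohort, tree_from_nested(nested)


class TestIncidenceRate:
    def test_values(self):
        assert incidence_rate(5, 250.0) == 2.0
        assert incidence_rate(0, 100.0) == 0.0
        with pytest.raises(NumericalError):
            incidence_rate(3, 0.0)

    def test_exponential_simulation_matches_hazard(self):
        """Hazard 0.1/y: IR ~ 10 per 100 py whatever the censoring."""
        df = make_exponential_cohort(n=5000, hazard=0.1, beta=0.0, seed=12)
        ir = incidence_rate(df["event"].sum(), df["time"].sum())
        se = 100 * np.sqrt(df["event"].sum()) / df["time"].sum()
        assert abs(ir - 10.0) < 3 * se


class TestNodeSummaries:
    def test_single_node_tree(self, small_cohort):
        tree = tree_from_nested({"leaf": "root", "hazard": 0.3})
        (summ,) = node_summaries(tree, small_cohort)
        assert summ.hr == 1.0 and summ.rank == 1 and summ.is_reference

    def test_conservation(self):
        cohort, tree = four_leaf_setup(n=800, seed=3)
        summs = node_summaries(tree, cohort)
        assert sum(s.n for s in summs) == len(cohort)
        assert sum(s.events for s in summs) == cohort.n_events
        assert sum(s.person_years for s in summs) == pytest.approx(cohort.person_years)

    def test_planted_hazard_ratio_recovery(self):
        """Estimated node HRs track the planted ratios 3/7/14 within 25%."""
        cohort, tree = four_leaf_setup(n=4000, seed=7)
        summs = sorted(node_summaries(tree, cohort), key=lambda s: s.incidence_rate)
        planted = np.array([1.0, 3.0, 7.0, 14.0])
        est = np.array([s.hr for s in summs])
        assert np.all(np.abs(np.log(est[1:] / planted[1:])) <= np.log(1.25))

    def test_ordinal_rank_follows_ir(self):
        cohort, tree = four_leaf_setup(n=1000, seed=9)
        summs = node_summaries(tree, cohort)
        by_rank = sorted(summs, key=lambda s: s.rank)
        irs = [s.incidence_rate for s in by_rank]
        assert irs == sorted(irs)


class TestIRV:
    @staticmethod
    def _summ(node_id, n, events, py):
        return NodeSummary(node_id, n, events, py, incidence_rate(events, py))

    def test_worked_two_node_example(self):
        """Two nodes of 50: (5 ev/250 py) and (15 ev/250 py) -> IRV = 2.0."""
        summs = [self._summ(1, 50, 5, 250.0), self._summ(2, 50, 15, 250.0)]
        assert irv(summs, overall_ir=4.0, N=100) == pytest.approx(2.0)

    def test_homogeneous_zero(self):
        summs = [self._summ(1, 60, 12, 300.0), self._summ(2, 40, 8, 200.0)]
        assert irv(summs) == pytest.approx(0.0)

    def test_relabel_invariance(self):
        a = [self._summ(1, 50, 5, 250.0), self._summ(2, 50, 15, 250.0)]
        b = [self._summ(9, 50, 15, 250.0), self._summ(4, 50, 5, 250.0)]
        assert irv(a) == pytest.approx(irv(b))

    def test_strictly_increases_when_risk_concentrates(self):
        base = [self._summ(1, 50, 10, 250.0), self._summ(2, 50, 10, 250.0)]
        moved = [self._summ(1, 50, 5, 250.0), self._summ(2, 50, 15, 250.0)]
        assert irv(moved) > irv(base)


class TestKaplanMeier:
    def test_no_censoring_equals_empirical(self):
        km = km_curve(np.array([1.0, 2.0, 3.0, 4.0]), np.ones(4))
        assert np.allclose(km.survival, [0.75, 0.5, 0.25, 0.0])

    def test_all_censored_flat(self):
        km = km_curve(np.array([1.0, 2.0, 3.0]), np.zeros(3))
        assert km.times.size == 0
        assert float(km.survival_at(2.5)) == 1.0

    def test_interleaved_censoring_hand_computed(self):
        """Events at 1,3 and a censoring at 2: S = 3/4, then 3/4 * 1/2."""
        t = np.array([1.0, 2.0, 3.0, 4.0])
        e = np.array([1, 0, 1, 0])
        km = km_curve(t, e)
        assert np.allclose(km.times, [1.0, 3.0])
        assert np.allclose(km.survival, [0.75, 0.375])
        assert float(km.survival_at(2.9)) == pytest.approx(0.75)

    def test_event_mass_sums_to_one_minus_tail(self):
        df = make_exponential_cohort(n=500, seed=13)
        km = km_curve(df["time"], df["event"])
        assert km.event_mass().sum() == pytest.approx(1.0 - km.survival[-1])


class TestCdAuc:
    def test_perfect_marker_no_censoring(self):
        rng = np.random.default_rng(1)
        t = rng.exponential(2.0, 100) + 0.01
        e = np.ones(100)
        assert cd_auc(-t, t, e, t=float(np.median(t))) == 1.0

    def test_null_marker_near_half(self):
        hits = 0
        for s in range(30):
            df = make_exponential_cohort(n=1000, hazard=0.3, seed=500 + s)
            marker = np.random.default_rng(s).normal(size=len(df))
            a = cd_auc(marker, df["time"], df["event"], t=2.0)
            hits += 0.45 <= a <= 0.55
        assert hits / 30 >= 0.9

    def test_no_censoring_equals_pair_enumeration(self):
        rng = np.random.default_rng(2)
        n = 150
        t = rng.exponential(2.0, n) + 0.01
        e = np.ones(n)
        m = (-t + rng.normal(scale=1.0, size=n)).round(1)  # ties included
        for th in (1.0, 2.0):
            cases = t <= th
            controls = t > th
            num = den = 0.0
            for mi in m[cases]:
                for mj in m[controls]:
                    den += 1
                    num += 1.0 if mi > mj else (0.5 if mi == mj else 0.0)
            assert cd_auc(m, t, e, t=th) == pytest.approx(num / den)

    def test_matches_scikit_survival_ipcw(self):
        from sksurv.metrics import cumulative_dynamic_auc

        df = make_exponential_cohort(n=400, beta=0.8, seed=3)
        m = df["x"].to_numpy()
        y = np.array(
            [(bool(e), t) for e, t in zip(df["event"], df["time"])],
            dtype=[("e", bool), ("t", float)],
        )
        ref, _ = cumulative_dynamic_auc(y, y, m, [1.5, 2.5])
        ours = [cd_auc(m, df["time"], df["event"], t=h) for h in (1.5, 2.5)]
        assert np.allclose(ours, ref, atol=1e-10)

    def test_undefined_without_cases(self):
        with pytest.raises(NumericalError):
            cd_auc(np.ones(3), np.array([5.0, 6.0, 7.0]), np.zeros(3), t=1.0)


class TestIauc:
    def test_perfect_marker(self):
        rng = np.random.default_rng(4)
        t = rng.exponential(2.0, 200) + 0.01
        e = np.ones(200)
        res = iauc(-t, t, e, t0=0.25, t1=5.0, n_boot=0)
        assert res.iauc == pytest.approx(1.0)

    def test_weights_normalised_and_value_bounded(self):
        df = make_exponential_cohort(n=500, beta=0.8, seed=5)
        res = iauc(df["x"].to_numpy(), df["time"], df["event"], n_boot=0)
        assert res.weights.sum() == pytest.approx(1.0)
        assert res.auc_values.min() - 1e-12 <= res.iauc <= res.auc_values.max() + 1e-12

    def test_invariant_under_increasing_transform(self):
        df = make_exponential_cohort(n=400, beta=0.8, seed=6)
        m = df["x"].to_numpy()
        a = iauc(m, df["time"], df["event"], n_boot=0).iauc
        b = iauc(np.exp(2 * m), df["time"], df["event"], n_boot=0).iauc
        assert a == pytest.approx(b)

    def test_no_events_in_window_rejected(self):
        t = np.array([10.0, 11.0, 12.0, 13.0])
        e = np.array([1, 1, 0, 0])
        with pytest.raises(NumericalError):
            iauc(np.arange(4.0), t, e, t0=0.25, t1=5.0, n_boot=0)

    def test_bootstrap_ci_seed_deterministic(self):
        df = make_exponential_cohort(n=200, beta=0.8, seed=7)
        m = df["x"].to_numpy()
        a = iauc(m, df["time"], df["event"], n_boot=30, seed=9)
        b = iauc(m, df["time"], df["event"], n_boot=30, seed=9)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)


class TestRiskBands:
    @staticmethod
    def _summaries(hrs):
        out = []
        for i, hr in enumerate(hrs, start=1):
            s = NodeSummary(i, 10, 5, 50.0, 10.0, hr=hr, rank=i)
            s.is_reference = hr == 1.0
            out.append(s)
        return out

    def test_published_grouping_pattern(self):
        """HRs {1, 2, 4, 6.1, 7.1, 12} -> low / 2 intermediate / 2 high / very high."""
        bands = risk_bands(self._summaries([1.0, 2.0, 4.0, 6.1, 7.1, 12.0]))
        assert list(bands.assignment.values()) == [
            "low", "intermediate", "intermediate", "high", "high", "very high",
        ]

    def test_all_below_first_edge_low(self):
        bands = risk_bands(self._summaries([1.0, 1.3, 1.8]))
        assert set(bands.assignment.values()) == {"low"}

    def test_monotone_in_hr(self):
        bands = risk_bands(self._summaries([1.0, 2.5, 3.0, 5.5, 11.0]))
        order = ["low", "intermediate", "high", "very high"]
        labels = [bands.assignment[i] for i in sorted(bands.assignment)]
        indices = [order.index(b) for b in labels]
        assert indices == sorted(indices)


class TestTreeMetrics:
    def test_end_to_end_on_planted_tree(self):
        cohort, tree = four_leaf_setup(n=1200, seed=11)
        tm = tree_metrics(tree, cohort, n_boot=20, seed=1)
        assert tm.N == 1200 and tm.f == 4
        assert tm.irv > 0
        assert 0.6 <= tm.iauc.iauc <= 1.0
        assert tm.banding.assignment[
            min(s.node_id for s in tm.summaries if s.is_reference)
        ] == "low"
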