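"""The hazard-ratio-splitting CART: split search, growth, routing, bagging."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from mirisk import (
    TreeParams,
    ValidationError,
    assign_node,
    bagging_select,
    best_split,
    enumerate_splits,
    generate_cohort,
    grow_tree,
    null_cohort_spec,
    null_truth,
    recovery_benchmark_spec,
    recovery_benchmark_truth,
    score_split,
    tree_from_nested,
)

from conftest import make_exponential_cohort

NULL_VARS = ["x1", "x2", "x3", "x4", "x5"]
REC_VARS = ["biomarker", "mir", "noise_cont", "noise_bin", "noise_scale"]


def two_group_frame(n=400, hr=1.0, seed=0):
    """Half the subjects carry an indicator with the given true hazard ratio."""
    rng = np.random.default_rng(seed)
    g = np.repeat([0.0, 1.0], n // 2)
    T = rng.exponential(1.0 / (0.2 * hr ** g))
    C = rng.uniform(0.5, 6.0, n)
    return pd.DataFrame(
        {"time": np.minimum(T, C), "event": (T <= C).astype(int), "g": g}
    )


class TestEnumerateSplits:
    def test_binary_variable_single_candidate(self):
        df = two_group_frame(seed=1)
        cands = enumerate_splits(df, "g", TreeParams(max_candidates=None))
        assert len(cands) == 1
        assert cands[0].cutoff == 0.5

    def test_k_distinct_values_give_k_minus_1(self):
        df = pd.DataFrame(
            {
                "time": np.arange(1.0, 13.0),
                "event": [1, 0] * 6,
                "v": np.repeat([1.0, 2.0, 5.0, 9.0], 3),
            }
        )
        cands = enumerate_splits(df, "v", TreeParams(max_candidates=None, min_node_n=2))
        assert len(cands) == 3

    def test_constant_variable_empty(self):
        df = two_group_frame(seed=2).assign(c=1.0)
        assert enumerate_splits(df, "c") == []

    def test_thinned_admissible_subset_of_exhaustive(self):
        df = make_exponential_cohort(n=300, beta=0.5, seed=3)
        full = {
            (c.variable, c.cutoff)
            for c in enumerate_splits(df, "x", TreeParams(max_candidates=None))
            if c.admissible
        }
        thin = {
            (c.variable, c.cutoff)
            for c in enumerate_splits(df, "x", TreeParams(max_candidates=25))
            if c.admissible
        }
        assert thin <= full


class TestScoreSplit:
    def test_null_wald_calibrated(self):
        """Identical survival in both children: Wald chi2 ~ chi2(1)."""
        crit = sps.chi2.ppf(0.95, 1)
        below = 0
        n_seeds = 60
        for s in range(n_seeds):
            df = two_group_frame(n=400, hr=1.0, seed=1000 + s)
            cand = enumerate_splits(df, "g")[0]
            cand = score_split(df, cand)
            below += cand.wald_z2 < crit
        assert 0.85 <= below / n_seeds <= 1.0

    def test_planted_split_attains_maximum(self):
        """With a true HR-3 dichotomy, that candidate wins the search."""
        wins = 0
        n_seeds = 30
        for s in range(n_seeds):
            rng = np.random.default_rng(2000 + s)
            df = two_group_frame(n=400, hr=3.0, seed=2000 + s)
            df["decoy"] = rng.normal(size=len(df))
            cand, _ = best_split(df, ["g", "decoy"], TreeParams(alpha_split=1.0, multiplicity="none"))
            wins += cand is not None and cand.variable == "g"
        assert wins / n_seeds >= 0.85

    def test_one_sided_candidate_inadmissible(self):
        df = two_group_frame(seed=4)
        from mirisk.tree import SplitCandidate

        cand = SplitCandidate(variable="g", cutoff=2.0)  # everything goes left
        scored = score_split(df, cand)
        assert not scored.admissible


class TestBestSplit:
    def test_none_when_nothing_significant(self):
        df = two_group_frame(n=200, hr=1.0, seed=5)
        df["u"] = np.random.default_rng(5).normal(size=len(df))
        cand, _ = best_split(df, ["u"], TreeParams(alpha_split=1e-12))
        assert cand is None

    def test_row_permutation_invariance(self):
        df = make_exponential_cohort(n=250, beta=0.8, seed=6)
        params = TreeParams(alpha_split=1.0, multiplicity="none")
        a, _ = best_split(df, ["x", "noise"], params)
        shuffled = df.sample(frac=1.0, random_state=1).reset_index(drop=True)
        b, _ = best_split(shuffled, ["x", "noise"], params)
        assert (a.variable, a.cutoff) == (b.variable, b.cutoff)
        assert a.wald_z2 == pytest.approx(b.wald_z2, rel=1e-9)

    def test_exhaustive_brute_force_oracle_small_fixture(self):
        """Independent exhaustive search with lifelines on 60 subjects."""
        from lifelines import CoxPHFitter

        df = make_exponential_cohort(n=60, beta=1.0, seed=7)
        df["b"] = (np.random.default_rng(7).normal(size=60) > 0).astype(float)
        params = TreeParams(
            alpha_split=1.0, multiplicity="none", min_node_n=10,
            min_node_events=3, max_candidates=None,
        )
        ours, _ = best_split(df, ["x", "noise", "b"], params)

        best_stat, best_pair = -np.inf, None
        for var in ["x", "noise", "b"]:
            u = np.unique(df[var])
            for cut in (u[:-1] + u[1:]) / 2:
                ind = (df[var] > cut).astype(float)
                ev = df["event"].to_numpy()
                if min(ind.sum(), (1 - ind).sum()) < 10:
                    continue
                if min(ev[ind == 1].sum(), ev[ind == 0].sum()) < 3:
                    continue
                fit = CoxPHFitter().fit(
                    pd.DataFrame(
                        {"time": df["time"], "event": df["event"], "i": ind}
                    ),
                    "time",
                    "event",
                )
                z2 = (fit.params_.iloc[0] / fit.standard_errors_.iloc[0]) ** 2
                if z2 > best_stat:
                    best_stat, best_pair = z2, (var, cut)
        assert (ours.variable, ours.cutoff) == best_pair
        assert ours.wald_z2 == pytest.approx(best_stat, rel=1e-3)


class TestGrowTree:
    def test_null_cohort_usually_root_only(self):
        root_only = 0
        n_seeds = 40
        for s in range(n_seeds):
            c, _ = generate_cohort(null_cohort_spec(400), null_truth(), 3000 + s)
            tree = grow_tree(c, NULL_VARS, TreeParams())
            root_only += tree.n_terminal == 1
        assert root_only / n_seeds >= 0.9

    def test_two_level_structure_recovery(self):
        ok = 0
        n_seeds = 25
        for s in range(n_seeds):
            c, _ = generate_cohort(
                recovery_benchmark_spec(600), recovery_benchmark_truth(), 4000 + s
            )
            tree = grow_tree(c, REC_VARS, TreeParams(max_depth=2))
            root = tree.nodes[1]
            root_ok = (
                not root.is_terminal
                and root.split.variable == "biomarker"
                and abs(root.split.cutoff - 7.2) <= 0.25 * 1.2
            )
            mir_ok = any(
                not nd.is_terminal
                and nd.split.variable == "mir"
                and abs(nd.split.cutoff - 1.5) <= 0.26
                for nd in tree.nodes.values()
            )
            ok += root_ok and mir_ok
        assert ok / n_seeds >= 0.85

    def test_depth_three_at_most_eight_leaves(self):
        c, _ = generate_cohort(recovery_benchmark_spec(600), recovery_benchmark_truth(), 1)
        tree = grow_tree(c, REC_VARS, TreeParams(max_depth=3))
        assert tree.n_terminal <= 8
        assert tree.depth <= 3

    def test_terminal_nodes_partition_cohort(self):
        c, _ = generate_cohort(recovery_benchmark_spec(600), recovery_benchmark_truth(), 2)
        tree = grow_tree(c, REC_VARS, TreeParams())
        terms = tree.terminal_nodes()
        assert sum(nd.n for nd in terms) == len(c)
        all_members = np.concatenate([nd.member_index for nd in terms])
        assert np.array_equal(np.sort(all_members), np.arange(len(c)))

    def test_stricter_alpha_never_deeper(self):
        c, _ = generate_cohort(recovery_benchmark_spec(600), recovery_benchmark_truth(), 3)
        deep = grow_tree(c, REC_VARS, TreeParams(alpha_split=0.2))
        shallow = grow_tree(c, REC_VARS, TreeParams(alpha_split=0.001))
        assert shallow.depth <= deep.depth
        assert shallow.n_terminal <= deep.n_terminal

    def test_tiny_cohort_root_only_with_warning(self):
        df = make_exponential_cohort(n=20, seed=8)
        with pytest.warns(UserWarning):
            tree = grow_tree(df, ["x"], TreeParams())
        assert tree.n_terminal == 1


class TestAssignment:
    @pytest.fixture
    def fig_tree(self):
        """Low NT-proBNP branch refined by the miRNA level, as in the fitted model."""
        return tree_from_nested(
            {
                "variable": "log_nt_probnp",
                "cutoff": 6.0,
                "left": {
                    "variable": "mir133a",
                    "cutoff": 1.5,
                    "left": {"leaf": "low-NT, low miR", "hazard": 0.13},
                    "right": {"leaf": "low-NT, high miR", "hazard": 0.053},
                },
                "right": {"leaf": "high-NT", "hazard": 0.4},
            }
        )

    def test_low_ntprobnp_high_mir_routes_to_lowest_risk(self, fig_tree):
        """log(NT-proBNP)=5.5 with miR=1.6 lands in the low-risk leaf."""
        nid = assign_node(fig_tree, {"log_nt_probnp": 5.5, "mir133a": 1.6})
        node = fig_tree.nodes[nid]
        # the lowest-risk leaf is the right child of the miRNA split
        assert fig_tree.nodes[node.parent].split.variable == "mir133a"
        assert nid == fig_tree.nodes[node.parent].right

    def test_boundary_goes_left(self, fig_tree):
        nid = assign_node(fig_tree, {"log_nt_probnp": 6.0, "mir133a": 1.5})
        parent = fig_tree.nodes[fig_tree.nodes[nid].parent]
        assert nid == parent.left

    def test_missing_variable_signalled(self, fig_tree):
        with pytest.raises(ValidationError):
            assign_node(fig_tree, {"log_nt_probnp": 5.0})

    def test_training_subjects_route_to_their_member_node(self):
        c, _ = generate_cohort(recovery_benchmark_spec(400), recovery_benchmark_truth(), 4)
        tree = grow_tree(c, REC_VARS, TreeParams())
        assigned = tree.assign_frame(c.data)
        for nd in tree.terminal_nodes():
            assert np.array_equal(np.sort(np.nonzero(assigned == nd.node_id)[0]),
                                  np.sort(nd.member_index))

    def test_nested_routing_matches_truth(self):
        truth = recovery_benchmark_truth()
        tree = tree_from_nested(truth.tree)
        c, _ = generate_cohort(recovery_benchmark_spec(300), truth, 5)
        assigned = tree.assign_frame(c.data)
        # same partition: each fitted node maps 1-1 onto a planted leaf
        for nid in np.unique(assigned):
            rows = c.data.loc[assigned == nid]
            leaves = {truth.leaf_id(r) for r in rows.to_dict("records")}
            assert len(leaves) == 1


class TestBagging:
    def test_smoke_frequencies_and_retention(self):
        c, _ = generate_cohort(recovery_benchmark_spec(300), recovery_benchmark_truth(), 6)
        rep = bagging_select(c, REC_VARS, B=25, seed=1)
        assert all(0.0 <= f <= 1.0 for f in rep.selection_frequency.values())
        assert set(rep.retained) <= set(REC_VARS)

    def test_seed_determinism(self):
        c, _ = generate_cohort(recovery_benchmark_spec(300), recovery_benchmark_truth(), 7)
        a = bagging_select(c, REC_VARS, B=10, seed=3)
        b = bagging_select(c, REC_VARS, B=10, seed=3)
        assert a == b

    def test_informative_variable_selected_more_than_noise(self):
        c, _ = generate_cohort(recovery_benchmark_spec(600), recovery_benchmark_truth(), 8)
        rep = bagging_select(c, REC_VARS, B=40, seed=4)
        f = rep.selection_frequency
        assert f["biomarker"] > f["noise_cont"]
        assert f["biomarker"] > f["noise_bin"]
        assert np.isfinite(rep.oob_iauc_mean)
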