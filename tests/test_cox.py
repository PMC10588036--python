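"""The Cox engine: Efron partial likelihood, concordance, bootstrap deltas."""

import numpy as np
import pandas as pd
import pytest

from mirisk import (
    BinarySplitCoxScorer,
    NumericalError,
    ValidationError,
    delta_cindex,
    fit_cox,
    harrell_cindex,
)

from conftest import make_exponential_cohort


class TestFitCox:
    def test_sign_flip_symmetry(self, exp_cohort):
        """Concatenating a covariate-sign-flipped copy forces coef = 0."""
        flipped = exp_cohort.copy()
        flipped[["x", "noise"]] *= -1
        both = pd.concat([exp_cohort, flipped], ignore_index=True)
        fit = fit_cox(both, ["x", "noise"])
        assert np.all(np.abs(fit.coef) < 1e-6)

    def test_four_subject_grid_search_oracle(self):
        """Hand-written partial likelihood, grid over [-5, 5] step 1e-4."""
        df = pd.DataFrame(
            {"time": [1.0, 2.0, 3.0, 4.0], "event": [1, 1, 1, 1], "x": [1.0, 0.0, 1.0, 0.0]}
        )
        x = df["x"].to_numpy()

        def ll(beta):
            # events at times 1..4; risk sets shrink one subject at a time
            total = 0.0
            for k in range(4):
                risk = x[k:]
                total += beta * x[k] - np.log(np.exp(beta * risk).sum())
            return total

        grid = np.arange(-5.0, 5.0 + 1e-9, 1e-4)
        lls = np.array([ll(b) for b in grid])
        beta_grid = grid[np.argmax(lls)]
        fit = fit_cox(df, ["x"])
        assert fit.converged
        assert abs(fit.coef[0] - beta_grid) <= 1e-3

    def test_matches_lifelines(self, exp_cohort):
        from lifelines import CoxPHFitter

        fit = fit_cox(exp_cohort, ["x", "noise"])
        ref = CoxPHFitter().fit(
            exp_cohort[["time", "event", "x", "noise"]], "time", "event"
        )
        assert np.allclose(fit.coef, ref.params_.values, atol=1e-5)
        assert np.allclose(fit.se, ref.standard_errors_.values, atol=1e-5)
        assert fit.log_likelihood == pytest.approx(ref.log_likelihood_, abs=1e-4)

    def test_efron_equals_breslow_without_ties(self):
        """With unique event times the two tie corrections coincide."""
        from lifelines import CoxPHFitter

        df = make_exponential_cohort(n=150, beta=0.5, seed=21)
        assert df["time"].nunique() == len(df)
        fit = fit_cox(df, ["x"])
        ref = CoxPHFitter().fit(df[["time", "event", "x"]], "time", "event")
        assert fit.coef[0] == pytest.approx(ref.params_.iloc[0], abs=1e-6)

    def test_hazard_ratio_recovery(self):
        """True HR 3 per unit: exp(coef) lands in [2.7, 3.3] for most seeds."""
        inside = 0
        for s in range(20):
            df = make_exponential_cohort(n=2000, beta=np.log(3.0), seed=100 + s)
            fit = fit_cox(df, ["x"])
            inside += 2.7 <= np.exp(fit.coef[0]) <= 3.3
        assert inside >= 17

    def test_separation_flagged_not_raised(self):
        df = pd.DataFrame(
            {
                "time": np.arange(1.0, 21.0),
                "event": [1] * 10 + [0] * 10,
                "x": [1.0] * 10 + [0.0] * 10,
            }
        )
        fit = fit_cox(df, ["x"])
        assert not fit.converged
        assert "separation" in fit.diagnostics or "monotone" in fit.diagnostics

    def test_collinear_pair_named(self, exp_cohort):
        df = exp_cohort.copy()
        df["x_copy"] = 2.0 * df["x"]
        with pytest.raises(ValidationError, match="x.*x_copy|x_copy.*x"):
            fit_cox(df, ["x", "x_copy"])

    def test_too_few_events_rejected(self):
        df = pd.DataFrame({"time": [1.0, 2.0], "event": [1, 0], "x": [0.5, 1.0]})
        with pytest.raises(ValidationError):
            fit_cox(df, ["x"])

    def test_binary_scorer_agrees_with_general_fit(self, exp_cohort):
        ind = (exp_cohort["x"] > 0.2).astype(float)
        df = exp_cohort.assign(ind=ind)
        fit = fit_cox(df, ["ind"])
        scorer = BinarySplitCoxScorer(
            df["time"].to_numpy(), df["event"].to_numpy()
        )
        res = scorer.score(ind.to_numpy())
        assert res.beta == pytest.approx(fit.coef[0], abs=1e-8)
        assert res.se == pytest.approx(fit.se[0], abs=1e-8)


class TestPredictedProbability:
    def test_probability_monotone_in_risk_and_time(self, exp_cohort):
        fit = fit_cox(exp_cohort, ["x"])
        X = np.array([[-1.0], [0.0], [2.0]])
        p2 = fit.predict_event_probability(X, 2.0)
        p4 = fit.predict_event_probability(X, 4.0)
        assert np.all(np.diff(p2) > 0)          # higher x -> higher risk
        assert np.all(p4 >= p2)                 # longer horizon -> higher risk
        assert np.all((p2 >= 0) & (p4 <= 1))


class TestCindex:
    def test_perfect_and_constant_scores(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        e = np.ones(4)
        assert harrell_cindex(-t, t, e) == 1.0
        assert harrell_cindex(np.zeros(4), t, e) == 0.5

    def test_brute_force_oracle_mixed_censoring(self):
        rng = np.random.default_rng(7)
        n = 60
        t = rng.exponential(2.0, n).round(1) + 0.1
        e = rng.binomial(1, 0.6, n)
        s = rng.normal(size=n).round(1)
        num = den = 0.0
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                usable = (t[i] < t[j] and e[i] == 1) or (
                    t[i] == t[j] and e[i] == 1 and e[j] == 0
                )
                if not usable:
                    continue
                den += 1
                num += 1.0 if s[i] > s[j] else (0.5 if s[i] == s[j] else 0.0)
        assert harrell_cindex(s, t, e) == pytest.approx(num / den)

    def test_matches_lifelines(self):
        from lifelines.utils import concordance_index

        df = make_exponential_cohort(n=300, beta=0.8, seed=31)
        s = df["x"].to_numpy()
        ours = harrell_cindex(s, df["time"].to_numpy(), df["event"].to_numpy())
        ref = concordance_index(df["time"], -s, df["event"])
        assert ours == pytest.approx(ref)

    def test_invariant_under_increasing_transform(self):
        df = make_exponential_cohort(n=200, beta=0.8, seed=32)
        s = df["x"].to_numpy()
        c1 = harrell_cindex(s, df["time"].to_numpy(), df["event"].to_numpy())
        c2 = harrell_cindex(
            np.exp(3 * s), df["time"].to_numpy(), df["event"].to_numpy()
        )
        assert c1 == pytest.approx(c2)

    def test_no_usable_pairs_signalled(self):
        with pytest.raises(NumericalError):
            harrell_cindex(
                np.array([1.0, 2.0]), np.array([1.0, 2.0]), np.array([0, 0])
            )


class TestDeltaCindex:
    def test_identical_scores_delta_zero(self):
        df = make_exponential_cohort(n=200, beta=0.8, seed=41)
        s = df["x"].to_numpy()
        res = delta_cindex(
            s, s, df["time"].to_numpy(), df["event"].to_numpy(), n_boot=200, seed=1
        )
        assert res.delta == 0.0
        assert res.ci_low <= 0.0 <= res.ci_high

    def test_true_signal_improves(self):
        df = make_exponential_cohort(n=600, beta=0.9, seed=42)
        noise = np.random.default_rng(5).normal(size=len(df))
        res = delta_cindex(
            noise,
            df["x"].to_numpy(),
            df["time"].to_numpy(),
            df["event"].to_numpy(),
            n_boot=300,
            seed=2,
        )
        assert res.delta > 0
        assert res.ci_low > 0

    def test_seed_determinism(self):
        df = make_exponential_cohort(n=150, beta=0.5, seed=43)
        args = (
            df["noise"].to_numpy(),
            df["x"].to_numpy(),
            df["time"].to_numpy(),
            df["event"].to_numpy(),
        )
        a = delta_cindex(*args, n_boot=150, seed=9)
        b = delta_cindex(*args, n_boot=150, seed=9)
        assert (a.ci_low, a.ci_high, a.p_value) == (b.ci_low, b.ci_high, b.p_value)
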