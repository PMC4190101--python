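import numpy as np
import pytest

from robsel import cox_core as cc
from robsel.data_io import SurvivalOutcome

from conftest import random_outcome


def _no_tie_data(rng, n=60, p=3, signal=0.8):
    X = rng.normal(size=(n, p))
    t = rng.exponential(1.0, n) * np.exp(-signal * X[:, 0])
    e = (rng.uniform(size=n) < 0.75).astype(int)
    if e.sum() < 2:
        e[:2] = 1
    return X, SurvivalOutcome(t, e)


class TestPartialLogLikelihood:
    def test_null_beta_equals_negative_log_risk_set_sizes(self, rng):
        out = random_outcome(rng, 25, with_ties=False)
        X = rng.normal(size=(25, 4))
        order = np.argsort(out.times)
        sizes = [np.sum(out.times >= out.times[i]) for i in order if out.events[i]]
        expected = -np.sum(np.log(sizes))
        assert cc.partial_log_likelihood(X, out, np.zeros(4)) == pytest.approx(expected)

    def test_hand_evaluated_two_sample_case(self):
        # one event among two samples, x = (1, 0), beta = 1
        out = SurvivalOutcome(np.array([1.0, 2.0]), np.array([1, 0]))
        X = np.array([[1.0], [0.0]])
        assert cc.partial_log_likelihood(X, out, np.array([1.0])) == pytest.approx(
            1.0 - np.log(np.e + 1.0)
        )

    def test_location_invariance_of_features(self, rng):
        X, out = _no_tie_data(rng)
        beta = rng.normal(size=3)
        v1 = cc.partial_log_likelihood(X, out, beta)
        v2 = cc.partial_log_likelihood(X + 3.7, out, beta)
        assert v1 == pytest.approx(v2, rel=1e-12)

    def test_zero_events_rejected(self, rng):
        out = SurvivalOutcome(np.array([1.0, 2.0]), np.array([0, 0]))
        with pytest.raises(ValueError):
            cc.partial_log_likelihood(np.ones((2, 1)), out, np.zeros(1))


class TestPenalizedFit:
    def test_lambda_above_max_gives_exact_null_model(self, rng):
        X, out = _no_tie_data(rng, n=50, p=10)
        lam = cc.lambda_max(X, out) * 1.01
        beta = cc.fit_penalized_cox(X, out, cc.PenaltySpec(lam, 1.0))
        assert np.count_nonzero(beta.beta) == 0

    def test_unpenalized_matches_independent_implementation(self, rng):
        from lifelines import CoxPHFitter
        import pandas as pd

        X, out = _no_tie_data(rng, n=120, p=2)
        ours = cc.fit_penalized_cox(X, out, cc.PenaltySpec(0.0, 1.0), standardize=False)
        df = pd.DataFrame(X, columns=["a", "b"])
        df["T"], df["E"] = out.times, out.events
        ref = CoxPHFitter().fit(df, "T", "E").params_.to_numpy()
        np.testing.assert_allclose(ours.beta, ref, atol=1e-4)

    def test_ridge_norm_shrinks_monotonically(self, rng):
        X, out = _no_tie_data(rng, n=60, p=5)
        lams = [0.01, 0.1, 1.0, 10.0]
        norms = [
            np.linalg.norm(cc.fit_penalized_cox(X, out, cc.PenaltySpec(l, 0.0)).beta)
            for l in lams
        ]
        assert all(a >= b for a, b in zip(norms, norms[1:]))

    def test_lasso_support_shrinks_along_the_path(self, rng):
        X, out = _no_tie_data(rng, n=80, p=20)
        grid = cc.default_lambda_grid(X, out, size=8)
        sizes = [
            np.count_nonzero(cc.fit_penalized_cox(X, out, cc.PenaltySpec(l, 1.0)).beta)
            for l in sorted(grid)
        ]
        # non-increasing support in lambda, allowing the path's minor wobbles
        violations = sum(a < b for a, b in zip(sizes, sizes[1:]))
        assert violations <= 1
        assert sizes[0] >= sizes[-1]

    def test_penalized_objective_beats_null(self, rng):
        X, out = _no_tie_data(rng, n=70, p=8)
        lam = cc.lambda_max(X, out) * 0.3
        Xs = (X - X.mean(0)) / X.std(0)
        beta = cc.fit_penalized_cox(Xs, out, cc.PenaltySpec(lam, 1.0), standardize=False).beta
        n = len(out)

        def obj(b):
            return cc.partial_log_likelihood(Xs, out, b) / n - lam * np.abs(b).sum()

        assert obj(beta) >= obj(np.zeros(8)) - 1e-9


class TestCvSelectLambda:
    def test_grid_of_length_one_returned_verbatim(self, rng):
        X, out = _no_tie_data(rng, n=40, p=4)
        spec = cc.cv_select_lambda(X, out, lambda_grid=np.array([0.123]))
        assert spec.lam == 0.123

    def test_pure_noise_prefers_heavy_penalty(self):
        hits = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(60, 30))
            out = random_outcome(rng, 60)
            grid = cc.default_lambda_grid(X, out, size=20)
            spec = cc.cv_select_lambda(X, out, lambda_grid=grid, seed=seed)
            hits += spec.lam >= np.median(grid)
        assert hits >= 4

    def test_strong_signal_recovered(self):
        hits = 0
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            X, out = _no_tie_data(rng, n=200, p=10, signal=1.2)
            spec = cc.cv_select_lambda(X, out, seed=seed, lambda_grid=cc.default_lambda_grid(X, out, size=30))
            beta = cc.fit_penalized_cox(X, out, spec)
            hits += 0 in beta.support()
        assert hits >= 5 * 0.9


class TestBaselineHazardAndSurvival:
    def test_nelson_aalen_limit_without_ties(self):
        out = SurvivalOutcome(np.array([1.0, 2.0, 3.0]), np.array([1, 1, 1]))
        bh = cc.estimate_baseline_hazard(np.zeros((3, 1)), out, np.zeros(1))
        np.testing.assert_allclose(bh.increments, [1 / 3, 1 / 2, 1.0])

    def test_nelson_aalen_limit_with_ties(self):
        out = SurvivalOutcome(np.array([1.0, 1.0, 2.0, 3.0]), np.array([1, 1, 1, 0]))
        bh = cc.estimate_baseline_hazard(np.zeros((4, 1)), out, np.zeros(1))
        np.testing.assert_allclose(bh.event_times, [1.0, 2.0])
        np.testing.assert_allclose(bh.increments, [2 / 4, 1 / 2])
        np.testing.assert_array_equal(bh.event_counts, [2, 1])

    def test_doubling_risk_halves_increments(self, rng):
        X, out = _no_tie_data(rng, n=30, p=2)
        beta = np.array([0.5, -0.2])
        bh1 = cc.estimate_baseline_hazard(X, out, beta)
        # add log(2) to every linear predictor via an intercept-like column
        bh2 = cc.estimate_baseline_hazard(
            np.column_stack([X, np.ones(30)]), out, np.r_[beta, np.log(2.0)]
        )
        np.testing.assert_allclose(bh2.increments, bh1.increments / 2.0)

    def test_survival_function_hand_value_and_monotonicity(self, rng):
        out = SurvivalOutcome(np.array([1.0, 2.0]), np.array([1, 0]))
        bh = cc.estimate_baseline_hazard(np.zeros((2, 1)), out, np.zeros(1))
        assert cc.survival_function(bh, np.zeros(1), np.zeros(1), 0.5) == 1.0
        assert cc.survival_function(bh, np.zeros(1), np.zeros(1), 1.0) == pytest.approx(
            np.exp(-0.5)
        )
        X, big_out = _no_tie_data(rng, n=40)
        beta = np.array([1.0, 0.0, 0.0])
        bh = cc.estimate_baseline_hazard(X, big_out, beta)
        ts = np.linspace(0, big_out.times.max(), 25)
        lo = [cc.survival_function(bh, beta, np.array([1.0, 0, 0]), t) for t in ts]
        hi = [cc.survival_function(bh, beta, np.array([-1.0, 0, 0]), t) for t in ts]
        assert all(np.diff(lo) <= 1e-12)  # non-increasing in t
        assert all(l <= h + 1e-12 for l, h in zip(lo, hi))  # higher risk, lower curve
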