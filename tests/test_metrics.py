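import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from robsel import metrics as me
from robsel.data_io import SurvivalOutcome
from robsel.synthetic import make_fixture

from conftest import random_outcome


def oracle_concordance(pred, outcome):
    """Independent exhaustive pair enumeration.

    A pair is usable unless both patients have events at the same time or the
    shorter observed time is censored; equal-time event-vs-censored pairs put
    the event first.  Concordant when the earlier patient has the larger risk
    prediction; prediction ties fall out of both counts.
    """
    t, e = outcome.times, outcome.events
    num = den = 0
    n = len(t)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if t[i] < t[j] and e[i] == 1:
                first = True
            elif t[i] == t[j] and e[i] == 1 and e[j] == 0:
                first = True
            else:
                first = False
            if first and pred[i] != pred[j]:
                den += 1
                num += pred[i] > pred[j]
    if den == 0:
        raise ValueError("no comparable pairs")
    return num / den


class TestConcordance:
    def test_matches_bruteforce_oracle_on_random_censored_data(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            n = int(rng.integers(4, 31))
            out = random_outcome(rng, n, censor_frac=rng.uniform(0.0, 0.6),
                                 with_ties=bool(rng.integers(0, 2)))
            pred = rng.choice([-1.0, 0.0, 0.5, 1.0, 2.0], size=n) if rng.integers(0, 2) \
                else rng.normal(size=n)
            try:
                expected = oracle_concordance(pred, out)
            except ValueError:
                with pytest.raises(ValueError):
                    me.concordance_index(pred, out)
                continue
            assert me.concordance_index(pred, out) == expected

    def test_perfect_order_fixture_scores_one(self):
        ds = make_fixture("perfect_order")
        assert me.concordance_index(ds.expression.design()[:, 0], ds.outcome) == 1.0

    def test_tied_event_pair_is_not_comparable(self):
        ds = make_fixture("tied_events")
        # 5 patients; the (S0,S1) both-event tie is excluded; S3 censored at 5
        # precedes nobody; usable untied pairs: S0/S1 vs {S2,S3,S4} and S2 vs {S3,S4}
        pred = ds.expression.design()[:, 0]
        assert me.concordance_index(pred, ds.outcome) == 1.0
        # flipping one prediction changes the count by exactly its pair share
        pred2 = pred.copy()
        pred2[4] = 10.0  # latest event now predicted most at risk: 3 discordant pairs
        assert me.concordance_index(pred2, ds.outcome) == pytest.approx(5 / 8)

    def test_binary_predictions_equal_auc(self):
        ds = make_fixture("binary_pred")
        pred = ds.expression.design()[:, 0]
        t = ds.outcome.times
        hi, lo = t[pred == 1], t[pred == 0]
        # independent rank-sum AUC: P(high-risk patient fails earlier)
        auc = np.mean([a < b for a in hi for b in lo])
        assert me.concordance_index(pred, ds.outcome) == pytest.approx(auc)

    def test_invariance_under_monotone_transform_and_reflection(self, rng):
        out = random_outcome(rng, 40)
        pred = rng.normal(size=40)
        c = me.concordance_index(pred, out)
        assert me.concordance_index(np.exp(3 * pred), out) == c
        assert me.concordance_index(-pred, out) == pytest.approx(1.0 - c)


class TestSetStability:
    def test_jaccard_identical_disjoint_and_hand_case(self):
        s = lambda *f: me.SignatureSet(tuple(f))
        assert me.jaccard_stability([s("a", "b"), s("a", "b"), s("b", "a")]) == 1.0
        assert me.jaccard_stability([s("a"), s("b")]) == 0.0
        assert me.jaccard_stability([s("a", "b", "c"), s("b", "c", "d")]) == 0.5

    def test_jaccard_invariant_under_list_permutation(self, rng):
        sigs = [me.SignatureSet(tuple(rng.choice(20, 5, replace=False).tolist()))
                for _ in range(4)]
        v = me.jaccard_stability(sigs)
        assert me.jaccard_stability(sigs[::-1]) == v

    def test_kuncheva_identical_chance_and_hand_case(self):
        s = lambda *f: me.SignatureSet(tuple(f))
        assert me.kuncheva_index([s(1, 2), s(1, 2)], p=10) == 1.0
        # k=2, p=10, overlap 1: (1 - 0.4) / (2 - 0.4)
        assert me.kuncheva_index([s(1, 2), s(2, 3)], p=10) == pytest.approx(0.375)
        # overlap exactly k^2/p: k=4, p=8, |A∩B|=2 -> 0
        assert me.kuncheva_index(
            [s(1, 2, 3, 4), s(3, 4, 5, 6)], p=8
        ) == pytest.approx(0.0)

    def test_kuncheva_requires_equal_sizes(self):
        with pytest.raises(ValueError, match="same size"):
            me.kuncheva_index([me.SignatureSet((1,)), me.SignatureSet((1, 2))], p=10)
        with pytest.raises(ValueError):
            me.kuncheva_index([me.SignatureSet((1, 2)), me.SignatureSet((3, 4))], p=2)

    def test_kuncheva_of_random_subsets_is_chance_corrected_to_zero(self):
        rng = np.random.default_rng(0)
        k, p, draws = 5, 40, 10000
        vals = np.empty(draws)
        for d in range(draws):
            a = me.SignatureSet(tuple(rng.choice(p, k, replace=False).tolist()))
            b = me.SignatureSet(tuple(rng.choice(p, k, replace=False).tolist()))
            vals[d] = me.kuncheva_index([a, b], p)
        assert abs(vals.mean()) < 0.02


class TestRankStability:
    def test_identical_rankings_have_zero_distance(self):
        a = me.SignatureSet(("x", "y", "z"), ranked=True)
        assert me.canberra_rank_distance([a, a], p=50) == 0.0

    def test_reversed_two_feature_ranking_hand_value(self):
        a = me.SignatureSet(("x", "y"), ranked=True)
        b = me.SignatureSet(("y", "x"), ranked=True)
        raw = abs(1 - 2) / (1 + 2) + abs(2 - 1) / (2 + 1)  # = 2/3
        expected = raw / me._canberra_null_expectation(2, 10)
        assert me.canberra_rank_distance([a, b], p=10) == pytest.approx(expected)

    @pytest.mark.parametrize("k,p", [(3, 15), (5, 40), (10, 60)])
    def test_monte_carlo_normalizer_matches_closed_form(self, k, p):
        # marginal rank of a feature: uniform on {1..k} w.p. 1/p each, k+1 otherwise;
        # linearity of expectation gives the expected null distance exactly
        a = np.arange(1, k + 1)
        within = np.abs(a[:, None] - a[None, :]) / (a[:, None] + a[None, :])
        e_pair = within.sum() / p**2 + 2 * (1 - k / p) / p * ((k + 1 - a) / (k + 1 + a)).sum()
        closed = p * e_pair
        assert me._canberra_null_expectation(k, p) == pytest.approx(closed, rel=0.03)

    def test_random_lists_score_about_one_after_normalization(self):
        rng = np.random.default_rng(7)
        p, k = 30, 4
        vals = []
        for _ in range(300):
            a = me.SignatureSet(tuple(rng.choice(p, k, replace=False).tolist()), ranked=True)
            b = me.SignatureSet(tuple(rng.choice(p, k, replace=False).tolist()), ranked=True)
            vals.append(me.canberra_rank_distance([a, b], p))
        assert np.mean(vals) == pytest.approx(1.0, abs=0.05)

    def test_rank_penalized_kuncheva_limits(self):
        a = me.SignatureSet(("x", "y", "z"), ranked=True)
        assert me.rank_penalized_kuncheva([a, a], p=100) == np.inf
        b = me.SignatureSet(("u", "v", "w"), ranked=True)
        assert me.rank_penalized_kuncheva([a, b], p=6) == 0.0  # overlap 0 <= chance
        c = me.SignatureSet(("x", "y", "q"), ranked=True)
        val = me.rank_penalized_kuncheva([a, c], p=100)
        assert 0.0 <= val < np.inf


class TestPairedTest:
    def test_identical_samples_are_non_significant(self):
        a = np.array([0.6, 0.7, 0.65, 0.62])
        assert me.paired_welch_test(a, a.copy()) == 0.5

    def test_constant_positive_shift_is_significant(self, rng):
        b = rng.normal(0.6, 0.05, size=30)
        a = b + 1.0 + rng.normal(0, 1e-3, size=30)
        assert me.paired_welch_test(a, b, side="greater") < 0.001

    def test_swapping_sides_flips_p(self, rng):
        a = rng.normal(0.65, 0.05, 30)
        b = rng.normal(0.60, 0.05, 30)
        p1 = me.paired_welch_test(a, b, side="greater")
        p2 = me.paired_welch_test(b, a, side="greater")
        assert p1 + p2 == pytest.approx(1.0)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_concordance_complement_identity_without_ties(seed):
    """c(pred) + c(-pred) == 1 whenever predictions are tie-free."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(5, 40))
    out = random_outcome(rng, n)
    pred = rng.normal(size=n)
    try:
        c = me.concordance_index(pred, out)
    except ValueError:
        return
    assert c + me.concordance_index(-pred, out) == pytest.approx(1.0)
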