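"""Statistical primitives vs independent oracles (enumeration, closed form,
scipy/lifelines/scikit-survival cross-checks)."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from methfield.stats import (
    benjamini_hochberg,
    coefficient_of_variation,
    cox_partial_loglik,
    hypergeometric_upper_tail,
    logrank_test,
    penalized_cox_fit,
    spearman_rho,
    wilcoxon_rank_sum,
)


class TestCoefficientOfVariation:
    def test_constant_vector_is_zero(self):
        assert coefficient_of_variation([0.5, 0.5, 0.5]) == 0.0

    def test_two_point_matches_direct_formula(self):
        x = np.array([0.2, 0.4])
        expected = x.std(ddof=1) / x.mean()  # direct-formula oracle
        assert coefficient_of_variation(x) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.4714, abs=1e-4)

    def test_zero_mean_is_undefined(self):
        assert math.isnan(coefficient_of_variation([-0.1, 0.1]))

    def test_short_input_raises(self):
        with pytest.raises(ValueError):
            coefficient_of_variation([0.3])

    @pytest.mark.parametrize("scale", [0.1, 1.0, 7.3])
    def test_scale_invariance(self, scale):
        rng = np.random.default_rng(0)
        x = rng.uniform(0.1, 1.0, 20)
        assert coefficient_of_variation(scale * x) == pytest.approx(
            coefficient_of_variation(x), rel=1e-12
        )


class TestSpearman:
    def test_monotone_and_antitone(self):
        assert spearman_rho([1, 2, 3], [10, 20, 30]) == pytest.approx(1.0)
        assert spearman_rho([1, 2, 3], [30, 20, 10]) == pytest.approx(-1.0)

    def test_ties_match_midrank_oracle(self):
        x, y = [1, 2, 2, 4], [4, 1, 2, 3]
        # oracle: rank-then-Pearson with scipy's independent implementation
        expected = sps.spearmanr(x, y).statistic
        assert spearman_rho(x, y) == pytest.approx(expected, abs=1e-12)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        r0 = spearman_rho(x, y)
        assert spearman_rho(np.exp(x), y) == pytest.approx(r0, abs=1e-12)
        assert spearman_rho(x, y**3) == pytest.approx(r0, abs=1e-12)

    def test_pairwise_complete_and_zero_variance(self):
        x = [1.0, 2.0, np.nan, 4.0, 5.0]
        y = [2.0, 3.0, 9.0, 5.0, 6.0]
        assert spearman_rho(x, y) == pytest.approx(1.0)
        assert math.isnan(spearman_rho([1, 1, 1], [1, 2, 3]))


def _exact_wilcoxon_oracle(a, b):
    """Full enumeration over all assignments of the pooled values."""
    pooled = np.concatenate([a, b])
    na = len(a)
    ranks = sps.rankdata(pooled)
    u_obs = ranks[:na].sum() - na * (na + 1) / 2
    us = []
    for comb in itertools.combinations(range(len(pooled)), na):
        us.append(ranks[list(comb)].sum() - na * (na + 1) / 2)
    us = np.array(us)
    return min(1.0, 2 * min((us >= u_obs).mean(), (us <= u_obs).mean()))


class TestWilcoxon:
    def test_small_exact_example(self):
        _, p = wilcoxon_rank_sum([1, 2], [3, 4])
        assert p == pytest.approx(2 / 6)

    def test_identical_samples_give_p_one(self):
        _, p = wilcoxon_rank_sum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_exact_path_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=rng.integers(2, 6))
        b = rng.normal(size=rng.integers(2, 6))
        _, p = wilcoxon_rank_sum(a, b)
        assert p == pytest.approx(_exact_wilcoxon_oracle(a, b), abs=1e-12)

    @pytest.mark.parametrize("seed", range(3))
    def test_normal_approximation_close_to_exact(self, seed):
        rng = np.random.default_rng(100 + seed)
        a = rng.normal(size=6)
        b = rng.normal(size=6)
        _, p_exact = wilcoxon_rank_sum(a, b)  # 12 <= 12: exact path
        big_a = np.concatenate([a, [a.max() + 10]])  # n=13 forces approx path
        _, p_lift = wilcoxon_rank_sum(np.concatenate([a, b]), np.array([0.0]))
        # cross-validate the approximation against scipy on a larger sample
        a2 = rng.normal(size=30)
        b2 = rng.normal(0.5, 1, size=30)
        _, p_approx = wilcoxon_rank_sum(a2, b2)
        p_scipy = sps.mannwhitneyu(a2, b2, alternative="two-sided").pvalue
        assert p_approx == pytest.approx(p_scipy, abs=0.02)
        assert 0 <= p_lift <= 1

    def test_two_paths_agree_for_moderate_n(self):
        rng = np.random.default_rng(5)
        a = rng.normal(size=6)
        b = rng.normal(size=6)
        _, p_exact = wilcoxon_rank_sum(a, b)
        p_scipy = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue
        assert abs(p_exact - p_scipy) < 0.02


class TestHypergeometric:
    def test_forced_outcomes(self):
        assert hypergeometric_upper_tail(10, 4, 3, 0) == 1.0
        assert hypergeometric_upper_tail(5, 5, 5, 5) == pytest.approx(1.0)

    def test_small_enumeration_example(self):
        # all C(10,3)=120 draws; 4 ways to draw 3 of the 4 successes
        assert hypergeometric_upper_tail(10, 4, 3, 3) == pytest.approx(4 / 120)

    def test_tail_complements_sum_to_one(self):
        for N, K, n in [(8, 3, 4), (12, 6, 5), (9, 9, 4)]:
            for k in range(0, min(n, K) + 1):
                upper = hypergeometric_upper_tail(N, K, n, k)
                lower = sps.hypergeom.cdf(k - 1, N, K, n)
                assert upper + lower == pytest.approx(1.0, abs=1e-12)

    def test_inconsistent_counts_raise(self):
        with pytest.raises(ValueError):
            hypergeometric_upper_tail(10, 4, 3, 4)
        with pytest.raises(ValueError):
            hypergeometric_upper_tail(10, 12, 3, 1)


class TestBenjaminiHochberg:
    def test_stepup_worked_example(self):
        q = benjamini_hochberg([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_and_capped(self):
        assert benjamini_hochberg([0.3])[0] == pytest.approx(0.3)
        assert np.all(benjamini_hochberg([1.0, 1.0, 1.0]) == 1.0)

    def test_against_independent_stepup_formula(self):
        rng = np.random.default_rng(2)
        for _ in range(25):
            p = rng.uniform(size=rng.integers(1, 40))
            m = p.size
            # independent oracle: literal q_i = min over p_(j) >= p_i of m p_(j)/rank_j
            order = np.argsort(p)
            q_oracle = np.empty(m)
            running = np.inf
            for rank in range(m, 0, -1):
                running = min(running, m * p[order[rank - 1]] / rank)
                q_oracle[order[rank - 1]] = min(running, 1.0)
            assert np.allclose(benjamini_hochberg(p), q_oracle, atol=1e-14)

    def test_q_dominates_p_and_is_monotone(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=50)
        q = benjamini_hochberg(p)
        assert np.all(q >= p - 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)

    def test_nan_entries_are_excluded(self):
        q = benjamini_hochberg([0.01, np.nan, 0.04])
        assert math.isnan(q[1])
        assert q[0] == pytest.approx(0.02)

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.1, 1.2])


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        time = [1, 2, 3, 1, 2, 3]
        event = [1, 1, 0, 1, 1, 0]
        res = logrank_test(time, event, ["a"] * 3 + ["b"] * 3)
        assert res.statistic == pytest.approx(0.0)

    def test_all_censored_is_flagged(self):
        res = logrank_test([1, 2, 3, 4], [0, 0, 0, 0], ["a", "a", "b", "b"])
        assert res.p == 1.0 and res.note == "no events"

    def test_six_subject_toy_matches_risk_set_tabulation(self):
        # group A events at 1,2,3; group B events at 4,5,6 — tabulate O-E/V by hand
        time = np.array([1, 2, 3, 4, 5, 6], dtype=float)
        event = np.ones(6, dtype=bool)
        group = np.array(["A", "A", "A", "B", "B", "B"])
        o_minus_e, v = 0.0, 0.0
        for t in time:
            at = time >= t
            n, n1 = at.sum(), (at & (group == "A")).sum()
            d = 1
            o_minus_e += (group[time == t][0] == "A") - d * n1 / n
            if n > 1:
                v += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
        expected = o_minus_e**2 / v
        res = logrank_test(time, event, group)
        assert res.statistic == pytest.approx(expected, rel=1e-12)

    def test_against_lifelines(self):
        lifelines_stats = pytest.importorskip("lifelines.statistics")
        rng = np.random.default_rng(4)
        time = rng.exponential(10, size=40)
        event = rng.random(40) < 0.7
        group = np.array(["x"] * 20 + ["y"] * 20)
        res = logrank_test(time, event, group)
        ll = lifelines_stats.logrank_test(
            time[group == "x"], time[group == "y"],
            event_observed_A=event[group == "x"], event_observed_B=event[group == "y"],
        )
        assert res.statistic == pytest.approx(ll.test_statistic, rel=1e-9)
        assert res.p == pytest.approx(ll.p_value, abs=1e-9)

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            logrank_test([1, 2], [1, 1], ["a", "a"])


class TestProperties:
    """Invariant checks over generated inputs (derandomized)."""

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.lists(st.floats(0.01, 0.99), min_size=2, max_size=30),
           st.floats(0.1, 50.0))
    def test_cv_scale_invariance(self, xs, c):
        x = np.asarray(xs)
        assert coefficient_of_variation(c * x) == pytest.approx(
            coefficient_of_variation(x), rel=1e-9, abs=1e-12
        )

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=40))
    def test_bh_dominates_p_and_respects_order(self, ps):
        p = np.asarray(ps)
        q = benjamini_hochberg(p)
        assert np.all(q >= p - 1e-12)
        assert np.all(q <= 1.0)
        order = np.argsort(p, kind="mergesort")
        assert np.all(np.diff(q[order]) >= -1e-12)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.lists(st.floats(-100, 100), min_size=3, max_size=25, unique=True),
           st.lists(st.floats(-100, 100), min_size=3, max_size=25, unique=True))
    def test_spearman_bounded_and_symmetric(self, xs, ys):
        n = min(len(xs), len(ys))
        x, y = np.asarray(xs[:n]), np.asarray(ys[:n])
        r = spearman_rho(x, y)
        if not math.isnan(r):
            assert -1.0 - 1e-12 <= r <= 1.0 + 1e-12
            assert spearman_rho(y, x) == pytest.approx(r, abs=1e-12)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(st.integers(1, 40), st.integers(0, 40), st.integers(0, 40),
           st.integers(0, 40))
    def test_hypergeom_tail_is_probability_and_antitone(self, N, K, n, k):
        K, n = min(K, N), min(n, N)
        k = min(k, min(n, K))
        p = hypergeometric_upper_tail(N, K, n, k)
        assert 0.0 <= p <= 1.0
        if k > 0:
            assert p <= hypergeometric_upper_tail(N, K, n, k - 1) + 1e-12


def _newton_unpenalized_cox(x, time, event, tol=1e-12):
    """Independent Newton-Raphson oracle for a single-covariate Cox model
    (Breslow ties), derived directly from the partial likelihood."""
    x = np.asarray(x, dtype=float)
    beta = 0.0
    for _ in range(100):
        grad, hess = 0.0, 0.0
        for t in np.unique(np.asarray(time, float)[np.asarray(event, bool)]):
            risk = np.asarray(time, float) >= t
            d = int((np.asarray(event, bool) & (np.asarray(time, float) == t)).sum())
            w = np.exp(beta * x[risk])
            xb = (x[risk] * w).sum() / w.sum()
            x2b = (x[risk] ** 2 * w).sum() / w.sum()
            grad += x[np.asarray(event, bool) & (np.asarray(time, float) == t)].sum() - d * xb
            hess += d * (x2b - xb**2)
        step = grad / hess
        beta += step
        if abs(step) < tol:
            break
    return beta


class TestPenalizedCox:
    def test_constant_feature_gets_zero(self):
        rng = np.random.default_rng(0)
        X = np.column_stack([np.ones(20), rng.normal(size=20)])
        b = penalized_cox_fit(X, rng.exponential(5, 20), rng.random(20) < 0.8,
                              l1_ratio=0.5, lam=0.1)
        assert b[0] == 0.0

    def test_huge_penalty_zeroes_everything(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(25, 4))
        b = penalized_cox_fit(X, rng.exponential(5, 25), np.ones(25, bool),
                              l1_ratio=1.0, lam=1e6)
        assert np.all(b == 0.0)

    def test_unpenalized_single_binary_feature_matches_newton_oracle(self):
        time = np.array([2.0, 4.0, 5.0, 7.0, 9.0, 12.0, 15.0, 20.0])
        event = np.array([1, 1, 0, 1, 1, 0, 1, 1], dtype=bool)
        x = np.array([1.0, 0.0, 1.0, 0.0, 1.0, 1.0, 0.0, 0.0])
        expected = _newton_unpenalized_cox(x, time, event)
        b = penalized_cox_fit(x[:, None], time, event, l1_ratio=0.1, lam=0.0,
                              tol=1e-12, max_iter=2000)
        assert b[0] == pytest.approx(expected, abs=1e-6)

    def test_matches_scikit_survival_coxnet(self):
        sksurv_lm = pytest.importorskip("sksurv.linear_model")
        rng = np.random.default_rng(2)
        n, p = 50, 6
        X = rng.normal(size=(n, p))
        time = rng.exponential(np.exp(-0.5 * X[:, 0]), n) + 0.01
        event = rng.random(n) < 0.8
        lam = 2.0
        b = penalized_cox_fit(X, time, event, l1_ratio=0.3, lam=lam,
                              standardize=False, tol=1e-9)
        y = np.array([(bool(e), t) for e, t in zip(event, time)],
                     dtype=[("event", "?"), ("time", "<f8")])
        m = sksurv_lm.CoxnetSurvivalAnalysis(
            l1_ratio=0.3, alphas=[lam / n], normalize=False, tol=1e-12
        )
        m.fit(X, y)
        assert np.allclose(b, m.coef_[:, 0], atol=1e-4)

    def test_returned_solution_beats_zero_objective(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(30, 5))
        time = rng.exponential(np.exp(-X[:, 0]), 30) + 0.01
        event = np.ones(30, bool)
        lam, l1 = 1.0, 0.2
        b = penalized_cox_fit(X, time, event, l1_ratio=l1, lam=lam, standardize=False)

        def obj(bb):
            pen = lam * (l1 * np.abs(bb).sum() + 0.5 * (1 - l1) * (bb**2).sum())
            return -cox_partial_loglik(X @ bb, time, event) + pen

        assert obj(b) <= obj(np.zeros(5)) + 1e-9

    def test_missing_values_and_no_events_raise(self):
        X = np.ones((6, 2))
        X[0, 0] = np.nan
        with pytest.raises(ValueError):
            penalized_cox_fit(X, np.arange(1, 7), np.ones(6, bool), lam=0.1)
        with pytest.raises(ValueError):
            penalized_cox_fit(np.ones((6, 2)), np.arange(1, 7), np.zeros(6, bool), lam=0.1)
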