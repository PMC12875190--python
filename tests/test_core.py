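"""Tests for the paired-permutation engine."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import robustpalmrt as rp
from conftest import make_problem


class TestSamplePermutations:
    def test_s1_has_only_the_identity(self):
        ps = rp.sample_permutations(1, 3, seed=0)
        assert ps.perms.shape == (3, 1)
        assert np.all(ps.perms == 0)

    def test_seeded_determinism(self):
        a = rp.sample_permutations(5, 100, seed=7)
        b = rp.sample_permutations(5, 100, seed=7)
        assert np.array_equal(a.perms, b.perms)

    def test_uniform_over_s4(self):
        """Each of the 24 permutations of S4 appears with frequency 1/24
        within 4 Monte-Carlo standard errors."""
        B = 10000
        ps = rp.sample_permutations(4, B, seed=1)
        codes = ps.perms @ np.array([64, 16, 4, 1])
        _, counts = np.unique(codes, return_counts=True)
        assert counts.size == 24
        freq = counts / B
        se = np.sqrt((1 / 24) * (23 / 24) / B)
        assert np.max(np.abs(freq - 1 / 24)) < 4 * se

    @pytest.mark.parametrize("n,B", [(0, 5), (5, 0), (-1, 3)])
    def test_invalid_arguments(self, n, B):
        with pytest.raises(ValueError):
            rp.sample_permutations(n, B, seed=0)


class TestPvalueFromScores:
    @pytest.mark.parametrize(
        "orig,perm,expected",
        [
            ((1, 1, 1, 1), (2, 2, 2, 2), 1 / 5),
            ((2, 2), (2, 3), 2 / 3),
            (tuple(range(9)), tuple(range(9)), 1.0),
        ],
    )
    def test_examples(self, orig, perm, expected):
        assert rp.pvalue_from_scores(np.array(orig, float), np.array(perm, float)) == pytest.approx(expected)

    @given(st.lists(st.tuples(st.floats(-1e6, 1e6), st.floats(-1e6, 1e6)), min_size=1, max_size=50))
    @settings(deadline=None, derandomize=True)
    def test_matches_brute_force_loop(self, pairs):
        orig = np.array([a for a, _ in pairs])
        perm = np.array([b for _, b in pairs])
        count = 0
        for a, b in pairs:
            if a >= b:
                count += 1
        assert rp.pvalue_from_scores(orig, perm) == pytest.approx((1 + count) / (1 + len(pairs)))

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            rp.pvalue_from_scores(np.array([1.0]), np.array([1.0, 2.0]))
        with pytest.raises(ValueError):
            rp.pvalue_from_scores(np.array([np.nan]), np.array([1.0]))


class TestRunTest:
    def test_perfect_null_fit_scores_vanish(self, rng):
        """Y exactly in the span of Z: every OLS residual vector is zero
        (to machine precision), so all paired L2 scores vanish.  In exact
        arithmetic every comparison would tie and the p-value would be 1;
        in floating point the scores agree only to ~1e-28, and with exact
        tie detection (no tolerance, by design) the comparison outcomes
        for these sub-epsilon scores are arbitrary -- the p-value stays
        valid because the noise is symmetric between the pair members."""
        n = 20
        Z = np.column_stack([np.ones(n), rng.standard_normal(n)])
        Y = Z @ np.array([2.0, -1.0])
        X = rng.standard_normal((n, 1))
        prob = rp.RegressionProblem(Y, X, Z)
        perms = rp.sample_permutations(n, 30, seed=0)
        res = rp.run_test(prob, "ols", "l2", perms)
        assert np.all(res.omega_orig < 1e-20)
        assert np.all(res.omega_perm < 1e-20)

    def test_deterministic_given_permutations(self):
        prob = make_problem(seed=3)
        perms = rp.sample_permutations(prob.n, 50, seed=9)
        r1 = rp.run_test(prob, "huber", "huber", perms)
        r2 = rp.run_test(prob, "huber", "huber", perms)
        assert r1.pvalue == r2.pvalue
        assert np.array_equal(r1.omega_orig, r2.omega_orig)

    @pytest.mark.parametrize("fitter,evaluator", [("ols", "l2"), ("ols", "huber"),
                                                  ("huber", "huber"), ("quantile", "l1")])
    def test_batched_path_matches_per_pair_loop(self, fitter, evaluator):
        """The vectorized fit_pair_batch path and the generic per-permutation
        loop produce identical paired scores."""

        class NoBatch:
            def __init__(self, inner):
                self.inner = inner

            def fit(self, Y, X, Zaug):
                return self.inner.fit(Y, X, Zaug)

        prob = make_problem(n=25, p=3, seed=11)
        perms = rp.sample_permutations(prob.n, 20, seed=2)
        f = rp.get_fitter(fitter)
        fast = rp.run_test(prob, f, evaluator, perms)
        slow = rp.run_test(prob, NoBatch(f), evaluator, perms)
        np.testing.assert_allclose(fast.omega_orig, slow.omega_orig, rtol=1e-9, atol=1e-10)
        np.testing.assert_allclose(fast.omega_perm, slow.omega_perm, rtol=1e-9, atol=1e-10)
        assert fast.pvalue == slow.pvalue

    @pytest.mark.parametrize("fitter,evaluator", [("ols", "l2"), ("huber", "huber")])
    def test_shift_invariance_end_to_end(self, fitter, evaluator, rng):
        """Adding Z theta to the response leaves every paired score, and
        hence the p-value, unchanged."""
        prob = make_problem(n=30, p=4, seed=5)
        theta = rng.standard_normal(prob.p) * 10
        shifted = rp.RegressionProblem(prob.Y + prob.Z @ theta, prob.X, prob.Z)
        perms = rp.sample_permutations(prob.n, 40, seed=4)
        a = rp.run_test(prob, fitter, evaluator, perms)
        b = rp.run_test(shifted, fitter, evaluator, perms)
        np.testing.assert_allclose(a.omega_orig, b.omega_orig, atol=1e-8)
        np.testing.assert_allclose(a.omega_perm, b.omega_perm, atol=1e-8)
        assert a.pvalue == b.pvalue

    def test_symmetry_identity(self, rng):
        """The comparison array T(p1, p2; eps) = omega(M(eps, X_{p2},
        [Z_{p1}, Z_{p2}])) satisfies the exchangeability identity
        T(p1, p2; eps_sigma) = T(p1 o sigma^-1, p2 o sigma^-1; eps) that
        underpins the finite-sample guarantee."""
        n, p = 25, 3
        Z = np.column_stack([np.ones(n), rng.standard_normal((n, p - 1))])
        X = rng.standard_normal((n, 1))
        f = rp.HuberFitter()
        ev = rp.ScaledHuberEvaluator()

        def T(p1, p2, err):
            Zaug = np.concatenate([Z[p1], Z[p2]], axis=1)
            return ev(f.fit(err, X[p2], Zaug))

        for _ in range(5):
            eps = rng.standard_normal(n)
            p1, p2, sig = rng.permutation(n), rng.permutation(n), rng.permutation(n)
            inv = np.argsort(sig)
            assert T(p1, p2, eps[sig]) == pytest.approx(T(p1[inv], p2[inv], eps), abs=1e-8)

    def test_permutation_length_mismatch(self):
        prob = make_problem(n=20)
        perms = rp.sample_permutations(21, 5, seed=0)
        with pytest.raises(ValueError):
            rp.run_test(prob, "ols", "l2", perms)

    def test_pvalue_floor(self):
        """The p-value can never drop below 1/(B+1)."""
        prob = make_problem(n=40, beta=50.0, seed=8)
        perms = rp.sample_permutations(prob.n, 19, seed=1)
        res = rp.run_test(prob, "ols", "l2", perms)
        assert res.pvalue >= 1 / 20


class TestInvertCI:
    def test_response_shift_moves_endpoints_exactly(self, rng):
        """Replacing Y by Y + X c shifts the interval by exactly c when the
        grid is shifted by c (the tested residuals are identical)."""
        prob = make_problem(n=40, p=3, beta=1.0, seed=6)
        perms = rp.sample_permutations(prob.n, 99, seed=3)
        grid = np.linspace(-3, 5, 41)
        c = 2.5
        ci1 = rp.invert_ci(prob, "ols", "l2", perms, alpha=0.05, beta_grid=grid)
        shifted = rp.RegressionProblem(prob.Y + prob.X[:, 0] * c, prob.X, prob.Z)
        ci2 = rp.invert_ci(shifted, "ols", "l2", perms, alpha=0.05, beta_grid=grid + c)
        assert ci2.lo == pytest.approx(ci1.lo + c)
        assert ci2.hi == pytest.approx(ci1.hi + c)
        np.testing.assert_array_equal(ci1.pvalues_on_grid, ci2.pvalues_on_grid)

    def test_alpha_zero_accepts_whole_grid(self):
        prob = make_problem(n=25, seed=2)
        perms = rp.sample_permutations(prob.n, 19, seed=5)
        grid = np.linspace(-4, 4, 9)
        ci = rp.invert_ci(prob, "ols", "l2", perms, alpha=0.0, beta_grid=grid)
        assert (ci.lo, ci.hi) == (grid[0], grid[-1])
        assert not ci.empty

    def test_coverage_of_true_effect(self):
        """The acceptance region {beta*: p(beta*) > alpha} contains the
        true beta with probability >= 1 - 2 alpha; the reported interval is
        its convex hull, so interval coverage can only be higher.  Checked
        by testing H0 on Y - X beta_true per replicate."""
        hits = 0
        n_reps = 200
        for i in range(n_reps):
            prob = make_problem(n=50, p=3, beta=1.0, seed=1000 + i)
            shifted = rp.RegressionProblem(prob.Y - prob.X[:, 0], prob.X, prob.Z)
            perms = rp.sample_permutations(prob.n, 99, seed=2000 + i)
            if rp.run_test(shifted, "ols", "l2", perms).pvalue > 0.05:
                hits += 1
        assert hits / n_reps >= 0.90

    def test_requires_scalar_covariate(self):
        prob = make_problem(n=30, d=2)
        perms = rp.sample_permutations(prob.n, 9, seed=0)
        with pytest.raises(ValueError):
            rp.invert_ci(prob, "ols", "l2", perms)


class TestRegressionProblem:
    def test_validation(self, rng):
        with pytest.raises(ValueError):
            rp.RegressionProblem(np.ones(2), np.ones((2, 1)), np.ones((2, 1)))
        with pytest.raises(ValueError):
            rp.RegressionProblem(np.ones(5), np.ones((4, 1)), np.ones((5, 1)))
        with pytest.raises(ValueError):
            rp.RegressionProblem(np.array([1.0, np.nan, 3.0]), np.ones((3, 1)), np.ones((3, 1)))

    def test_type_i_error_bounded_under_null(self):
        """Monte-Carlo check of the finite-sample 2*alpha bound (and the
        empirically observed <= alpha behavior) for the OLS-L2 pairing."""
        alpha = 0.05
        n_reps = 300
        rej = 0
        for i in range(n_reps):
            prob = make_problem(n=50, p=2, beta=0.0, seed=5000 + i, design="cauchy")
            perms = rp.sample_permutations(prob.n, 99, seed=6000 + i)
            rej += rp.run_test(prob, "ols", "l2", perms).pvalue <= alpha
        rate = rej / n_reps
        se = np.sqrt(2 * alpha * (1 - 2 * alpha) / n_reps)
        assert rate <= 2 * alpha + 3 * se
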