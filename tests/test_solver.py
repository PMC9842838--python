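"""MBAR solver: fixed-point structure, Newton acceleration, invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import mbarkit as mk
from mbarkit import ConvergenceError, InputError
from mbarkit.solver import newton_step, self_consistent_step
from mbarkit import synthetic as syn
from mbarkit.uncertainty import bootstrap_se


def reference_fixed_point(u, counts, tol=1e-12, start=None, max_iter=200000):
    """Independent plain fixed-point iteration, written from the equations.

    Deliberately naive (direct exponentials with a max-shift, no Newton, no
    shared code path) so it can serve as an oracle for the production solver.
    """
    u = np.asarray(u, dtype=float)
    counts = np.asarray(counts, dtype=float)
    k = u.shape[0]
    f = np.zeros(k) if start is None else np.asarray(start, dtype=float)
    for _ in range(max_iter):
        shift = (f[:, None] - u).max(axis=0)
        denom = np.log(
            np.sum(
                counts[:, None] * np.exp(f[:, None] - u - shift[None, :]),
                axis=0,
            )
        ) + shift
        f_new = np.empty(k)
        for i in range(k):
            w = -u[i] - denom
            m = w.max()
            f_new[i] = -(m + np.log(np.exp(w - m).sum()))
        f_new -= f_new[0]
        if np.max(np.abs(f_new - f)) < tol:
            return f_new
        f = f_new
    raise RuntimeError("reference iteration did not converge")


def random_instance(rng, k=None, n_max=200):
    k = k or rng.integers(2, 5)
    counts = rng.integers(10, n_max // k + 10, size=k)
    centers = rng.uniform(-1.0, 1.0, size=k)
    sigmas = rng.uniform(0.7, 1.5, size=k)
    pooled = np.concatenate(
        [rng.normal(centers[i], sigmas[i], counts[i]) for i in range(k)]
    )
    u = np.vstack(
        [(pooled - centers[i]) ** 2 / (2 * sigmas[i] ** 2) for i in range(k)]
    )
    return u, counts


class TestSolveMbar:
    def test_single_state_is_anchored_zero(self):
        u = np.random.default_rng(0).normal(size=(1, 50))
        res = mk.solve_mbar(u, [50])
        assert res.f_hat[0] == 0.0
        assert res.converged

    def test_identical_states_give_zero_difference(self):
        rng = np.random.default_rng(1)
        row = rng.normal(size=100)
        res = mk.solve_mbar(np.vstack([row, row]), [50, 50])
        assert res.delta_f(1) == pytest.approx(0.0, abs=1e-12)

    def test_two_state_gaussian_recovers_log_sigma_ratio(self):
        """sigma=(1,2): analytic df = -ln 2, confirmed independently by
        quadrature of the Gaussian configuration integral; the estimate must
        land within 3 bootstrap SE."""
        ds = syn.gen_harmonic_states([1.0, 2.0], n_samples=10000, seed=42)
        analytic = ds.f_analytic[1] - ds.f_analytic[0]
        x = np.linspace(-30, 30, 200001)
        quad = -(
            np.log(np.trapezoid(np.exp(-x**2 / 8.0), x))
            - np.log(np.trapezoid(np.exp(-x**2 / 2.0), x))
        )
        assert analytic == pytest.approx(-np.log(2.0))
        assert quad == pytest.approx(analytic, abs=1e-10)

        res = mk.solve_mbar(ds.matrix)

        def estimator(idx, counts):
            r = mk.solve_mbar(ds.matrix.u[:, idx], counts,
                              initial_f=res.f_hat, compute_ess=False)
            return r.f_hat[1]

        se, _ = bootstrap_se(estimator, ds.matrix.counts, 50, seed=7)
        assert abs(res.delta_f(1) - analytic) < 3 * se

    def test_matches_independent_fixed_point_iteration(self):
        """Production solver vs a naive fixed-point oracle started elsewhere."""
        rng = np.random.default_rng(5)
        for _ in range(8):
            u, counts = random_instance(rng)
            res = mk.solve_mbar(u, counts, compute_ess=False)
            start = np.concatenate([[0.0], rng.uniform(-2, 2, len(counts) - 1)])
            ref = reference_fixed_point(u, counts, start=start)
            np.testing.assert_allclose(res.f_hat, ref, atol=1e-7)

    def test_nonconvergence_carries_residual_trace(self):
        u, counts = random_instance(np.random.default_rng(8), k=3)
        with pytest.raises(ConvergenceError) as err:
            mk.solve_mbar(u, counts, max_iterations=2, tolerance=1e-14)
        assert len(err.value.residual_trace) == 2

    def test_all_infinite_column_rejected(self):
        u = np.array([[0.0, np.inf], [0.0, np.inf]])
        with pytest.raises(InputError, match="infinite"):
            mk.solve_mbar(u, [1, 1])

    def test_inf_entries_are_benign(self):
        """+inf reduced potentials contribute zero weight, nothing more."""
        rng = np.random.default_rng(9)
        u, counts = random_instance(rng, k=2)
        u_inf = u.copy()
        u_inf[1, 0] = np.inf  # one unreachable configuration for state 2
        res = mk.solve_mbar(u_inf, counts, compute_ess=False)
        assert np.isfinite(res.f_hat).all()

    def test_low_overlap_warns_on_ess(self):
        """An appended target far from the sampled state has tiny ESS."""
        rng = np.random.default_rng(3)
        x = rng.normal(0.0, 1.0, 200)
        u = np.vstack([x**2 / 2.0, (x - 6.0) ** 2 / 2.0])
        with pytest.warns(UserWarning, match="effective sample size"):
            mk.solve_mbar(u, [200, 0])


class TestSteps:
    def test_self_consistent_step_fixed_at_solution(self):
        u, counts = random_instance(np.random.default_rng(11), k=3)
        res = mk.solve_mbar(u, counts, tolerance=1e-13, compute_ess=False)
        stepped = self_consistent_step(res.f_hat, u, counts)
        np.testing.assert_allclose(stepped, res.f_hat, atol=1e-12)

    def test_uniform_potentials_stay_at_zero(self):
        f = self_consistent_step(np.zeros(3), np.zeros((3, 30)), [10, 10, 10])
        np.testing.assert_allclose(f, 0.0, atol=1e-14)

    def test_single_state_step_returns_zero(self):
        f = self_consistent_step(
            np.zeros(1), np.random.default_rng(0).normal(size=(1, 10)), [10]
        )
        np.testing.assert_allclose(f, [0.0])

    def test_newton_zero_update_at_solution(self):
        u, counts = random_instance(np.random.default_rng(12), k=3)
        res = mk.solve_mbar(u, counts, tolerance=1e-13, compute_ess=False)
        stepped = newton_step(res.f_hat, u, counts)
        np.testing.assert_allclose(stepped, res.f_hat, atol=1e-10)

    def test_newton_contracts_quadratically_near_solution(self):
        ds = syn.gen_harmonic_states([1.0, 2.0, 3.0], n_samples=2000, seed=21)
        u, counts = ds.matrix.u, ds.matrix.counts
        sol = mk.solve_mbar(u, counts, tolerance=1e-13, compute_ess=False)
        f = sol.f_hat + np.array([0.0, 1e-2, -1e-2])
        residuals = [mk.residual(f, u, counts)]
        for _ in range(3):
            f = newton_step(f, u, counts)
            residuals.append(mk.residual(f, u, counts))
        # r_{t+1} <= C r_t^2 with a generous constant
        assert residuals[1] <= 100 * residuals[0] ** 2
        assert residuals[2] <= 100 * residuals[1] ** 2 + 1e-13

    def test_hybrid_beats_pure_self_consistency(self):
        """On a 3-state Gaussian toy the Newton phase reaches 1e-8 in fewer
        sweeps than plain fixed-point iteration from the same start."""
        ds = syn.gen_harmonic_states([1.0, 2.0, 3.0], n_samples=2000, seed=22)
        u, counts = ds.matrix.u, ds.matrix.counts
        res = mk.solve_mbar(u, counts, tolerance=1e-8, compute_ess=False)
        f = np.zeros(3)
        n_sc = 0
        while mk.residual(f, u, counts) > 1e-8:
            f = self_consistent_step(f, u, counts)
            n_sc += 1
            assert n_sc < 100000
        assert res.n_iterations < n_sc


class TestInvariants:
    def test_weight_normalization_per_sampled_state(self):
        u, counts = random_instance(np.random.default_rng(31), k=4)
        res = mk.solve_mbar(u, counts, compute_ess=False)
        for k in range(4):
            w = np.exp(res.f_hat[k] - u[k] - res.log_denominator)
            assert w.sum() == pytest.approx(1.0, abs=1e-8)

    def test_gauge_row_shift_moves_only_that_state(self):
        u, counts = random_instance(np.random.default_rng(32), k=3)
        res = mk.solve_mbar(u, counts, tolerance=1e-12, compute_ess=False)
        c = 1.7
        u2 = u.copy()
        u2[2] += c
        res2 = mk.solve_mbar(u2, counts, tolerance=1e-12, compute_ess=False)
        np.testing.assert_allclose(res2.f_hat[:2], res.f_hat[:2], atol=1e-9)
        assert res2.f_hat[2] - res.f_hat[2] == pytest.approx(c, abs=1e-9)

    def test_permutation_equivariance(self):
        u, counts = random_instance(np.random.default_rng(33), k=4)
        res = mk.solve_mbar(u, counts, tolerance=1e-12, compute_ess=False)
        perm = np.array([2, 0, 3, 1])
        # permute states; samples must be reordered to keep counts aligned
        offsets = np.concatenate([[0], np.cumsum(counts)])
        sample_order = np.concatenate(
            [np.arange(offsets[p], offsets[p + 1]) for p in perm]
        )
        res_p = mk.solve_mbar(
            u[np.ix_(perm, sample_order)], counts[perm],
            tolerance=1e-12, compute_ess=False,
        )
        expected = res.f_hat[perm] - res.f_hat[perm][0]
        np.testing.assert_allclose(res_p.f_hat, expected, atol=1e-9)

    def test_residual_gauge_invariance(self):
        u, counts = random_instance(np.random.default_rng(34), k=3)
        f = np.array([0.0, 0.3, -0.2])
        r1 = mk.residual(f, u, counts)
        shifted = f + 5.0
        shifted -= shifted[0]
        r2 = mk.residual(shifted, u, counts)
        assert r1 == pytest.approx(r2, rel=1e-12)

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_random_instances_match_oracle(self, seed):
        u, counts = random_instance(np.random.default_rng(seed))
        res = mk.solve_mbar(u, counts, compute_ess=False)
        ref = reference_fixed_point(u, counts)
        np.testing.assert_allclose(res.f_hat, ref, atol=1e-7)
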