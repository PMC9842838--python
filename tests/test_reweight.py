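"""Target-state reweighting: weights, free energies, averages, PMFs."""

import numpy as np
import pytest

import mbarkit as mk
from mbarkit import InputError, OverlapError
from mbarkit import synthetic as syn
from mbarkit.reweight import _pmf_raw, log_form_expectation
from mbarkit.solver import effective_sample_sizes

from conftest import UMBRELLA, UMBRELLA_EDGES, align


@pytest.fixture(scope="module")
def gaussian_pair():
    ds = syn.gen_harmonic_states([1.0, 2.0], n_samples=4000, seed=17)
    res = mk.solve_mbar(ds.matrix)
    pooled = np.concatenate(ds.samples)
    return ds, res, pooled


class TestTargetWeights:
    def test_single_state_weights_are_uniform(self):
        rng = np.random.default_rng(0)
        u = rng.normal(size=(1, 100))
        res = mk.solve_mbar(u, [100])
        logw = mk.target_log_weights(res, u[0])
        np.testing.assert_allclose(np.exp(logw), 1.0 / 100, atol=1e-12)

    def test_constant_shift_leaves_weights_unchanged(self, gaussian_pair):
        ds, res, pooled = gaussian_pair
        u_t = pooled**2 / 2.0
        w1 = mk.target_log_weights(res, u_t)
        w2 = mk.target_log_weights(res, u_t + 11.0)
        np.testing.assert_allclose(w1, w2, atol=1e-12)

    def test_no_overlap_raises(self, gaussian_pair):
        ds, res, pooled = gaussian_pair
        with pytest.raises(OverlapError):
            mk.target_log_weights(res, np.full_like(pooled, np.inf))

    def test_wrong_length_rejected(self, gaussian_pair):
        ds, res, _ = gaussian_pair
        with pytest.raises(InputError):
            mk.target_log_weights(res, np.zeros(3))

    def test_sampled_target_has_higher_ess_than_narrow_extrapolation(
        self, gaussian_pair
    ):
        """Extrapolating to a state narrower than anything sampled must cost
        effective samples relative to re-querying a sampled state."""
        ds, res, pooled = gaussian_pair

        def ess_of(u_t):
            logw = mk.target_log_weights(res, u_t)
            return 1.0 / np.exp(
                np.logaddexp.reduce(2.0 * logw)
            )

        ess_sampled = ess_of(pooled**2 / 2.0)
        ess_narrow = ess_of(pooled**2 / (2.0 * 0.25**2))
        assert ess_sampled >= ess_narrow


class TestTargetFreeEnergy:
    def test_sampled_state_row_recovers_f_hat_exactly(self, gaussian_pair):
        ds, res, _ = gaussian_pair
        for i in range(2):
            assert mk.target_free_energy(res, ds.matrix.u[i]) == pytest.approx(
                res.f_hat[i], abs=1e-9
            )

    def test_shifted_row_shifts_f(self, gaussian_pair):
        ds, res, _ = gaussian_pair
        f = mk.target_free_energy(res, ds.matrix.u[1] + 2.5)
        assert f == pytest.approx(res.f_hat[1] + 2.5, abs=1e-9)

    def test_unrestrained_target_matches_quadrature(self, umbrella_study):
        """Free-energy gap between the unrestrained ensemble and window 1
        agrees with direct 1-D quadrature within 3 bootstrap SE."""
        st = umbrella_study
        pot, beta = st["potential"], UMBRELLA["beta"]
        u0 = np.zeros(st["matrix"].n_total)
        est = mk.target_free_energy(st["result"], u0)  # minus f_1 = 0 anchor

        w1 = syn.harmonic(k=UMBRELLA["spring_k"], center=-1.4)
        grid = np.linspace(-3.5, 3.5, 40001)
        f_free = -np.log(np.trapezoid(np.exp(-beta * pot.energy(grid)), grid))
        f_w1 = -np.log(
            np.trapezoid(
                np.exp(-beta * (pot.energy(grid) + w1.energy(grid))), grid
            )
        )
        ref = f_free - f_w1

        def estimator(idx, counts):
            r = mk.solve_mbar(st["matrix"].u[:, idx], counts,
                              initial_f=st["result"].f_hat, compute_ess=False)
            return mk.target_free_energy(r, u0[idx])

        se, _ = mk.bootstrap_se(estimator, st["matrix"].counts, 30, seed=5)
        assert abs(est - ref) < 3 * max(se, 1e-3)


class TestExpectation:
    def test_constant_observables(self, gaussian_pair):
        ds, res, pooled = gaussian_pair
        u_t = pooled**2 / 2.0
        assert mk.expectation(res, u_t, np.ones_like(pooled)) == pytest.approx(1.0)
        assert mk.expectation(res, u_t, np.full_like(pooled, 3.3)) == pytest.approx(3.3)

    def test_single_state_reduces_to_arithmetic_mean(self):
        rng = np.random.default_rng(2)
        u = rng.normal(size=(1, 500))
        a = rng.normal(size=500)
        res = mk.solve_mbar(u, [500])
        assert mk.expectation(res, u[0], a) == pytest.approx(a.mean())

    def test_log_form_equivalence_for_positive_observable(self, gaussian_pair):
        """<A> via direct weighting equals the two-free-energy form for A>0."""
        ds, res, pooled = gaussian_pair
        u_t = pooled**2 / 2.0
        a = np.exp(-np.abs(pooled))
        direct = mk.expectation(res, u_t, a)
        via_logs = log_form_expectation(res, u_t, a)
        assert direct == pytest.approx(via_logs, rel=1e-10)

    def test_second_moment_of_gaussian_target(self, gaussian_pair):
        """<x^2> under the sigma=1 target should be near 1."""
        ds, res, pooled = gaussian_pair
        est = mk.expectation(res, pooled**2 / 2.0, pooled**2)
        assert est == pytest.approx(1.0, abs=0.1)


class TestComputePmf:
    def test_uniform_weights_equal_occupancy_is_flat(self):
        x = np.linspace(0.0, 1.0, 1000, endpoint=False) + 0.0005
        u = np.zeros((1, 1000))
        res = mk.solve_mbar(u, [1000])
        prof = mk.compute_pmf(res, u[0], x, np.linspace(0, 1, 11))
        np.testing.assert_allclose(prof.pmf, 0.0, atol=1e-12)
        assert not prof.empty.any()

    def test_empty_bin_flagged_and_excluded(self):
        x = np.array([0.1, 0.15, 0.9, 0.95])
        u = np.zeros((1, 4))
        res = mk.solve_mbar(u, [4])
        prof = mk.compute_pmf(res, u[0], x, np.array([0.0, 0.25, 0.5, 1.0]))
        assert prof.empty.tolist() == [False, True, False]
        assert np.isnan(prof.pmf[1])
        assert np.nanmin(prof.pmf) == 0.0

    def test_all_bins_empty_raises(self):
        x = np.array([5.0, 6.0])
        u = np.zeros((1, 2))
        res = mk.solve_mbar(u, [2])
        with pytest.raises(InputError):
            mk.compute_pmf(res, u[0], x, np.array([0.0, 1.0]))

    def test_weight_partition_before_shift(self, gaussian_pair):
        """Bin weights are a partition: sum_b exp(-raw_b) = 1 when the bins
        cover every sample."""
        ds, res, pooled = gaussian_pair
        logw = mk.target_log_weights(res, pooled**2 / 2.0)
        edges = np.linspace(pooled.min() - 0.1, pooled.max() + 0.1, 31)
        raw, _, empty = _pmf_raw(logw, pooled, edges)
        assert np.nansum(np.exp(-raw[~empty])) == pytest.approx(1.0, abs=1e-10)

    def test_split_origin_state_invariance(self):
        """Presenting one origin state's samples as two duplicate states with
        the counts split between them must not move the other free energies
        or the PMF (the estimator sees the same mixture distribution)."""
        ds = syn.gen_harmonic_states([1.0, 1.5], n_samples=1000, seed=23)
        res = mk.solve_mbar(ds.matrix, tolerance=1e-12)
        pooled = np.concatenate(ds.samples)
        u = ds.matrix.u
        u_split = np.vstack([u[0], u[0], u[1]])
        res2 = mk.solve_mbar(u_split, [600, 400, 1000], tolerance=1e-12)
        # duplicate rows share one free energy; the last state is unmoved
        assert res2.f_hat[1] == pytest.approx(0.0, abs=1e-10)
        assert res2.f_hat[2] == pytest.approx(res.f_hat[1], abs=1e-10)
        edges = np.linspace(-3, 3, 25)
        u_t = pooled**2 / 2.0
        p1 = mk.compute_pmf(res, u_t, pooled, edges)
        p2 = mk.compute_pmf(res2, u_t, pooled, edges)
        np.testing.assert_allclose(p1.pmf, p2.pmf, atol=1e-10)

    def test_umbrella_pmf_matches_quadrature(self, umbrella_study):
        st = umbrella_study
        prof = mk.compute_pmf(
            st["result"], np.zeros(st["matrix"].n_total), st["cv"],
            UMBRELLA_EDGES,
        )
        ref = syn.pmf_reference(st["potential"], UMBRELLA["beta"],
                                UMBRELLA_EDGES)
        ok = prof.eff_count >= 50
        assert np.max(np.abs(align(prof.pmf, ref, ok))) < 0.1

    def test_two_dimensional_pmf_plumbing(self):
        samples, _ = syn.gen_periodic_2d(n_samples=3000, seed=6)
        u = np.zeros((1, 3000))
        res = mk.solve_mbar(u, [3000])
        edges = (np.linspace(0, 360, 13), np.linspace(0, 360, 13))
        prof = mk.compute_pmf(res, u[0], samples, edges)
        assert prof.pmf.shape == (12, 12)
        assert prof.ndim == 2
        assert np.nanmin(prof.pmf) == 0.0
        frame = prof.to_frame()
        assert len(frame) == 144

    def test_three_dimensions_rejected(self):
        u = np.zeros((1, 10))
        res = mk.solve_mbar(u, [10])
        with pytest.raises(InputError):
            mk.compute_pmf(res, u[0], np.zeros((10, 3)),
                           (np.linspace(0, 1, 3),) * 3)

    def test_kcal_conversion(self):
        x = np.concatenate([np.full(5, 0.1), np.full(5, 0.9)])
        u = np.zeros((1, 10))
        res = mk.solve_mbar(u, [10])
        prof = mk.compute_pmf(res, u[0], x, np.array([0.0, 0.5, 1.0]))
        kcal = prof.in_kcal_mol(300.0)
        np.testing.assert_allclose(
            kcal, prof.pmf * mk.KB_KCAL_MOL_K * 300.0
        )


class TestCostFraction:
    @pytest.mark.parametrize(
        "n,total,expected", [(2000, 30000, 6.7), (5000, 30000, 16.7)]
    )
    def test_single_point_reweighting_cost(self, n, total, expected):
        assert mk.reweighting_cost_fraction(n, total) == pytest.approx(
            expected, abs=0.05
        )

    def test_invalid_counts(self):
        with pytest.raises(InputError):
            mk.reweighting_cost_fraction(10, 0)
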