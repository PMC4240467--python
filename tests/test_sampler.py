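import numpy as np
import pytest

import commlda
from commlda import AbundanceMatrix, ModelSpec
from commlda.sampler import (
    AssignmentState,
    credible_interval,
    expand_to_tokens,
    gibbs_conditional,
    log_likelihood,
    point_estimates,
    relabel,
    run_gibbs,
)

from conftest import match_to_truth


class TestExpandToTokens:
    def test_direct_expansion(self):
        m = AbundanceMatrix(np.array([[2, 0], [0, 1]]))
        tu, ts = expand_to_tokens(m)
        assert list(zip(tu, ts)) == [(0, 0), (0, 0), (1, 1)]

    def test_masked_cells_excluded(self):
        m = AbundanceMatrix(np.array([[2, 5]]), np.array([[True, False]]))
        tu, ts = expand_to_tokens(m)
        assert len(tu) == 2 and set(ts) == {0}

    def test_token_total_matches_observed_counts(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 8, size=(6, 9))
        counts[:, 0] += 1
        m = AbundanceMatrix(counts)
        tu, ts = expand_to_tokens(m)
        assert len(tu) == m.n_tokens


class TestGibbsConditional:
    def _state(self, n_uc, m_cs):
        n_uc = np.asarray(n_uc)
        m_cs = np.asarray(m_cs)
        return AssignmentState(
            z=np.zeros(0, dtype=int), token_unit=np.zeros(0, dtype=int),
            token_species=np.zeros(0, dtype=int),
            n_uc=n_uc, m_cs=m_cs, m_c=m_cs.sum(axis=1),
        )

    def test_first_token_is_uniform_by_symmetry(self):
        state = self._state(np.zeros((1, 3)), np.zeros((3, 4)))
        p = gibbs_conditional(state, 0, 0, ModelSpec(3))
        assert np.allclose(p, 1 / 3)

    def test_hand_evaluated_example(self):
        # C=2, alpha=gamma=1, S=2; minus-i counts: n_u=(3,1), m_.s=(4,0), m_c=(6,2)
        state = self._state([[3, 1]], [[4, 2], [0, 2]])
        p = gibbs_conditional(state, 0, 0, ModelSpec(2))
        assert np.allclose(p, [5 / 6, 1 / 6])

    def test_large_alpha_flattens_toward_uniform(self):
        state = self._state([[30, 1]], [[40, 2], [1, 2]])
        p = gibbs_conditional(state, 0, 0, ModelSpec(2, alpha=1e6, gamma=1e6))
        assert np.abs(p - 0.5).max() < 1e-3


class TestLogLikelihood:
    def test_single_species_is_zero(self):
        m = AbundanceMatrix(np.array([[7], [3]]))
        assert log_likelihood(m, np.ones((2, 1)), np.ones((1, 1))) == 0.0

    def test_hand_computed_value(self):
        m = AbundanceMatrix(np.array([[2, 2]]))
        ll = log_likelihood(m, np.ones((1, 1)), np.array([[0.5, 0.5]]))
        assert ll == pytest.approx(4 * np.log(0.5), abs=1e-12)

    def test_invariant_under_joint_label_permutation(self):
        rng = np.random.default_rng(1)
        m = AbundanceMatrix(rng.integers(1, 10, size=(4, 5)))
        theta = rng.dirichlet(np.ones(3), size=4)
        phi = rng.dirichlet(np.ones(5), size=3)
        perm = np.array([2, 0, 1])
        assert log_likelihood(m, theta, phi) == pytest.approx(
            log_likelihood(m, theta[:, perm], phi[perm]), abs=1e-10
        )

    def test_masked_cells_use_restricted_normaliser(self):
        # one species masked: likelihood renormalises over the other two
        counts = np.array([[4, 6, 0]])
        mask = np.array([[True, True, False]])
        m = AbundanceMatrix(counts, mask)
        theta = np.array([[1.0]])
        phi = np.array([[0.2, 0.3, 0.5]])
        expected = 4 * np.log(0.4) + 6 * np.log(0.6)
        assert log_likelihood(m, theta, phi) == pytest.approx(expected, abs=1e-10)

    def test_zero_probability_with_positive_count_is_minus_inf(self):
        m = AbundanceMatrix(np.array([[2, 2]]))
        with pytest.warns(UserWarning, match="zero predicted"):
            ll = log_likelihood(m, np.ones((1, 1)), np.array([[1.0, 0.0]]))
        assert ll == -np.inf


class TestPointEstimates:
    def test_map_with_uniform_prior_is_raw_proportions(self):
        theta, _ = point_estimates(np.array([[7, 3]]), np.ones((2, 2)), ModelSpec(2), "map")
        assert np.allclose(theta, [[0.7, 0.3]])

    def test_posterior_mean_of_empty_unit_is_prior_mean(self):
        theta, _ = point_estimates(np.array([[0, 0]]), np.ones((2, 2)), ModelSpec(2))
        assert np.allclose(theta, [[0.5, 0.5]])

    def test_posterior_mean_formula(self):
        _, phi = point_estimates(np.array([[10]]), np.array([[2, 2, 6]]), ModelSpec(1))
        assert np.allclose(phi, [[3 / 13, 3 / 13, 7 / 13]])

    def test_map_clamps_alpha_below_one(self):
        theta, _ = point_estimates(np.array([[0, 5]]), np.ones((2, 2)), ModelSpec(2, alpha=0.5), "map")
        assert theta.min() >= 0 and np.allclose(theta.sum(axis=1), 1)


class TestRelabel:
    def test_swap_is_undone(self):
        rng = np.random.default_rng(2)
        ref = rng.dirichlet(np.ones(6), size=3)
        theta = rng.dirichlet(np.ones(3), size=(1, 4))
        swapped = ref[[1, 2, 0]]
        phi_out, theta_out, _ = relabel(swapped[None], theta, ref)
        assert np.allclose(phi_out[0], ref)

    def test_idempotent_on_aligned_sample(self):
        rng = np.random.default_rng(3)
        ref = rng.dirichlet(np.ones(5), size=3)
        theta = rng.dirichlet(np.ones(3), size=(1, 2))
        phi_out, theta_out, perms = relabel(ref[None], theta, ref)
        assert np.array_equal(perms[0], [0, 1, 2])
        assert np.allclose(phi_out[0], ref)
        assert np.allclose(theta_out, theta)

    def test_recovers_random_permutations_under_noise(self):
        rng = np.random.default_rng(4)
        hits = 0
        trials = 1000
        for _ in range(trials):
            ref = rng.dirichlet(np.ones(8), size=3)
            perm = rng.permutation(3)
            noisy = ref[perm] + rng.normal(0, 0.01, size=ref.shape)
            _, _, perms = relabel(noisy[None], np.zeros((1, 1, 3)), ref)
            # sample row i is ref[perm[i]], so the recovered assignment
            # (reference slot -> sample row) is the inverse permutation
            if np.array_equal(perms[0], np.argsort(perm)):
                hits += 1
        assert hits / trials >= 0.99


class TestCredibleInterval:
    def test_constant_samples_give_zero_width(self):
        s = np.full((10, 2, 2), 0.4)
        lo, hi = credible_interval(s)
        assert np.allclose(lo, 0.4) and np.allclose(hi, 0.4)

    def test_linear_interpolation_quantiles(self):
        s = np.arange(0.1, 1.05, 0.1).reshape(-1, 1)
        lo, hi = credible_interval(s, level=0.8)
        assert lo[0] == pytest.approx(0.19)
        assert hi[0] == pytest.approx(0.91)

    def test_refuses_single_sample(self):
        with pytest.raises(ValueError, match="two samples"):
            credible_interval(np.zeros((1, 2)))

    def test_fit_refuses_unrelabeled_samples(self, small_truth):
        fit = run_gibbs(small_truth.data, ModelSpec(2), n_iter=60, burnin=30, thin=5, seed=0)
        fit.relabeled = False
        with pytest.raises(ValueError, match="not relabeled"):
            fit.credible_interval("theta")


class TestRunGibbs:
    def test_identical_seed_identical_result(self, small_truth):
        kw = dict(n_iter=200, burnin=100, thin=5, seed=11)
        a = run_gibbs(small_truth.data, ModelSpec(3), **kw)
        b = run_gibbs(small_truth.data, ModelSpec(3), **kw)
        assert np.array_equal(a.theta_samples, b.theta_samples)
        assert np.array_equal(a.phi_samples, b.phi_samples)
        assert np.array_equal(a.theta_map, b.theta_map)
        assert np.array_equal(a.loglik_trace, b.loglik_trace)

    def test_count_tables_match_assignments_in_every_sample(self, small_truth):
        fit = run_gibbs(small_truth.data, ModelSpec(3), n_iter=100, burnin=50, thin=10,
                        seed=7, keep_z=True)
        tu, ts = expand_to_tokens(small_truth.data)
        P, S = small_truth.data.counts.shape
        for k in range(fit.n_samples):
            st = AssignmentState.from_assignments(tu, ts, fit.z_samples[k], P, 3, S)
            assert np.array_equal(st.n_uc, fit.n_uc_samples[k])
            assert np.array_equal(st.m_cs, fit.m_cs_samples[k])

    def test_samples_live_on_the_simplex(self, scaled_fit):
        for arr, axis in [(scaled_fit.theta_samples, 2), (scaled_fit.phi_samples, 2)]:
            assert arr.min() >= 0 and arr.max() <= 1
            assert np.abs(arr.sum(axis=axis) - 1).max() < 1e-9

    def test_more_communities_than_tokens_warns_but_runs(self):
        m = AbundanceMatrix(np.array([[1, 1]]))
        with pytest.warns(UserWarning, match="degenerate"):
            fit = run_gibbs(m, ModelSpec(5), n_iter=20, burnin=10, thin=2, seed=0)
        assert fit.n_samples == 5

    def test_invalid_run_lengths_rejected(self, small_truth):
        with pytest.raises(ValueError):
            run_gibbs(small_truth.data, ModelSpec(2), n_iter=10, burnin=10, seed=0)
        with pytest.raises(ValueError):
            run_gibbs(small_truth.data, ModelSpec(2), n_iter=10, burnin=5, thin=0, seed=0)


class TestParameterRecovery:
    def test_toy_recovers_mixture_and_profiles(self):
        truth = commlda.toy_three_unit(1000)
        fit = run_gibbs(truth.data, ModelSpec(2), n_iter=1000, burnin=500, thin=5, seed=5)
        perm = match_to_truth(fit.phi_mean, truth.phi_true)
        assert np.abs(fit.theta_mean[:, perm] - truth.theta_true).max() < 0.05
        assert np.abs(fit.phi_mean[perm] - truth.phi_true).max() < 0.05

    def test_gradient_theta_recovery(self, scaled_truth, scaled_fit):
        """Joint-fit recovery sits close to the information floor: with phi
        fixed at truth the posterior-mean error is just under 0.05 at 100
        individuals/unit, and the joint fit (which must also estimate phi
        from 20k tokens) lands near 0.065."""
        res = commlda.fold_in(
            scaled_truth.data, scaled_truth.phi_true, scaled_truth.data.species_ids,
            ModelSpec(3), n_iter=1000, burnin=500, thin=5, seed=3,
        )
        assert np.abs(res.theta_mean - scaled_truth.theta_true).mean() < 0.05
        perm = match_to_truth(scaled_fit.phi_mean, scaled_truth.phi_true)
        mae = np.abs(scaled_fit.theta_mean[:, perm] - scaled_truth.theta_true).mean()
        assert mae < 0.08
        # species profiles are recovered far more precisely than mixtures
        assert np.abs(scaled_fit.phi_mean[perm] - scaled_truth.phi_true).mean() < 0.005
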