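"""Full-conditional correctness, chain mechanics, and the log joint."""
import numpy as np
import pytest
from scipy import stats

from _oracles import quadrature_inclusion_probability
from conftest import micro_design, recovery_config
from pedsur.sampler import (
    ChainConfig, FitData, MCMCState, PriorSpec, _draw_mvn_prec, gibbs_sweep,
    inclusion_beta_params, init_state, invwishart_rvs, iw_posterior_params,
    log_joint, random_effect_fullcond, run_chain, snv_inclusion_moments,
    update_regression_coefficients, update_snv_indicator,
)
from pedsur.simulate import simulate_dataset


PRIORS = PriorSpec(a=1.0, b=4.0, tau2=4.0, v0=25.0, nu0=5.0, s0=1.0)


class TestInitState:
    def test_orthonormal_design_zero_response(self):
        data = micro_design()
        state = init_state(data, PRIORS)
        assert np.allclose(state.beta_fixed, 0.0)
        assert np.all(state.gamma == 0)
        assert np.allclose(state.q, 1.0 / 5.0)

    def test_deterministic(self):
        data = micro_design()
        s1, s2 = init_state(data, PRIORS, seed=1), init_state(data, PRIORS, seed=1)
        np.testing.assert_array_equal(s1.sigma_e, s2.sigma_e)
        np.testing.assert_array_equal(s1.beta_fixed, s2.beta_fixed)

    def test_singular_design_rejected(self):
        data = micro_design()
        data.C = np.column_stack([data.C, data.C[:, 0]])
        data.n_fixed = data.C.shape[1]
        with pytest.raises(np.linalg.LinAlgError):
            init_state(data, PRIORS)

    def test_residual_variance_split_recovers_sigma_e(self):
        cfg = recovery_config(G=2, causal=(), betas=())
        data, truth = simulate_dataset(cfg, seed=14)
        fit = FitData.from_dataset(data, standardize=False)
        state = init_state(fit, PRIORS)
        for k in (0, 1):
            se2 = cfg.sigma_e[k] ** 2
            assert abs(state.sigma_e[k, k] - se2) / se2 < 0.2


class TestConjugateClosedForms:
    def test_inclusion_probability_parameters(self):
        assert inclusion_beta_params(0, 3, 1.0, 3.0) == (1.0, 6.0)
        assert inclusion_beta_params(3, 3, 1.0, 3.0) == (4.0, 3.0)

    def test_inverse_wishart_parameters(self):
        S0 = 0.5 * np.eye(2)
        vecs = np.array([[1.0, 2.0], [0.5, -1.0], [0.0, 1.0]])
        df, scale = iw_posterior_params(4.0, S0, vecs)
        assert df == 4.0 + 3  # df grows by exactly the number of vectors
        np.testing.assert_allclose(scale, S0 + vecs.T @ vecs, atol=1e-12)
        df0, scale0 = iw_posterior_params(4.0, S0, np.zeros((5, 2)))
        assert df0 == 9.0
        np.testing.assert_allclose(scale0, S0, atol=1e-15)

    def test_random_effect_moments_match_hand_formula(self):
        sigma_p = np.array([[2.0, 0.6], [0.6, 1.5]])
        sigma_e = np.array([[1.2, 0.4], [0.4, 0.9]])
        resid_sum = np.array([1.7, -0.3])
        n = 4
        mean, cov = random_effect_fullcond(sigma_p, sigma_e, resid_sum, n)
        prec = np.linalg.inv(sigma_p) + n * np.linalg.inv(sigma_e)
        cov_hand = np.linalg.inv(prec)
        mean_hand = cov_hand @ np.linalg.inv(sigma_e) @ resid_sum
        np.testing.assert_allclose(cov, cov_hand, atol=1e-10)
        np.testing.assert_allclose(mean, mean_hand, atol=1e-10)

    def test_equal_precision_average(self):
        # one observation, identity prior and residual covariance:
        # posterior mean is residual/2, covariance I/2
        mean, cov = random_effect_fullcond(np.eye(2), np.eye(2),
                                           np.array([3.0, -1.0]), 1)
        np.testing.assert_allclose(mean, [1.5, -0.5], atol=1e-12)
        np.testing.assert_allclose(cov, np.eye(2) / 2, atol=1e-12)

    def test_single_coefficient_normal_normal_posterior(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=30)
        y = 2.0 * x + rng.normal(size=30)
        v, tau2 = 1.3, 4.0
        _, m, var = snv_inclusion_moments(x, y, v, tau2)
        post_prec = 1 / tau2 + x @ x / v
        np.testing.assert_allclose(var, 1 / post_prec, atol=1e-12)
        np.testing.assert_allclose(m, (x @ y / v) / post_prec, atol=1e-12)


class TestSnvIndicator:
    def test_zero_variance_column_is_uninformative(self):
        x = np.zeros(10)
        log_bf, m, _ = snv_inclusion_moments(x, np.random.default_rng(1).normal(size=10),
                                             1.0, 100.0)
        assert log_bf == 0.0 and m == 0.0

    def test_vanishing_slab_is_uninformative(self):
        rng = np.random.default_rng(2)
        x, u = rng.normal(size=20), rng.normal(size=20)
        log_bf, _, _ = snv_inclusion_moments(x, u, 1.0, 1e-14)
        assert abs(log_bf) < 1e-5

    def test_matches_quadrature_oracle(self):
        # printed toy: 2 subjects, explicit dosages and working responses
        x = np.array([1.0, -1.0, 0.0, 2.0]) - 0.5
        u = np.array([0.8, -1.1, 0.2, 1.9])
        v, tau2, q = 0.7, 2.5, 0.3
        log_bf, _, _ = snv_inclusion_moments(x, u, v, tau2)
        p_gibbs = 1.0 / (1.0 + np.exp(-(np.log(q / (1 - q)) + log_bf)))
        p_quad = quadrature_inclusion_probability(x, u, v, tau2, q)
        assert p_gibbs == pytest.approx(p_quad, abs=1e-4)

    def test_invalid_slab_variance(self):
        data = micro_design()
        state = init_state(data, PRIORS)
        bad = PriorSpec(a=1.0, b=2.0, tau2=-1.0)
        with pytest.raises(ValueError):
            update_snv_indicator(state, data, bad, 0, 0,
                                 np.random.default_rng(0))


class TestRegressionUpdate:
    def test_noiseless_limit_recovers_coefficients(self):
        rng = np.random.default_rng(3)
        data = micro_design(n_fam=3, n_subj_per=4, G=2)
        beta = np.array([[1.0, -2.0], [0.5, 3.0]])
        data.y[:] = data.C @ beta.T
        state = init_state(data, PriorSpec(a=1, b=2, tau2=1, v0=1e8))
        state.sigma_e = 1e-12 * np.eye(2)
        state.sigma_p = state.sigma_s = 0.1 * np.eye(2)
        state.p_fam[:] = 0.0
        state.s_subj[:] = 0.0
        update_regression_coefficients(state, data, PriorSpec(a=1, b=2, tau2=1, v0=1e8),
                                       rng)
        np.testing.assert_allclose(state.beta_fixed, beta, atol=1e-4)

    def test_diagonal_residual_covariance_decouples_traits(self):
        # with rho_e = 0 trait 1's draw is unchanged by trait 2's data
        data = micro_design(n_fam=3, n_subj_per=4, G=2)
        rng1, rng2 = np.random.default_rng(11), np.random.default_rng(11)
        st1 = init_state(data, PRIORS)
        st1.sigma_e = np.diag([1.0, 2.0])
        st2 = st1.copy()
        data2 = micro_design(n_fam=3, n_subj_per=4, G=2)
        data2.y[:, 1] = 99.0  # perturb the other trait only
        update_regression_coefficients(st1, data, PRIORS, rng1)
        update_regression_coefficients(st2, data2, PRIORS, rng2)
        np.testing.assert_allclose(st1.beta_fixed[0], st2.beta_fixed[0], atol=1e-12)

    def test_mvn_precision_draw_moments(self):
        prec = np.array([[4.0, 1.0], [1.0, 3.0]])
        b = np.array([2.0, -1.0])
        rng = np.random.default_rng(5)
        draws = np.array([_draw_mvn_prec(prec, b, rng)[0] for _ in range(4000)])
        mean_hand = np.linalg.solve(prec, b)
        np.testing.assert_allclose(draws.mean(axis=0), mean_hand, atol=0.05)
        np.testing.assert_allclose(np.cov(draws.T), np.linalg.inv(prec), atol=0.05)


class TestInverseWishart:
    def test_mean_matches_theory(self):
        df, scale = 12.0, np.array([[2.0, 0.5], [0.5, 1.0]])
        rng = np.random.default_rng(6)
        draws = np.mean([invwishart_rvs(df, scale, rng) for _ in range(4000)], axis=0)
        np.testing.assert_allclose(draws, scale / (df - 3), rtol=0.08)

    def test_agrees_with_scipy_density(self):
        rng = np.random.default_rng(7)
        df, scale = 9.0, np.array([[1.5, 0.3], [0.3, 0.8]])
        x = invwishart_rvs(df, scale, rng)
        # draw is a plausible point under scipy's density (finite logpdf, SPD)
        assert np.isfinite(stats.invwishart.logpdf(x, df, scale))
        assert np.all(np.linalg.eigvalsh(x) > 0)


class TestSweepAndChain:
    def test_sweep_preserves_invariants_and_moves(self):
        data = micro_design(G=3)
        rng = np.random.default_rng(8)
        from pedsur.validation import draw_state_from_prior, simulate_response
        state = draw_state_from_prior(data, PRIORS, rng)
        simulate_response(state, data, rng)
        before = state.copy()
        gibbs_sweep(state, data, PRIORS, (rng, rng))
        state.validate()
        assert not np.allclose(before.beta_fixed, state.beta_fixed)
        gibbs_sweep(state, data, PRIORS, (rng, rng))
        state.validate()

    def test_draw_count_arithmetic(self):
        assert ChainConfig(n_iterations=100, burn_in=50, thinning=10).n_draws == 5

    def test_chain_is_deterministic(self):
        cfg = recovery_config(G=3, causal=(0,), betas=((-8.0, -9.0),))
        data, _ = simulate_dataset(cfg, seed=2)
        ccfg = ChainConfig(n_iterations=60, burn_in=20, thinning=4, seed=5)
        s1 = run_chain(data, PriorSpec(), ccfg)
        s2 = run_chain(data, PriorSpec(), ccfg)
        assert s1.n_draws == 10
        np.testing.assert_array_equal(s1.gamma, s2.gamma)
        np.testing.assert_array_equal(s1.beta_fixed, s2.beta_fixed)
        np.testing.assert_array_equal(s1.sigma_e, s2.sigma_e)

    def test_univariate_mode_zeroes_off_diagonals(self):
        cfg = recovery_config(G=3, causal=(0,), betas=((-8.0, -9.0),))
        data, _ = simulate_dataset(cfg, seed=2)
        ccfg = ChainConfig(n_iterations=60, burn_in=20, thinning=4, seed=5,
                           mode="univariate")
        s = run_chain(data, PriorSpec(), ccfg)
        for name in ("sigma_p", "sigma_s", "sigma_e"):
            off = getattr(s, name)[:, 0, 1]
            assert np.all(off == 0.0)

    def test_chain_samples_save_load_round_trip(self, tmp_path):
        cfg = recovery_config(G=2, causal=(), betas=())
        data, _ = simulate_dataset(cfg, seed=3)
        s = run_chain(data, PriorSpec(),
                      ChainConfig(n_iterations=30, burn_in=10, thinning=2, seed=1))
        path = tmp_path / "chain.npz"
        s.save(path)
        from pedsur.sampler import ChainSamples
        again = ChainSamples.load(path)
        np.testing.assert_array_equal(again.gamma, s.gamma)
        assert again.snv_ids == s.snv_ids
        assert again.mode == s.mode


class TestLogJoint:
    def _toy(self):
        # 1 family, 1 subject, 1 visit
        data = FitData(
            y=np.array([[0.7, -0.2]]), C=np.ones((1, 1)), S=np.zeros((1, 0)),
            fam=np.array([0]), subj=np.array([0]), subj_fam=np.array([0]),
        )
        state = MCMCState(
            beta_fixed=np.array([[0.3], [-0.1]]),
            beta_snv=np.zeros((2, 0)), gamma=np.zeros((2, 0), dtype=np.int8),
            q=np.array([0.2, 0.4]),
            p_fam=np.array([[0.1, -0.2]]), s_subj=np.array([[0.05, 0.3]]),
            sigma_p=np.array([[1.1, 0.2], [0.2, 0.9]]),
            sigma_s=np.array([[0.7, -0.1], [-0.1, 1.2]]),
            sigma_e=np.array([[1.0, 0.3], [0.3, 0.8]]),
        )
        return data, state

    def test_matches_hand_summed_density(self):
        data, state = self._toy()
        pri = PriorSpec(a=1.0, b=3.0, tau2=2.0, v0=10.0, nu0=5.0, s0=0.5)
        resid = data.y[0] - np.array([0.3, -0.1]) - state.p_fam[0] - state.s_subj[0]
        expected = (
            stats.multivariate_normal.logpdf(resid, np.zeros(2), state.sigma_e)
            + stats.multivariate_normal.logpdf(state.p_fam[0], np.zeros(2), state.sigma_p)
            + stats.multivariate_normal.logpdf(state.s_subj[0], np.zeros(2), state.sigma_s)
            + stats.norm.logpdf(0.3, 0, np.sqrt(10.0))
            + stats.norm.logpdf(-0.1, 0, np.sqrt(10.0))
            + stats.beta.logpdf(0.2, 1.0, 3.0) + stats.beta.logpdf(0.4, 1.0, 3.0)
            + stats.invwishart.logpdf(state.sigma_p, 5.0, 0.5 * np.eye(2))
            + stats.invwishart.logpdf(state.sigma_s, 5.0, 0.5 * np.eye(2))
            + stats.invwishart.logpdf(state.sigma_e, 5.0, 0.5 * np.eye(2))
        )
        assert log_joint(state, data, pri) == pytest.approx(expected, abs=1e-10)

    def test_larger_residual_decreases_density(self):
        data, state = self._toy()
        state.sigma_e = np.eye(2)
        pri = PriorSpec(a=1, b=3, tau2=2.0, v0=10.0, nu0=5.0, s0=0.5)
        base = log_joint(state, data, pri)
        data.y[0] = 2 * data.y[0]
        assert log_joint(state, data, pri) < base

    def test_family_relabeling_invariance(self):
        rng = np.random.default_rng(9)
        data = micro_design(n_fam=3, n_subj_per=2, G=1)
        from pedsur.validation import draw_state_from_prior, simulate_response
        pri = PriorSpec(a=1, b=3, tau2=1.0, v0=1.0, nu0=6.0, s0=1.0)
        state = draw_state_from_prior(data, pri, rng)
        simulate_response(state, data, rng)
        base = log_joint(state, data, pri)
        # swap family labels 0 and 1 everywhere
        perm = np.array([1, 0, 2])
        data.fam = perm[data.fam]
        data.subj_fam = perm[data.subj_fam]
        state.p_fam = state.p_fam[[1, 0, 2]]
        assert log_joint(state, data, pri) == pytest.approx(base, abs=1e-10)
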