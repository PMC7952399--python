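import numpy as np
import pytest
from scipy import stats

import emeth
from emeth import EmethError, FitOptions
from emeth.core import _solve_simplex_qp

from conftest import make_noise_free_bulk


class TestEStep:
    def test_identical_components_give_prior(self):
        rng = np.random.default_rng(0)
        e = rng.normal(0, 0.1, (30, 4))
        pi = np.array([0.0, 0.2, 0.7, 1.0])
        g = emeth.e_step_posterior(e, np.ones_like(e), 0.01, 0.01, pi)
        np.testing.assert_allclose(g, np.broadcast_to(pi, g.shape), atol=1e-12)

    def test_matches_direct_bayes_computation(self):
        # independent oracle: explicit normal densities and Bayes' rule
        e, w, sa2, sc2, pa = 0.1, 1.0, 0.01, 0.001, 0.1
        fa = stats.norm.pdf(e, 0, np.sqrt(sa2 * w))
        fc = stats.norm.pdf(e, 0, np.sqrt(sc2 * w))
        expected = pa * fa / (pa * fa + (1 - pa) * fc)
        g = emeth.e_step_posterior(np.array([[e]]), np.array([[w]]),
                                   sa2, sc2, np.array([pa]))
        assert g[0, 0] == pytest.approx(expected, abs=1e-12)
        assert g[0, 0] == pytest.approx(0.7597816661, abs=1e-9)

    def test_random_instances_match_bayes_oracle(self):
        rng = np.random.default_rng(7)
        e = rng.normal(0, 0.2, (40, 6))
        w = rng.uniform(0.2, 3.0, (40, 6))
        pa = rng.uniform(0.01, 0.99, 6)
        sa2, sc2 = 0.02, 0.004
        fa = stats.norm.pdf(e, 0, np.sqrt(sa2 * w))
        fc = stats.norm.pdf(e, 0, np.sqrt(sc2 * w))
        expected = pa * fa / (pa * fa + (1 - pa) * fc)
        g = emeth.e_step_posterior(e, w, sa2, sc2, pa)
        np.testing.assert_allclose(g, expected, atol=1e-10)

    def test_zero_prior_gives_zero_posterior(self):
        e = np.array([[5.0], [0.0]])
        g = emeth.e_step_posterior(e, np.ones_like(e), 0.01, 0.001,
                                   np.array([0.0]))
        np.testing.assert_array_equal(g, 0.0)

    def test_laplace_family_matches_density_ratio(self):
        e, w, sa2, sc2, pa = 0.07, 1.3, 0.02, 0.002, 0.3
        ba = np.sqrt(sa2 * w / 2.0)        # Laplace scale, matched variance
        bc = np.sqrt(sc2 * w / 2.0)
        fa = stats.laplace.pdf(e, 0, ba)
        fc = stats.laplace.pdf(e, 0, bc)
        expected = pa * fa / (pa * fa + (1 - pa) * fc)
        g = emeth.e_step_posterior(np.array([[e]]), np.array([[w]]),
                                   sa2, sc2, np.array([pa]), family="laplace")
        assert g[0, 0] == pytest.approx(expected, abs=1e-12)

    def test_invalid_variances_rejected(self):
        with pytest.raises(EmethError):
            emeth.e_step_posterior(np.zeros((2, 2)), np.ones((2, 2)),
                                   0.001, 0.01, np.array([0.5, 0.5]))


class TestMStepProportions:
    def test_pure_sample_recovered_exactly(self, small_reference):
        K = small_reference.n_cpgs
        z = small_reference.values[:, 0]
        rho = emeth.m_step_proportions(z, small_reference, 0.0, None,
                                       np.full(K, 0.1), 0.01, 0.001,
                                       ridge=0.0)
        np.testing.assert_allclose(rho, [1.0, 0.0, 0.0], atol=1e-6)

    def test_matches_brute_force_grid_on_two_types(self):
        # oracle: exhaustive search over rho1 in {0, 0.001, ..., 1}
        rng = np.random.default_rng(3)
        nu = rng.uniform(0.05, 0.95, (20, 2))
        ref = emeth.ReferenceMatrix([f"c{k}" for k in range(20)],
                                    ("a", "b"), nu)
        z = np.clip(nu @ [0.37, 0.63] + rng.normal(0, 0.05, 20), 0, 1)
        gamma = rng.uniform(0, 1, 20)
        w = rng.uniform(0.5, 2.0, 20)
        sa2, sc2, ridge = 0.02, 0.003, 0.5
        u = gamma / (sa2 * w) + (1 - gamma) / (sc2 * w)

        def objective(r1):
            rho = np.array([r1, 1.0 - r1])
            e = z - nu @ rho
            return 0.5 * np.sum(u * e * e) + ridge * np.sum(rho ** 2)

        grid = np.arange(0, 1.0005, 0.001)
        best = grid[np.argmin([objective(r) for r in grid])]
        rho = emeth.m_step_proportions(z, ref, 0.0, None, gamma, sa2, sc2,
                                       weights_i=w, ridge=ridge)
        assert abs(rho[0] - best) <= 0.001 + 1e-9
        assert objective(rho[0]) <= objective(best) + 1e-9

    def test_huge_ridge_drives_to_uniform(self, small_reference):
        K, Q = small_reference.n_cpgs, small_reference.n_cell_types
        z = small_reference.values[:, 1]
        rho = emeth.m_step_proportions(z, small_reference, 0.0, None,
                                       np.full(K, 0.5), 0.01, 0.001,
                                       ridge=1e8)
        np.testing.assert_allclose(rho, np.full(Q, 1.0 / Q), atol=1e-3)

    def test_eta_above_one_is_infeasible(self, small_reference):
        K = small_reference.n_cpgs
        with pytest.raises(EmethError, match="infeasible"):
            emeth.m_step_proportions(np.full(K, 0.5), small_reference, 1.5,
                                     np.zeros(K), np.full(K, 0.1),
                                     0.01, 0.001)

    def test_respects_eta_mass_constraint(self, small_reference):
        K = small_reference.n_cpgs
        rho = emeth.m_step_proportions(np.full(K, 0.4), small_reference, 0.3,
                                       np.full(K, 0.5), np.full(K, 0.1),
                                       0.01, 0.001, ridge=1.0)
        assert rho.sum() == pytest.approx(0.7, abs=1e-9)
        assert (rho >= -1e-12).all()


class TestSimplexQP:
    def test_objective_not_worse_than_random_feasible_points(self):
        rng = np.random.default_rng(11)
        Q, I = 5, 20
        A = rng.normal(size=(I, Q, Q))
        H = A @ A.transpose(0, 2, 1) + np.eye(Q)
        b = rng.normal(size=(I, Q))
        s = rng.uniform(0.3, 1.0, I)
        rho, _ = _solve_simplex_qp(H, b, s)
        assert (rho >= -1e-12).all()
        np.testing.assert_allclose(rho.sum(axis=1), s, atol=1e-8)
        obj = 0.5 * np.einsum("iq,iqp,ip->i", rho, H, rho) \
            - np.einsum("iq,iq->i", rho, b)
        for _ in range(200):
            cand = rng.dirichlet(np.ones(Q), size=I) * s[:, None]
            cobj = 0.5 * np.einsum("iq,iqp,ip->i", cand, H, cand) \
                - np.einsum("iq,iq->i", cand, b)
            assert (obj <= cobj + 1e-8).all()

    def test_zero_mass_sample_returns_zeros(self):
        H = np.eye(3)[None]
        rho, _ = _solve_simplex_qp(H, np.ones((1, 3)), np.array([0.0]))
        np.testing.assert_array_equal(rho, 0.0)


class TestMStepVariances:
    def test_symmetric_case_no_swap(self):
        e = np.full((4, 3), 0.2)
        gamma = np.full((4, 3), 0.5)
        sa2, sc2, pi, g, warns = emeth.m_step_variances_and_pi(
            e, gamma, np.ones_like(e))
        assert sa2 == pytest.approx(0.04)
        assert sc2 == pytest.approx(0.04)
        np.testing.assert_allclose(pi, 0.5)
        np.testing.assert_allclose(g, gamma)
        assert warns == []

    def test_hand_set_two_by_two_oracle(self):
        e = np.array([[0.1, 0.2], [0.3, 0.05]])
        gamma = np.array([[0.9, 0.1], [0.6, 0.4]])
        w = np.array([[1.0, 2.0], [0.5, 1.0]])
        q2 = e ** 2 / w
        exp_a = (gamma * q2).sum() / gamma.sum()
        exp_c = ((1 - gamma) * q2).sum() / (1 - gamma).sum()
        if exp_a < exp_c:
            exp_a, exp_c = exp_c, exp_a
        sa2, sc2, pi, _, _ = emeth.m_step_variances_and_pi(e, gamma, w)
        assert sa2 == pytest.approx(exp_a, rel=1e-12)
        assert sc2 == pytest.approx(exp_c, rel=1e-12)

    def test_empty_component_keeps_previous_value(self):
        e = np.array([[0.1, 0.2]])
        gamma = np.ones_like(e)
        sa2, sc2, pi, _, warns = emeth.m_step_variances_and_pi(
            e, gamma, np.ones_like(e), prev=(0.5, 0.007))
        assert sc2 == pytest.approx(0.007)
        assert any("consistent component empty" in w for w in warns)

    def test_label_swap_restores_variance_ordering(self):
        rng = np.random.default_rng(2)
        e = rng.normal(0, 0.1, (50, 2))
        gamma = np.where(np.abs(e) < 0.05, 0.9, 0.1)  # aberrant label on small e
        sa2, sc2, pi, g, _ = emeth.m_step_variances_and_pi(
            e, gamma, np.ones_like(e))
        assert sa2 >= sc2
        np.testing.assert_allclose(g, 1 - gamma)


class TestPenalizedLoglik:
    def test_single_component_collapse(self):
        rng = np.random.default_rng(4)
        e = rng.normal(0, 0.05, (10, 3))
        rho = rng.dirichlet(np.ones(4), 3).T
        ridge = 2.0
        ll = emeth.penalized_loglik(e, np.ones_like(e), 0.01, 0.001,
                                    np.zeros(3), rho, ridge)
        expected = stats.norm.logpdf(e, 0, np.sqrt(0.001)).sum() \
            - ridge * np.sum(rho ** 2)
        assert ll == pytest.approx(expected, rel=1e-12)

    def test_two_cpg_hand_computation(self):
        e = np.array([[0.05], [-0.1]])
        w = np.array([[1.0], [2.0]])
        sa2, sc2, pa = 0.02, 0.004, 0.3
        expected = 0.0
        for k in range(2):
            fa = stats.norm.pdf(e[k, 0], 0, np.sqrt(sa2 * w[k, 0]))
            fc = stats.norm.pdf(e[k, 0], 0, np.sqrt(sc2 * w[k, 0]))
            expected += np.log(pa * fa + (1 - pa) * fc)
        ll = emeth.penalized_loglik(e, w, sa2, sc2, np.array([pa]),
                                    np.zeros((2, 1)), 0.0)
        assert ll == pytest.approx(expected, rel=1e-12)

    def test_zero_residuals_hit_density_mode(self):
        e = np.zeros((5, 2))
        pa = np.array([0.2, 0.8])
        ll = emeth.penalized_loglik(e, np.ones_like(e), 0.01, 0.001, pa,
                                    np.zeros((3, 2)), 0.0)
        per = np.log(pa * stats.norm.pdf(0, 0, 0.1)
                     + (1 - pa) * stats.norm.pdf(0, 0, np.sqrt(0.001)))
        assert ll == pytest.approx(5 * per.sum(), rel=1e-12)


class TestSelectRidge:
    def test_singleton_grid_short_circuits(self, small_reference, monkeypatch):
        import emeth.core as core
        calls = []
        monkeypatch.setattr(core, "_fit_at_ridge",
                            lambda *a, **k: calls.append(1))
        bulk = make_noise_free_bulk(small_reference,
                                    np.full((3, 4), 1 / 3))
        ridge = emeth.select_ridge(bulk, small_reference, np.zeros(4),
                                   FitOptions(ridge_grid=[3.5]))
        assert ridge == 3.5
        assert calls == []

    def test_default_grid_and_folds_run_twenty_fits(self, tiny_reference,
                                                    monkeypatch):
        import emeth.core as core
        cfg = emeth.SimulationConfig(K=60, I=8, Q=4, sigma_c2=0.002,
                                     lambda_ratio=10, include_special=False,
                                     seed=0)
        bulk, truth = emeth.simulate_mixtures(tiny_reference, cfg)
        real = core._fit_at_ridge
        calls = []

        def counting(*args, **kwargs):
            calls.append(args[4])
            return real(*args, **kwargs)

        monkeypatch.setattr(core, "_fit_at_ridge", counting)
        emeth.select_ridge(bulk, tiny_reference, truth.true_eta,
                           FitOptions(seed=1))
        assert len(calls) == 20          # 4 penalty values x 5 CpG folds

    def test_too_few_cpgs_for_folds(self, small_reference):
        bulk = make_noise_free_bulk(small_reference, np.full((3, 2), 1 / 3))
        bulk = emeth.BulkBetaMatrix(bulk.cpg_ids[:3], bulk.sample_ids,
                                    bulk.values[:3])
        ref = emeth.ReferenceMatrix(small_reference.cpg_ids[:3],
                                    small_reference.cell_types,
                                    small_reference.values[:3])
        with pytest.raises(EmethError, match="folds"):
            emeth.select_ridge(bulk, ref, np.zeros(2),
                               FitOptions(cv_folds=5, ridge_grid=[0.0, 1.0]))

    def test_collinear_reference_prefers_positive_ridge(self, immune_reference):
        chosen = []
        for seed in range(10):
            cfg = emeth.SimulationConfig(K=946, I=30, sigma_c2=0.00221,
                                         lambda_ratio=10, seed=seed)
            bulk, truth = emeth.simulate_mixtures(immune_reference, cfg)
            ridge = emeth.select_ridge(bulk, immune_reference, truth.true_eta,
                                       FitOptions(seed=seed))
            chosen.append(ridge)
        assert sum(r > 0 for r in chosen) > 5


class TestFitEmeth:
    def test_noise_free_mixture_recovered(self, small_reference):
        rng = np.random.default_rng(8)
        rho = rng.dirichlet(np.ones(3), size=6).T
        bulk = make_noise_free_bulk(small_reference, rho)
        fit = emeth.fit_emeth(bulk, small_reference,
                              options=FitOptions(ridge_grid=[0.0]))
        np.testing.assert_allclose(fit.proportions, rho, atol=1e-4)
        assert fit.sigma_c2 <= 1e-8

    def test_monotone_loglik_across_random_fits(self, tiny_reference):
        for seed in range(4):
            cfg = emeth.SimulationConfig(K=60, I=10, Q=4, sigma_c2=0.003,
                                         lambda_ratio=8, seed=seed)
            bulk, truth = emeth.simulate_mixtures(tiny_reference, cfg)
            info = emeth.SampleInfo(truth.sample_ids, truth.true_eta)
            fit = emeth.fit_emeth(bulk, tiny_reference, info,
                                  FitOptions(ridge_grid=[0.6], seed=seed))
            tr = np.asarray(fit.loglik_trace)
            scale = max(1.0, np.abs(tr).max())
            assert np.diff(tr).min() >= -1e-8 * scale

    def test_simplex_feasibility_of_fit(self, tiny_reference):
        cfg = emeth.SimulationConfig(K=60, I=10, Q=4, sigma_c2=0.002,
                                     lambda_ratio=10, seed=3)
        bulk, truth = emeth.simulate_mixtures(tiny_reference, cfg)
        info = emeth.SampleInfo(truth.sample_ids, truth.true_eta)
        fit = emeth.fit_emeth(bulk, tiny_reference, info,
                              FitOptions(ridge_grid=[0.6]))
        assert (fit.proportions >= -1e-6).all()
        np.testing.assert_allclose(fit.proportions.sum(axis=0),
                                   1 - truth.true_eta, atol=1e-6)
        assert (fit.gamma >= 0).all() and (fit.gamma <= 1).all()

    def test_binom_weights_and_laplace_variants_run(self, tiny_reference):
        cfg = emeth.SimulationConfig(K=60, I=8, Q=4, sigma_c2=0.002,
                                     lambda_ratio=10, seed=1)
        bulk, truth = emeth.simulate_mixtures(tiny_reference, cfg)
        info = emeth.SampleInfo(truth.sample_ids, truth.true_eta)
        for kwargs in (dict(variance_weights="binom"),
                       dict(error_family="laplace")):
            fit = emeth.fit_emeth(bulk, tiny_reference, info,
                                  FitOptions(ridge_grid=[0.6], **kwargs))
            assert np.isfinite(fit.proportions).all()
            np.testing.assert_allclose(fit.proportions.sum(axis=0),
                                       1 - truth.true_eta, atol=1e-6)

    def test_inappropriate_reference_triggers_aberrant_warning(
            self, tiny_reference):
        # most CpG-sample entries deviate from the deconvolution model
        # (60-75% aberrant at 50x variance), so the fit should warn that
        # the reference looks inappropriate for these samples
        cfg = emeth.SimulationConfig(K=60, I=20, Q=4, sigma_c2=0.001,
                                     lambda_ratio=50,
                                     aberrant_range=(0.55, 0.75),
                                     include_special=False, seed=3)
        bulk, _ = emeth.simulate_mixtures(tiny_reference, cfg)
        fit = emeth.fit_emeth(bulk, tiny_reference,
                              options=FitOptions(ridge_grid=[0.6]))
        assert any("aberrant" in w and "reference" in w
                   for w in fit.warnings)

    def test_seed_reproducibility(self, tiny_reference):
        cfg = emeth.SimulationConfig(K=60, I=8, Q=4, sigma_c2=0.002,
                                     lambda_ratio=10, seed=2)
        bulk, truth = emeth.simulate_mixtures(tiny_reference, cfg)
        info = emeth.SampleInfo(truth.sample_ids, truth.true_eta)
        f1 = emeth.fit_emeth(bulk, tiny_reference, info, FitOptions(seed=5))
        f2 = emeth.fit_emeth(bulk, tiny_reference, info, FitOptions(seed=5))
        np.testing.assert_array_equal(f1.proportions, f2.proportions)
        assert f1.chosen_ridge == f2.chosen_ridge
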