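"""Variational Laplace: free energy, convergence, priors, model comparison."""

import numpy as np
import pytest

from neurodcm.containers import CrossSpectra
from neurodcm.inversion import (
    InversionConfig,
    Posterior,
    PriorDensity,
    _generic_variational_laplace,
    calibrate_empirical_priors,
    compare_models,
    free_energy,
    variational_laplace,
)


def _linear_problem(rng, n=20, d=3, tau=50.0):
    J = rng.standard_normal((n, d))
    theta_true = np.array([0.5, -0.3, 0.2])[:d]
    y = J @ theta_true + rng.standard_normal(n) / np.sqrt(tau)
    prior = PriorDensity(np.zeros(d), 0.5 * np.eye(d))
    return J, y, prior, tau


class TestFreeEnergyConjugate:
    def test_linear_gaussian_equals_log_evidence(self, rng):
        """At the conjugate posterior the free energy equals the analytic
        log model evidence of the linear-Gaussian model (closed form)."""
        J, y, prior, tau = _linear_problem(rng)
        n, d = J.shape
        # conjugate posterior
        Pp = np.linalg.inv(prior.cov)
        Sq = np.linalg.inv(tau * J.T @ J + Pp)
        mu = Sq @ (tau * J.T @ y)
        F = free_energy(y, J @ mu, J, mu, Sq, prior, tau)
        # analytic evidence: y ~ N(0, J Sp J^T + I/tau)
        C = J @ prior.cov @ J.T + np.eye(n) / tau
        sign, logdet = np.linalg.slogdet(C)
        log_ev = -0.5 * (n * np.log(2 * np.pi) + logdet
                         + y @ np.linalg.solve(C, y))
        assert F == pytest.approx(log_ev, abs=1e-6)

    def test_zero_residual_prior_posterior_has_no_complexity(self):
        prior = PriorDensity(np.zeros(2), np.eye(2))
        y = np.zeros(4)
        J = np.zeros((4, 2))
        F = free_energy(y, y, J, prior.mean, prior.cov, prior, 1.0)
        expected_accuracy = 0.5 * 4 * np.log(1.0) - 0.5 * 4 * np.log(2 * np.pi)
        assert F == pytest.approx(expected_accuracy, abs=1e-12)

    def test_widening_prior_shrinks_deviation_penalty(self, rng):
        # with the posterior mean far from the prior mean, the quadratic
        # deviation term dominates the KL and widening the prior raises F
        J, y, prior, tau = _linear_problem(rng)
        mu = np.array([4.0, -3.0, 2.0])
        Sq = 0.01 * np.eye(3)
        f_narrow = free_energy(y, J @ mu, J, mu, Sq, prior, tau)
        wide = PriorDensity(prior.mean, 10.0 * prior.cov)
        f_wide = free_energy(y, J @ mu, J, mu, Sq, wide, tau)
        assert f_wide > f_narrow


class TestGenericAscent:
    def test_recovers_linear_gaussian_posterior(self, rng):
        J, y, prior, tau = _linear_problem(rng)
        Pp = np.linalg.inv(prior.cov)
        Sq_exact = np.linalg.inv(tau * J.T @ J + Pp)
        mu_exact = Sq_exact @ (tau * J.T @ y)

        def predict(Theta):
            return Theta @ J.T, np.ones(Theta.shape[0], dtype=bool)

        cfg = InversionConfig(max_iter=50, tol=1e-10, noise_precision=tau,
                              init_amplitude_matching=False)
        mu, Sq, F, trace, _ = _generic_variational_laplace(y, predict, prior,
                                                           cfg)
        np.testing.assert_allclose(mu, mu_exact, atol=1e-6)
        np.testing.assert_allclose(Sq, Sq_exact, atol=1e-6)

    def test_trace_is_monotone(self, rng):
        J, y, prior, tau = _linear_problem(rng)

        def predict(Theta):
            # mildly nonlinear map
            return Theta @ J.T + 0.1 * (Theta**2) @ J.T, \
                np.ones(Theta.shape[0], dtype=bool)

        cfg = InversionConfig(max_iter=30, tol=1e-8)
        _, _, _, trace, _ = _generic_variational_laplace(y, predict, prior,
                                                         cfg)
        assert np.all(np.diff(trace) >= -1e-9)


class TestFullInversionRoundTrip:
    def test_noiseless_self_generated_data(self, forward_model, pspec):
        """Round-trip oracle: fitting model-generated data recovers an
        essentially perfect fit and a monotone free-energy trace."""
        freqs = np.arange(20.0, 48.5, 1.0)
        truth = np.zeros(46)
        truth[pspec.index("kappa_NMDA.PR")] = -0.5
        truth[pspec.index("g_AMPA.PL")] = 0.2
        S, ok, _ = forward_model.csd_batch(truth[None, :], freqs)
        assert ok[0]
        obs = CrossSpectra(freqs, S[0])
        post = variational_laplace(
            obs, forward_model,
            config=InversionConfig(max_iter=32, tol=1e-2),
        )
        assert post.r2 >= 99.0
        assert np.all(np.diff(post.trace) >= -1e-9)
        # strongly perturbed parameters recovered to the right sign/size
        assert post.mean[pspec.index("g_AMPA.PL")] == pytest.approx(0.2,
                                                                    abs=0.1)

    def test_rejects_non_hermitian_input(self, forward_model):
        freqs = np.arange(20.0, 25.0)
        vals = np.random.default_rng(0).standard_normal((5, 8, 8)) + 0j
        vals[0, 0, 1] = 5.0
        with pytest.raises(ValueError):
            variational_laplace(CrossSpectra(freqs, vals), forward_model)


class TestEmpiricalPriors:
    def _post(self, mean):
        d = len(mean)
        return Posterior(np.asarray(mean, float), np.eye(d), -1.0)

    def test_single_posterior_is_its_mean(self):
        base = PriorDensity(np.zeros(3), np.eye(3))
        out = calibrate_empirical_priors([self._post([1.0, 2.0, 3.0])], base)
        np.testing.assert_allclose(out.mean, [1.0, 2.0, 3.0])
        np.testing.assert_allclose(out.cov, base.cov)

    def test_three_posteriors_average(self):
        base = PriorDensity(np.zeros(2), np.eye(2))
        posts = [self._post([1.0, 0.0]), self._post([2.0, 3.0]),
                 self._post([3.0, 3.0])]
        out = calibrate_empirical_priors(posts, base)
        np.testing.assert_allclose(out.mean, [2.0, 2.0])

    def test_empty_list_raises(self):
        base = PriorDensity(np.zeros(2), np.eye(2))
        with pytest.raises(ValueError):
            calibrate_empirical_priors([], base)

    def test_pipeline_calibrates_on_three_random_controls(self, rng):
        """The cohort pipeline inverts exactly three randomly chosen
        controls to re-center the priors."""
        from neurodcm.cohort import CohortSpec, generate_cohort
        from neurodcm.pipeline import invert_cohort, COHORT_INVERSION
        from dataclasses import replace

        spec = CohortSpec(group_sizes={"nmdar": 1, "encephalopathy": 1,
                                       "control": 4}, seed=5)
        tab = generate_cohort(spec)
        cfg = replace(COHORT_INVERSION, max_iter=2)
        out = invert_cohort(tab, band=(20.0, 30.0), config=cfg, seed=0)
        groups = dict(zip(tab.table["id"], tab.table["group"]))
        assert len(out["calibration_ids"]) == 3
        assert all(groups[s] == "control" for s in out["calibration_ids"])


class TestModelComparisonRecovery:
    def test_variant_generated_data_favours_variant(self, lead_field, modes8):
        """Generative recovery: cross-spectra produced by the model WITH
        the superficial-pyramidal-to-stellate NMDA link are better
        explained (summed free energy) by that variant than by the
        default structure."""
        from neurodcm.cohort import _wishart_sample
        from neurodcm.forward import ForwardModel
        from neurodcm.network import build_default_network

        net_v = build_default_network(include_sp_to_ss=True)
        net_d = build_default_network(include_sp_to_ss=False)
        fm_v = ForwardModel(net_v, lead_field, modes8)
        fm_d = ForwardModel(net_d, lead_field, modes8)
        freqs = np.arange(2.0, 48.5, 2.0)
        theta = np.zeros(46)
        S, ok, _ = fm_v.csd_batch(theta[None, :], freqs)
        assert ok[0]
        cfg = InversionConfig(max_iter=16, tol=0.05, fd_scheme="forward")
        F_v, F_d = {}, {}
        for k in range(2):
            S_hat = _wishart_sample(S[0], 144, np.random.default_rng(50 + k))
            obs = CrossSpectra(freqs, S_hat)
            F_v[k] = variational_laplace(obs, fm_v, config=cfg).free_energy
            F_d[k] = variational_laplace(obs, fm_d, config=cfg).free_energy
        res = compare_models(F_d, F_v)
        assert res["winner"] == "variant"
        assert res["total"] > 0


class TestCompareModels:
    def test_identical_f_gives_zero_deltas(self):
        F = {"s1": -10.0, "s2": -12.0}
        res = compare_models(F, dict(F))
        assert all(v == 0.0 for v in res["delta_f"].values())
        assert res["total"] == 0.0

    def test_sum_linearity(self):
        Fd = {"s1": -10.0, "s2": -12.0, "s3": -9.0}
        Fv = {"s1": -9.0, "s2": -13.0, "s3": -8.5}
        res = compare_models(Fd, Fv)
        assert res["total"] == pytest.approx(sum(res["delta_f"].values()))
        assert res["total"] == pytest.approx(sum(Fv.values()) - sum(Fd.values()))

    def test_mismatched_subjects_raise(self):
        with pytest.raises(ValueError):
            compare_models({"a": 1.0}, {"b": 1.0})
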