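"""Forward CSD prediction: fixed points, transfer functions, fit metric."""

import numpy as np
import pytest

from neurodcm.containers import CrossSpectra
from neurodcm.forward import (
    LinearizedSystem,
    NoiseParams,
    StabilityError,
    find_fixed_point,
    fit_variance_explained,
    predicted_csd,
    transfer_functions,
)
from neurodcm.microcircuit import C_MEMBRANE
from neurodcm._cmc import CMCEngine


class TestFixedPoint:
    def test_residual_below_tolerance(self, net, pspec):
        x = find_fixed_point(net, pspec.zeros())
        eng = CMCEngine(net)
        nat = eng.materialize(np.zeros((1, 41)))
        res = np.abs(eng.f(x[None, :], nat)).max() * C_MEMBRANE
        assert res <= 1e-8

    def test_conductances_equal_coupled_presynaptic_rates(self, net):
        eng = CMCEngine(net)
        nat = eng.materialize(np.zeros((1, 41)))
        x, ok = eng.fixed_point(nat)
        assert ok.all()
        xs = x.reshape(1, 4, 4, 4)
        V, g = xs[..., 0], xs[..., 1:]
        F = 0.5 * (1 + np.tanh(0.5 * (V + 40.0) / nat["slope"][:, None, None]))
        drive = np.einsum("btprsq,bsq->btpr", nat["W"], F)
        np.testing.assert_allclose(g, drive, atol=1e-9)

    def test_invariant_to_batch_duplication(self, net):
        eng = CMCEngine(net)
        nat = eng.materialize(np.zeros((3, 41)))
        x, ok = eng.fixed_point(nat)
        assert ok.all()
        np.testing.assert_allclose(x[0], x[1], atol=1e-10)
        np.testing.assert_allclose(x[0], x[2], atol=1e-10)


class TestTransferFunctions:
    def test_one_state_lorentzian(self):
        """x' = -a x + u has |H|^2 = 1/(a^2 + w^2) in closed form."""
        a = 30.0
        lin = LinearizedSystem(
            x_star=np.zeros(1),
            jacobian=np.array([[-a]]),
            delayed_jacobian=np.array([[-a]]),
            input_matrix=np.eye(1),
            output_matrix=np.eye(1),
        )
        freqs = np.array([1.0, 5.0, 20.0])
        H = transfer_functions(lin, freqs)
        w = 2 * np.pi * freqs
        np.testing.assert_allclose(
            np.abs(H[:, 0, 0]) ** 2, 1.0 / (a**2 + w**2), rtol=1e-12
        )

    def test_dc_gain(self, forward_model, pspec):
        lin = forward_model.linearize(pspec.zeros())
        H0 = transfer_functions(lin, np.array([1e-9]))[0]
        expected = -lin.output_matrix @ np.linalg.solve(
            lin.delayed_jacobian, lin.input_matrix
        )
        np.testing.assert_allclose(H0, expected, rtol=1e-6)

    def test_unstable_system_raises(self):
        lin = LinearizedSystem(
            x_star=np.zeros(1),
            jacobian=np.array([[0.5]]),
            delayed_jacobian=np.array([[0.5]]),
            input_matrix=np.eye(1),
            output_matrix=np.eye(1),
        )
        with pytest.raises(StabilityError):
            transfer_functions(lin, np.array([1.0]))


class TestPredictedCsd:
    def test_hermitian_nonneg_diag(self, net, pspec, lead_field, modes8):
        freqs = np.arange(2.0, 48.5, 2.0)
        cs = predicted_csd(net, pspec.zeros(), freqs, lead_field, modes8)
        assert cs.is_hermitian()
        diag = np.einsum("fmm->fm", cs.values).real
        assert (diag >= 0).all()

    def test_zero_noise_rank_at_most_sources(self, net, pspec, lead_field,
                                             modes8):
        freqs = np.array([10.0, 30.0])
        noise = NoiseParams(u_amp=0.025, n_amp=0.0, c_amp=0.0)
        cs = predicted_csd(net, pspec.zeros(), freqs, lead_field, modes8,
                           noise=noise)
        for k in range(len(freqs)):
            assert np.linalg.matrix_rank(cs.values[k], tol=1e-14) <= 4

    def test_amplitude_scales_quadratically(self, net, pspec, lead_field,
                                            modes8):
        freqs = np.array([20.0, 35.0])
        n1 = NoiseParams(u_amp=0.02, n_amp=0.0, c_amp=0.0)
        n2 = NoiseParams(u_amp=0.04, n_amp=0.0, c_amp=0.0)
        c1 = predicted_csd(net, pspec.zeros(), freqs, lead_field, modes8, n1)
        c2 = predicted_csd(net, pspec.zeros(), freqs, lead_field, modes8, n2)
        np.testing.assert_allclose(c2.values, 4.0 * c1.values, rtol=1e-10)

    def test_matches_cohort_generator_noiseless_path(self, net, pspec,
                                                     lead_field, modes8):
        """Shared-code consistency: the fast-mode generator's channel CSD,
        projected through the same modes, equals predicted_csd exactly."""
        from neurodcm.cohort import _channel_csd
        from neurodcm.forward import ForwardModel

        freqs = np.arange(5.0, 45.5, 5.0)
        pv = pspec.zeros()
        fm = ForwardModel(net, lead_field, modes8)
        S_ch = _channel_csd(fm, pv, freqs, lead_field, alpha_amp=0.0)
        S_modes = np.einsum("cm,fcd,dn->fmn", modes8, S_ch, modes8)
        cs = fm.predict(pv, freqs)
        scale = np.abs(cs.values).max()
        np.testing.assert_allclose(S_modes, cs.values, atol=1e-9 * scale)


class TestFitVarianceExplained:
    def _cs(self, vals):
        freqs = np.arange(1.0, 1.0 + vals.shape[0])
        return CrossSpectra(freqs, vals)

    def test_identity_is_100(self, rng):
        A = rng.standard_normal((5, 3, 3)) + 1j * rng.standard_normal((5, 3, 3))
        A = A + np.swapaxes(A, 1, 2).conj()
        cs = self._cs(A)
        assert fit_variance_explained(cs, cs) == pytest.approx(100.0)

    def test_affine_invariance(self, rng):
        A = rng.standard_normal((5, 3, 3)) + 1j * rng.standard_normal((5, 3, 3))
        B = 3.0 * A  # |B| = 3|A|: positively affine in absolute values
        assert fit_variance_explained(self._cs(A), self._cs(B)) == \
            pytest.approx(100.0)

    def test_toy_vectors_match_correlation_oracle(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = np.array([1.5, 1.9, 3.4, 3.9])
        va = np.zeros((4, 1, 1), dtype=complex)
        vb = np.zeros((4, 1, 1), dtype=complex)
        va[:, 0, 0], vb[:, 0, 0] = a, b
        # from-scratch Pearson correlation
        r = ((a - a.mean()) @ (b - b.mean())) / np.sqrt(
            ((a - a.mean()) ** 2).sum() * ((b - b.mean()) ** 2).sum()
        )
        assert fit_variance_explained(self._cs(va), self._cs(vb)) == \
            pytest.approx(100 * r**2, abs=1e-10)

    def test_constant_vectors_raise(self):
        v = np.ones((4, 1, 1), dtype=complex)
        with pytest.raises(ValueError):
            fit_variance_explained(self._cs(v), self._cs(v))
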