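"""Forward mapping from parameters to predicted sensor-mode cross-spectra.

The nonlinear network is linearized about its fixed point; first-order
delay compensation yields an effective Jacobian whose eigenvalues are the
transfer-function poles.  Endogenous innovations drive the spiny stellate
populations; their power-law spectrum, together with mode-level and common
observation noise, completes the generative model of the observed CSD:

    S(f) = H(f) G_u(f) H(f)^H  +  G_n(f) I  +  G_c(f) b b^T

with H(f) the transfer function projected through the lead field and
spatial modes, and b the mode-space image of a spatially common noise
component.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._cmc import CMCEngine, ModelConfig, StabilityError
from .containers import CrossSpectra
from .network import LeadField, NetworkModel
from .params import OBS_LABELS, ParamVector

__all__ = [
    "NoiseParams",
    "LinearizedSystem",
    "ForwardModel",
    "find_fixed_point",
    "transfer_functions",
    "predicted_csd",
    "fit_variance_explained",
    "StabilityError",
]

#: Pivot frequency (Hz) of the power-law innovations/noise spectra; the
#: spectral exponent tilts power about this frequency instead of rescaling
#: the whole spectrum.
F_PIVOT = 32.0


@dataclass
class NoiseParams:
    """Observation-model spectra (natural units).

    Innovations: G_u(f) = u_amp^2 (f/f_pivot)^(-u_exp), one independent
    stream per source.  Mode noise: G_n(f) on the diagonal; common noise:
    G_c(f) on the rank-one spatially uniform component.
    """

    u_amp: float = 0.001
    u_exp: float = 1.0
    n_amp: float = 0.0006
    n_exp: float = 0.5
    c_amp: float = 0.00032

    @classmethod
    def from_log_scales(cls, obs: np.ndarray) -> "NoiseParams":
        base = cls()
        return cls(
            u_amp=base.u_amp * np.exp(obs[0]),
            u_exp=base.u_exp * np.exp(obs[1]),
            n_amp=base.n_amp * np.exp(obs[2]),
            n_exp=base.n_exp * np.exp(obs[3]),
            c_amp=base.c_amp * np.exp(obs[4]),
        )

    def innovations(self, freqs: np.ndarray) -> np.ndarray:
        return self.u_amp**2 * (np.asarray(freqs) / F_PIVOT) ** (-self.u_exp)

    def mode_noise(self, freqs: np.ndarray) -> np.ndarray:
        return self.n_amp**2 * (np.asarray(freqs) / F_PIVOT) ** (-self.n_exp)

    def common_noise(self, freqs: np.ndarray) -> np.ndarray:
        return self.c_amp**2 * np.ones_like(np.asarray(freqs, dtype=float))


@dataclass
class LinearizedSystem:
    """Fixed point, Jacobians and input/output matrices of one linearization."""

    x_star: np.ndarray        # (n,)
    jacobian: np.ndarray      # (n, n)
    delayed_jacobian: np.ndarray
    input_matrix: np.ndarray  # (n, n_sources)
    output_matrix: np.ndarray  # (n_out, n)
    eigenvalues: np.ndarray | None = None

    @property
    def max_eig_real(self) -> float:
        w = self.eigenvalues
        if w is None:
            w = np.linalg.eigvals(self.delayed_jacobian)
        return float(w.real.max())


class ForwardModel:
    """Maps log-scale parameter vectors to predicted mode-space CSD.

    Bundles the network engine with a lead field and a spatial-mode matrix.
    All heavy entry points accept a batch of parameter vectors; the
    batched path is what the inversion's finite-difference scheme calls.
    """

    def __init__(self, net: NetworkModel, lf: LeadField, modes: np.ndarray,
                 config: ModelConfig | None = None):
        self.engine = CMCEngine(net, config)
        self.net = net
        self.lf = lf
        self.modes = np.asarray(modes, dtype=float)
        if self.modes.shape[0] != lf.gain.shape[0]:
            raise ValueError("mode matrix and lead field disagree on channels")
        # mode-space source mixing (n_modes x n_sources)
        self._A = self.modes.T @ lf.gain
        # mode-space image of the spatially common (all-channel) component
        self._b_common = self.modes.T @ np.ones(lf.gain.shape[0]) / np.sqrt(
            lf.gain.shape[0]
        )

    @property
    def spec(self):
        return self.engine.spec

    def n_free(self) -> int:
        return self.spec.n_params + len(OBS_LABELS)

    # -------------------------------------------------------------- #
    def linearize_batch(self, lam: np.ndarray, x0=None):
        """Fixed points and delay-adjusted Jacobians for (B, n_neuronal)."""
        return self.engine.linearize(lam, x0=x0)

    def csd_batch(self, theta: np.ndarray, freqs: np.ndarray, x0=None):
        """Predicted CSD for a batch of full parameter vectors.

        ``theta`` is (B, n_neuronal + n_obs).  Returns ``(S, ok, info)``
        where S is (B, n_freq, m, m) complex, and ok flags batch elements
        whose fixed point converged and whose linearization is stable.
        """
        theta = np.atleast_2d(np.asarray(theta, dtype=float))
        B = theta.shape[0]
        n_p = self.spec.n_params
        lam, obs = theta[:, :n_p], theta[:, n_p:]
        lin = self.engine.linearize(lam, x0=x0)
        ok = lin["ok"].copy()
        Bm = self.engine.input_matrix(lin["nat"])
        Out = self._A @ self.engine.output_matrix(self.lf.population_weights)
        freqs = np.asarray(freqs, dtype=float)
        H, eig = self.engine.transfer(
            lin["Jd"], Bm if Bm.ndim == 3 else Bm[0], Out, freqs,
            check_stability=False,
        )
        ok &= eig.real.max(axis=1) < 0
        m = Out.shape[0]
        S = np.zeros((B, freqs.size, m, m), dtype=complex)
        # per-batch observation spectra
        base = NoiseParams()
        u_amp = base.u_amp * np.exp(obs[:, 0])
        u_exp = base.u_exp * np.exp(obs[:, 1])
        n_amp = base.n_amp * np.exp(obs[:, 2])
        n_exp = base.n_exp * np.exp(obs[:, 3])
        c_amp = base.c_amp * np.exp(obs[:, 4])
        rel = freqs[None, :] / F_PIVOT
        Gu = u_amp[:, None] ** 2 * rel ** (-u_exp[:, None])   # (B, F)
        Gn = n_amp[:, None] ** 2 * rel ** (-n_exp[:, None])
        Gc = c_amp[:, None] ** 2 * np.ones_like(rel)
        S = np.einsum("bfik,bf,bfjk->bfij", H, Gu, H.conj(),
                      optimize=True)
        S += Gn[..., None, None] * np.eye(m)
        S += Gc[..., None, None] * np.outer(self._b_common, self._b_common)
        S = 0.5 * (S + np.swapaxes(S, -1, -2).conj())
        info = {"lin": lin, "H": H, "eig": eig}
        return S, ok, info

    def predict(self, params: ParamVector, freqs: np.ndarray) -> CrossSpectra:
        """Predicted CrossSpectra for a single parameter vector.

        Raises :class:`StabilityError` if the linearization is unstable.
        """
        theta = np.concatenate([params.values, params.obs])
        S, ok, info = self.csd_batch(theta[None, :], freqs)
        if not ok[0]:
            raise StabilityError(float(info["eig"][0].real.max()))
        return CrossSpectra(np.asarray(freqs, dtype=float), S[0])

    def linearize(self, params: ParamVector) -> LinearizedSystem:
        lin = self.engine.linearize(params.values[None, :])
        if not lin["ok"][0]:
            res = float(
                np.abs(self.engine.f(lin["x"], lin["nat"])).max() * self.engine.C
            )
            raise RuntimeError(
                f"fixed point did not converge (residual {res:.3g})"
            )
        Bm = self.engine.input_matrix(lin["nat"])[0]
        Out = self._A @ self.engine.output_matrix(self.lf.population_weights)
        return LinearizedSystem(
            x_star=lin["x"][0],
            jacobian=lin["J"][0],
            delayed_jacobian=lin["Jd"][0],
            input_matrix=Bm,
            output_matrix=Out,
            eigenvalues=np.linalg.eigvals(lin["Jd"][0]),
        )


def find_fixed_point(net: NetworkModel, params: ParamVector,
                     config: ModelConfig | None = None,
                     tol: float = 1e-8) -> np.ndarray:
    """Solve the stationarity condition f(x*) = 0 for one parameter vector.

    Returns the flattened fixed point; raises with the residual if Newton
    iteration fails.
    """
    eng = CMCEngine(net, config)
    nat = eng.materialize(params.values[None, :])
    x, ok = eng.fixed_point(nat, tol=tol)
    if not ok[0]:
        res = float(np.abs(eng.f(x, nat)).max() * eng.C)
        raise RuntimeError(
            f"fixed-point iteration did not reach tolerance {tol:g}: "
            f"residual {res:.3g}"
        )
    return x[0]


def transfer_functions(lin: LinearizedSystem, freqs: np.ndarray) -> np.ndarray:
    """H(f) = Out (2*pi*i*f I - J_delayed)^-1 B on a frequency grid (Hz).

    Raises :class:`StabilityError` when the delay-adjusted Jacobian has a
    non-negative eigenvalue real part.
    """
    w = lin.eigenvalues
    if w is None:
        w = np.linalg.eigvals(lin.delayed_jacobian)
    if w.real.max() >= 0:
        raise StabilityError(float(w.real.max()))
    freqs = np.asarray(freqs, dtype=float)
    iw = 2j * np.pi * freqs
    n = lin.delayed_jacobian.shape[0]
    out = np.empty((freqs.size, lin.output_matrix.shape[0],
                    lin.input_matrix.shape[1]), dtype=complex)
    for k, z in enumerate(iw):
        out[k] = lin.output_matrix @ np.linalg.solve(
            z * np.eye(n) - lin.delayed_jacobian, lin.input_matrix
        )
    return out


def predicted_csd(net: NetworkModel, params: ParamVector, freqs: np.ndarray,
                  lf: LeadField, modes: np.ndarray,
                  noise: NoiseParams | None = None,
                  config: ModelConfig | None = None) -> CrossSpectra:
    """Analytic sensor-mode CSD for one parameter vector.

    If ``noise`` is given it overrides the observation parameters carried
    in ``params.obs``.
    """
    fm = ForwardModel(net, lf, modes, config)
    if noise is None:
        return fm.predict(params, freqs)
    lin = fm.linearize(params)
    H = transfer_functions(lin, freqs)
    Gu = noise.innovations(freqs)
    S = np.einsum("fik,f,fjk->fij", H, Gu, H.conj())
    m = H.shape[1]
    S += noise.mode_noise(freqs)[:, None, None] * np.eye(m)
    S += noise.common_noise(freqs)[:, None, None] * np.outer(
        fm._b_common, fm._b_common
    )
    S = 0.5 * (S + np.swapaxes(S, -1, -2).conj())
    return CrossSpectra(np.asarray(freqs, dtype=float), S)


def fit_variance_explained(predicted: CrossSpectra,
                           observed: CrossSpectra) -> float:
    """Percent variance explained: 100 x r^2 between |predicted| and |observed|.

    Both CSDs are concatenated into vectors of absolute values; the squared
    Pearson correlation of those vectors is reported as a percentage.
    """
    if predicted.values.shape != observed.values.shape:
        raise ValueError("predicted and observed CSD shapes differ")
    if not np.allclose(predicted.freqs, observed.freqs):
        raise ValueError("frequency grids differ")
    a = np.abs(predicted.values).ravel()
    b = np.abs(observed.values).ravel()
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("correlation undefined for constant CSD vectors")
    r = np.corrcoef(a, b)[0, 1]
    return float(100.0 * r**2)
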