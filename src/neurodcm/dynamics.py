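"""Post-fit mechanistic analyses: population spectra and stability.

The fitted model can be interrogated beyond the scalp: the spectral
response of any population (notably the inhibitory interneurons, which
are invisible to EEG because their dendritic arborization is closed-field)
and the eigenspectrum of the delay-adjusted Jacobian, whose largest real
part measures distance from dynamical instability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._cmc import CMCEngine, ModelConfig
from .forward import NoiseParams, StabilityError
from .microcircuit import PopulationKind
from .network import NetworkModel
from .params import ParamVector

__all__ = ["StabilityReport", "population_spectrum", "stability_eigenspectrum"]


@dataclass
class StabilityReport:
    """Eigenvalues of the delay-adjusted Jacobian and derived summaries."""

    eigenvalues: np.ndarray
    max_real: float
    oscillation_freqs: np.ndarray  # Hz, non-negative, sorted descending by Re

    @property
    def n_states(self) -> int:
        return self.eigenvalues.size


def _linearize(net: NetworkModel, params: ParamVector,
               config: ModelConfig | None):
    eng = CMCEngine(net, config)
    lin = eng.linearize(params.values[None, :])
    if not lin["ok"][0]:
        raise RuntimeError("fixed point did not converge")
    return eng, lin


def population_spectrum(net: NetworkModel, params: ParamVector,
                        population: PopulationKind, freqs,
                        noise: NoiseParams | None = None,
                        config: ModelConfig | None = None,
                        measure: str = "voltage") -> np.ndarray:
    """Power spectrum of one population's activity, averaged over sources.

    The output matrix selects the requested population's voltage states
    directly (no lead field), so populations that do not reach the scalp
    — the inhibitory interneurons — can still be interrogated.  With
    ``measure="firing"`` the local slope of the firing sigmoid at the
    fixed point converts voltage fluctuations to rate fluctuations.
    """
    noise = noise or NoiseParams.from_log_scales(params.obs)
    freqs = np.asarray(freqs, dtype=float)
    eng, lin = _linearize(net, params, config)
    w = np.linalg.eigvals(lin["Jd"][0])
    if w.real.max() >= 0:
        raise StabilityError(float(w.real.max()))
    Out = eng.population_output_matrix(population)
    if measure == "firing":
        nat = lin["nat"]
        xs = lin["x"].reshape(1, eng.S, 4, 4)
        V = xs[0, :, int(population), 0]
        s = nat["slope"][0]
        F = 0.5 * (1.0 + np.tanh(0.5 * (V + 40.0) / s))
        Out = Out * (F * (1.0 - F) / s)[:, None]
    elif measure != "voltage":
        raise ValueError("measure must be 'voltage' or 'firing'")
    Bm = eng.input_matrix(lin["nat"])[0]
    H, _ = eng.transfer(lin["Jd"], Bm, Out, freqs, check_stability=True)
    Gu = noise.innovations(freqs)
    S = np.einsum("fik,f,fjk->fij", H[0], Gu, H[0].conj())
    return np.einsum("fss->fs", S).real.mean(axis=1)


def stability_eigenspectrum(net: NetworkModel, params: ParamVector,
                            config: ModelConfig | None = None
                            ) -> StabilityReport:
    """Full eigen-decomposition of the delay-adjusted Jacobian."""
    _, lin = _linearize(net, params, config)
    w = np.linalg.eigvals(lin["Jd"][0])
    order = np.argsort(-w.real)
    w = w[order]
    osc = np.abs(w.imag) / (2.0 * np.pi)
    return StabilityReport(
        eigenvalues=w,
        max_real=float(w.real.max()),
        oscillation_freqs=osc,
    )
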