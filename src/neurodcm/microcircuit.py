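"""Single-source, four-population conductance-based neural mass model.

Each cortical source is modelled as four interacting neuronal populations
(layer IV spiny stellate cells, superficial pyramidal cells, inhibitory
interneurons and deep pyramidal cells).  Every population carries four
states: a membrane potential V and three ligand-gated conductances for
AMPA, GABA_A and NMDA receptors.  Membrane dynamics are capacitive current
balance; conductances follow first-order channel kinetics driven by
sigmoid presynaptic firing.  The NMDA conductance is gated by a
voltage-dependent magnesium-block non-linearity.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PopulationKind",
    "ReceptorKind",
    "ChannelSpec",
    "MgBlockParams",
    "FiringParams",
    "SourceParams",
    "PopulationState",
    "presynaptic_rate",
    "mg_block_gain",
    "mg_block_gain_deriv",
    "population_derivatives",
    "default_priors",
    "DEFAULT_CHANNELS",
    "V_LEAK",
    "V_THRESH",
    "C_MEMBRANE",
    "G_LEAK",
]


class PopulationKind(enum.IntEnum):
    """The four neuronal populations, in canonical state-ordering."""

    SS = 0  # layer IV spiny stellate
    SP = 1  # superficial pyramidal
    II = 2  # inhibitory interneuron
    DP = 3  # deep pyramidal


class ReceptorKind(enum.IntEnum):
    """The three ionotropic receptor channels, in canonical state-ordering."""

    AMPA = 0
    GABAA = 1
    NMDA = 2


# Fixed physiological constants (mV / relative conductance units).
V_LEAK = -70.0       # potassium leak reversal
V_THRESH = -40.0     # firing threshold potential
G_LEAK = 1.0         # leak conductance (relative units)
C_MEMBRANE = 8e-3    # membrane capacitance; tau_m = C/gL = 8 ms

#: Reversal potentials: sodium (AMPA) 60 mV, calcium (NMDA) 10 mV,
#: chloride (GABA_A) -70 mV.
REVERSAL = {
    ReceptorKind.AMPA: 60.0,
    ReceptorKind.GABAA: -70.0,
    ReceptorKind.NMDA: 10.0,
}

#: Prior channel time constants (ms): AMPA 12, GABA_A 8, NMDA 100.
PRIOR_TAU_MS = {
    ReceptorKind.AMPA: 12.0,
    ReceptorKind.GABAA: 8.0,
    ReceptorKind.NMDA: 100.0,
}


@dataclass(frozen=True)
class ChannelSpec:
    """One ligand-gated channel: receptor, reversal potential, prior kinetics."""

    receptor: ReceptorKind
    reversal_potential: float  # mV
    prior_time_constant: float  # ms

    def __post_init__(self):
        if self.prior_time_constant <= 0:
            raise ValueError("prior_time_constant must be positive")

    @property
    def prior_rate_constant(self) -> float:
        """Rate constant 1/tau in ms^-1."""
        return 1.0 / self.prior_time_constant


DEFAULT_CHANNELS = tuple(
    ChannelSpec(r, REVERSAL[r], PRIOR_TAU_MS[r]) for r in ReceptorKind
)

# Excitatory reversals lie above the leak reversal; GABA_A sits at (or below)
# the leak reversal, per the fixed chloride/potassium values.
assert all(
    c.reversal_potential > V_LEAK
    for c in DEFAULT_CHANNELS
    if c.receptor is not ReceptorKind.GABAA
)
assert DEFAULT_CHANNELS[ReceptorKind.GABAA].reversal_potential <= V_LEAK


@dataclass(frozen=True)
class MgBlockParams:
    """Voltage-dependent magnesium-block gain on the NMDA conductance.

    gain(V) = alpha / (1 + beta * exp(-gamma * V)); three free parameters.
    """

    alpha: float = 1.5
    beta: float = 0.33
    gamma: float = 0.06  # mV^-1

    def __post_init__(self):
        if not (self.alpha > 0 and self.beta > 0 and self.gamma > 0):
            raise ValueError("MgBlockParams must all be positive")


@dataclass(frozen=True)
class FiringParams:
    """Sigmoid firing non-linearity of a population ensemble.

    ``variance`` is the dispersion of membrane potentials around the mean
    within the ensemble (mV^2); a larger variance flattens the sigmoid.
    The logistic slope parameter is sqrt(variance).
    """

    threshold: float = V_THRESH  # mV
    variance: float = 64.0  # mV^2  (slope sqrt(variance) = 8 mV)

    def __post_init__(self):
        if self.variance <= 0:
            raise ValueError("ensemble firing variance must be positive")

    @property
    def slope(self) -> float:
        return float(np.sqrt(self.variance))


@dataclass
class PopulationState:
    """Four states of one population: V plus AMPA/GABA_A/NMDA conductances."""

    V: float
    g_AMPA: float = 0.0
    g_GABAA: float = 0.0
    g_NMDA: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.V, self.g_AMPA, self.g_GABAA, self.g_NMDA])


@dataclass
class SourceParams:
    """Natural-unit parameters of one source (one cortical column).

    Rate constants are in s^-1, delays in ms, currents in mV * gL units.
    """

    kappa: dict = field(
        default_factory=lambda: {
            r: 1000.0 / PRIOR_TAU_MS[r] for r in ReceptorKind
        }
    )
    mg: MgBlockParams = field(default_factory=MgBlockParams)
    firing: FiringParams = field(default_factory=FiringParams)
    background: float = 12.0  # tonic depolarizing current
    delay_ms: float = 1.0  # intra-source transmission delay
    leak_reversal: float = V_LEAK
    leak_conductance: float = G_LEAK
    capacitance: float = C_MEMBRANE

    def __post_init__(self):
        if any(k <= 0 for k in self.kappa.values()):
            raise ValueError("rate constants must be positive")
        if self.delay_ms <= 0:
            raise ValueError("delay must be positive")


def presynaptic_rate(V, fp: FiringParams):
    """Mean firing rate in (0, 1) of an ensemble with membrane potential V.

    Logistic sigmoid of (V - threshold), with slope set by the square root
    of the ensemble firing variance.  Strictly increasing in V.
    """
    if fp.variance <= 0:
        raise ValueError("ensemble firing variance must be positive")
    z = (np.asarray(V, dtype=float) - fp.threshold) / fp.slope
    return 0.5 * (1.0 + np.tanh(0.5 * z))  # numerically stable logistic


def presynaptic_rate_deriv(V, fp: FiringParams):
    """dF/dV of the firing sigmoid."""
    F = presynaptic_rate(V, fp)
    return F * (1.0 - F) / fp.slope


def mg_block_gain(V, mg: MgBlockParams):
    """Voltage-dependent NMDA gain alpha / (1 + beta exp(-gamma V)).

    Saturates at ``alpha`` for depolarized potentials and is strictly
    increasing in V (channels unblock with depolarization).
    """
    V = np.asarray(V, dtype=float)
    return mg.alpha / (1.0 + mg.beta * np.exp(-mg.gamma * V))


def mg_block_gain_deriv(V, mg: MgBlockParams):
    """d(gain)/dV = gamma * m * (1 - m/alpha)."""
    m = mg_block_gain(V, mg)
    return mg.gamma * m * (1.0 - m / mg.alpha)


def population_derivatives(
    state: PopulationState,
    presyn_inputs: dict,
    sp: SourceParams,
    mg: MgBlockParams | None = None,
) -> np.ndarray:
    """Time derivatives of one population's four states (per second).

    V' = ( g_L (V_L - V) + sum_r g_r m_r(V) (E_r - V) + background ) / C
    g_r' = kappa_r (drive_r - g_r)

    where m_r == 1 for AMPA/GABA_A and m_NMDA is the magnesium-block gain,
    and ``presyn_inputs`` maps each receptor to its coupling-weighted
    presynaptic drive.
    """
    mg = mg or sp.mg
    V = state.V
    g = {
        ReceptorKind.AMPA: state.g_AMPA,
        ReceptorKind.GABAA: state.g_GABAA,
        ReceptorKind.NMDA: state.g_NMDA,
    }
    gate = {
        ReceptorKind.AMPA: 1.0,
        ReceptorKind.GABAA: 1.0,
        ReceptorKind.NMDA: float(mg_block_gain(V, mg)),
    }
    current = sp.leak_conductance * (sp.leak_reversal - V) + sp.background
    for r in ReceptorKind:
        current += g[r] * gate[r] * (REVERSAL[r] - V)
    dV = current / sp.capacitance
    dg = [
        sp.kappa[r] * (float(presyn_inputs.get(r, 0.0)) - g[r])
        for r in ReceptorKind
    ]
    return np.array([dV, *dg])


def default_priors() -> dict:
    """Prior means of the microcircuit parameters, in natural units.

    Every free neuronal parameter is a log-scale factor on these prior
    means: value = prior_mean * exp(lambda), lambda ~ N(0, prior variance).
    """
    return {
        "tau_ms": dict(PRIOR_TAU_MS),
        "rate_constants_per_ms": {
            r: 1.0 / PRIOR_TAU_MS[r] for r in ReceptorKind
        },
        "reversal_mV": dict(REVERSAL),
        "leak_reversal_mV": V_LEAK,
        "mg_block": MgBlockParams(),
        "firing": FiringParams(),
        "background": SourceParams().background,
        "delay_ms": SourceParams().delay_ms,
        "capacitance": C_MEMBRANE,
        "leak_conductance": G_LEAK,
    }
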