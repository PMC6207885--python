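"""Fronto-parietal four-source network: nodes, edges, lead field, parameters.

The default network places left/right parietal and left/right prefrontal
sources at canonical MNI coordinates of the resting-state (default mode)
network.  Forward connections run from parietal superficial pyramidal cells
to frontal spiny stellate and deep pyramidal cells; backward connections
run from frontal deep pyramidal cells to parietal superficial pyramidal
cells and inhibitory interneurons.  Homologous sources are linked by fixed
lateral (interhemispheric) couplings between superficial pyramidal cells,
which carry no free gain parameters so that the free neuronal parameter
count of the default model is exactly 41.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .microcircuit import PopulationKind as P
from .params import ParamSpec, ParamPartition

__all__ = [
    "SourceNode",
    "Edge",
    "NetworkModel",
    "LeadField",
    "build_default_network",
    "count_parameters",
    "assemble_state_equations",
    "project_to_sensors",
]


@dataclass(frozen=True)
class SourceNode:
    name: str
    mni: tuple  # (x, y, z) in mm
    hemisphere: str  # "L" | "R"


@dataclass(frozen=True)
class Edge:
    source: str
    target: str
    name: str


@dataclass
class NetworkModel:
    """Nodes plus forward/backward/lateral edge structure and variant flag."""

    nodes: list
    forward: list   # parietal -> frontal, within hemisphere
    backward: list  # frontal -> parietal, within hemisphere
    lateral: list   # homologous interhemispheric SP -> SP links (fixed gain)
    include_sp_to_ss: bool = False

    def __post_init__(self):
        names = [n.name for n in self.nodes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate source names")
        for e in self.forward + self.backward + self.lateral:
            if e.source not in names or e.target not in names:
                raise ValueError(f"edge {e} refers to unknown source")

    @property
    def source_names(self) -> list:
        return [n.name for n in self.nodes]

    @property
    def n_sources(self) -> int:
        return len(self.nodes)

    @property
    def n_states(self) -> int:
        """Global state dimension: 4 populations x 4 states per source."""
        return 16 * self.n_sources

    def node_index(self, name: str) -> int:
        return self.source_names.index(name)

    def param_spec(self) -> ParamSpec:
        return ParamSpec(
            self.source_names,
            forward_names=[e.name for e in self.forward],
            backward_names=[e.name for e in self.backward],
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "nodes": [asdict(n) for n in self.nodes],
                "forward": [asdict(e) for e in self.forward],
                "backward": [asdict(e) for e in self.backward],
                "lateral": [asdict(e) for e in self.lateral],
                "include_sp_to_ss": self.include_sp_to_ss,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "NetworkModel":
        d = json.loads(text)
        return cls(
            nodes=[SourceNode(n["name"], tuple(n["mni"]), n["hemisphere"])
                   for n in d["nodes"]],
            forward=[Edge(**e) for e in d["forward"]],
            backward=[Edge(**e) for e in d["backward"]],
            lateral=[Edge(**e) for e in d["lateral"]],
            include_sp_to_ss=d["include_sp_to_ss"],
        )


#: Populations targeted by extrinsic connections.
FORWARD_TARGETS = (P.SS, P.DP)   # from SP of the origin
BACKWARD_TARGETS = (P.SP, P.II)  # from DP of the origin


def build_default_network(include_sp_to_ss: bool = False) -> NetworkModel:
    """The four-source resting-state network at canonical MNI locations."""
    nodes = [
        SourceNode("PL", (-29.0, -68.0, 49.0), "L"),  # left parietal
        SourceNode("PR", (29.0, -68.0, 49.0), "R"),   # right parietal
        SourceNode("FL", (-33.0, 45.0, 28.0), "L"),   # left prefrontal
        SourceNode("FR", (33.0, 45.0, 28.0), "R"),    # right prefrontal
    ]
    forward = [Edge("PL", "FL", "L"), Edge("PR", "FR", "R")]
    backward = [Edge("FL", "PL", "L"), Edge("FR", "PR", "R")]
    lateral = [
        Edge("PL", "PR", "P_lr"), Edge("PR", "PL", "P_rl"),
        Edge("FL", "FR", "F_lr"), Edge("FR", "FL", "F_rl"),
    ]
    return NetworkModel(nodes, forward, backward, lateral,
                        include_sp_to_ss=include_sp_to_ss)


def count_parameters(net: NetworkModel) -> ParamPartition:
    """Receptor-wise partition of the free neuronal parameter vector.

    For the default network: 15 NMDA (4 rate constants + 4 intrinsic
    weights to excitatory targets + 4 to inhibitory targets + 3 magnesium
    block), 12 AMPA (4 rate + 4 intrinsic + 2 forward + 2 backward), 8
    GABA_A (4 rate + 4 intrinsic) and 6 other (firing variance, background
    current, 4 delays) = 41 in total.
    """
    return net.param_spec().partition()


def assemble_state_equations(net: NetworkModel, params, config=None):
    """The network's global vector field and analytic Jacobian.

    Returns ``(f, jac)`` where ``f(x)`` maps a flattened global state (64
    entries for the default network) to its time derivative and ``jac(x)``
    returns the analytic Jacobian; both close over the natural-unit
    parameters derived from the log-scale vector ``params``.
    """
    from ._cmc import CMCEngine

    eng = CMCEngine(net, config)
    values = params.values if hasattr(params, "values") else np.asarray(params)
    nat = eng.materialize(np.atleast_2d(values))

    def f(x):
        return eng.f(np.atleast_2d(np.asarray(x, dtype=float)), nat)[0]

    def jac(x):
        return eng.jac(np.atleast_2d(np.asarray(x, dtype=float)), nat)[0]

    return f, jac


@dataclass
class LeadField:
    """Linear gain from source activity to scalp channels.

    ``gain`` is (n_channels x n_sources); ``population_weights`` scales each
    population's contribution to its source's summed output.  Inhibitory
    interneurons do not contribute to scalp EEG (weight 0): their dendritic
    arborization produces no open-field dipole.
    """

    gain: np.ndarray
    population_weights: np.ndarray = field(
        default_factory=lambda: np.array([0.1, 0.6, 0.0, 0.3])
    )
    channel_names: list | None = None

    def __post_init__(self):
        self.gain = np.asarray(self.gain, dtype=float)
        self.population_weights = np.asarray(self.population_weights, dtype=float)
        if self.population_weights.shape != (4,):
            raise ValueError("population_weights must have length 4")
        if self.population_weights[P.II] != 0.0:
            raise ValueError("inhibitory interneuron lead-field weight must be 0")


def project_to_sensors(source_csd: np.ndarray, lf: LeadField,
                       modes: np.ndarray) -> np.ndarray:
    """Project a per-frequency source CSD to sensor-mode space.

    S_modes(w) = M^T L S_src(w) L^T M for each frequency; the result is
    Hermitian whenever the input is.

    Parameters
    ----------
    source_csd : (..., n_freq, n_src, n_src) complex
    lf : LeadField with gain (n_channels, n_src)
    modes : (n_channels, n_modes) with orthonormal columns
    """
    source_csd = np.asarray(source_csd)
    L = lf.gain
    if L.shape[1] != source_csd.shape[-1]:
        raise ValueError("lead field / source CSD dimension mismatch")
    if modes.shape[0] != L.shape[0]:
        raise ValueError("mode matrix / lead field channel mismatch")
    A = modes.T @ L  # (n_modes, n_src)
    out = np.einsum("ms,...st,nt->...mn", A, source_csd, A.conj())
    # enforce exact Hermitian symmetry against rounding
    return 0.5 * (out + np.swapaxes(out, -1, -2).conj())
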