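"""Synthetic lead fields mapping the four sources to the 10-20 montage.

Subject anatomy is out of reach for a synthetic cohort, so two schematic
gain models are provided: a deterministic distance-based mapping built
from the 2-D schematic positions of the 10-20 electrodes (smooth, focal
topographies over the parietal/frontal sources), and a seeded random
matrix with unit-norm columns for tests that only need mixing structure.
"""

from __future__ import annotations

import numpy as np

from .containers import CHANNELS_1020
from .network import LeadField, NetworkModel

__all__ = ["schematic_lead_field", "random_lead_field", "ELECTRODE_XY"]

#: Schematic 2-D scalp positions (x: left-right, y: posterior-anterior),
#: unit head radius.
ELECTRODE_XY = {
    "Fp1": (-0.31, 0.95), "Fp2": (0.31, 0.95),
    "F7": (-0.81, 0.59), "F3": (-0.43, 0.55), "Fz": (0.0, 0.52),
    "F4": (0.43, 0.55), "F8": (0.81, 0.59),
    "T3": (-1.0, 0.0), "C3": (-0.52, 0.0), "Cz": (0.0, 0.0),
    "C4": (0.52, 0.0), "T4": (1.0, 0.0),
    "T5": (-0.81, -0.59), "P3": (-0.43, -0.55), "Pz": (0.0, -0.52),
    "P4": (0.43, -0.55), "T6": (0.81, -0.59),
    "O1": (-0.31, -0.95), "O2": (0.31, -0.95),
    "A1": (-1.15, 0.05), "A2": (1.15, 0.05),
}

#: Approximate scalp projections of the four default sources.
_SOURCE_XY = {
    "PL": (-0.35, -0.55), "PR": (0.35, -0.55),
    "FL": (-0.40, 0.60), "FR": (0.40, 0.60),
}


def schematic_lead_field(net: NetworkModel,
                         spread: float = 0.55,
                         channel_names=None) -> LeadField:
    """Deterministic gain matrix with Gaussian fall-off from each source's
    scalp projection; columns normalized to unit norm."""
    channel_names = list(channel_names or CHANNELS_1020)
    pos = np.array([ELECTRODE_XY[ch] for ch in channel_names])
    cols = []
    for node in net.nodes:
        if node.name in _SOURCE_XY:
            sx, sy = _SOURCE_XY[node.name]
        else:
            # fall back to the MNI x/y signs for non-default networks
            sx = np.clip(node.mni[0] / 80.0, -1, 1)
            sy = np.clip(node.mni[1] / 90.0, -1, 1)
        d2 = (pos[:, 0] - sx) ** 2 + (pos[:, 1] - sy) ** 2
        g = np.exp(-d2 / (2.0 * spread**2))
        cols.append(g / np.linalg.norm(g))
    return LeadField(np.column_stack(cols), channel_names=channel_names)


def random_lead_field(net: NetworkModel, seed: int,
                      channel_names=None) -> LeadField:
    """Seeded random gain matrix with unit-norm columns."""
    channel_names = list(channel_names or CHANNELS_1020)
    rng = np.random.default_rng(seed)
    G = rng.standard_normal((len(channel_names), net.n_sources))
    G /= np.linalg.norm(G, axis=0, keepdims=True)
    return LeadField(G, channel_names=channel_names)
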