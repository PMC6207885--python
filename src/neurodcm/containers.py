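"""Data containers and array I/O: recordings, epochs, spatial modes, CSDs.

Cross-spectra and spatial modes are stored in an HDF5 container with a
fixed layout: ``/csd/freqs``, ``/csd/real``, ``/csd/imag`` and ``/modes``.
EDF recordings are read through MNE.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np

__all__ = [
    "Recording",
    "EpochSet",
    "SpatialModes",
    "CrossSpectra",
    "CHANNELS_1020",
    "read_edf",
]

#: The 21-channel 10-20 montage used by routine clinical EEG.
CHANNELS_1020 = [
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "Cz", "C4", "T4",
    "T5", "P3", "Pz", "P4", "T6",
    "O1", "O2", "A1", "A2",
]


@dataclass
class Recording:
    """Multichannel EEG: (n_channels x n_samples) in microvolts."""

    samples: np.ndarray
    rate: float  # Hz
    channel_names: list = field(default_factory=lambda: list(CHANNELS_1020))

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be (n_channels, n_samples)")
        if len(self.channel_names) != self.samples.shape[0]:
            raise ValueError("channel_names length mismatch")
        if not (1.0 <= self.rate <= 5000.0):
            raise ValueError("implausible sampling rate")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def duration(self) -> float:
        return self.samples.shape[1] / self.rate

    def channel_index(self, name: str) -> int:
        return self.channel_names.index(name)


@dataclass
class EpochSet:
    """Artifact-screened segments: (n_epochs x n_channels x n_samples)."""

    epochs: np.ndarray
    rate: float
    channel_names: list
    epoch_length: float = 5.0  # seconds
    n_rejected: int = 0

    def __post_init__(self):
        self.epochs = np.asarray(self.epochs, dtype=float)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be (n_epochs, n_channels, n_samples)")

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]


@dataclass
class SpatialModes:
    """Orthonormal channel mixtures (left singular vectors) and weights."""

    matrix: np.ndarray  # (n_channels, k)
    singular_values: np.ndarray

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        gram = self.matrix.T @ self.matrix
        if not np.allclose(gram, np.eye(self.matrix.shape[1]), atol=1e-8):
            raise ValueError("mode columns must be orthonormal")

    @property
    def k(self) -> int:
        return self.matrix.shape[1]


@dataclass
class CrossSpectra:
    """Hermitian complex CSD per frequency: (n_freq, m, m)."""

    freqs: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.values = np.asarray(self.values, dtype=complex)
        if self.values.ndim != 3 or self.values.shape[0] != self.freqs.size:
            raise ValueError("values must be (n_freq, m, m)")
        if self.values.shape[1] != self.values.shape[2]:
            raise ValueError("CSD matrices must be square")

    @property
    def n_modes(self) -> int:
        return self.values.shape[1]

    def is_hermitian(self, atol: float = 1e-10) -> bool:
        return bool(
            np.allclose(
                self.values, np.swapaxes(self.values, 1, 2).conj(), atol=atol
            )
        )

    def band(self, f_lo: float, f_hi: float) -> "CrossSpectra":
        sel = (self.freqs >= f_lo) & (self.freqs <= f_hi)
        return CrossSpectra(self.freqs[sel], self.values[sel])

    # ------------------------------ I/O ------------------------------ #
    def save(self, path, modes: SpatialModes | None = None) -> None:
        with h5py.File(path, "w") as h:
            g = h.create_group("csd")
            g.create_dataset("freqs", data=self.freqs)
            g.create_dataset("real", data=self.values.real)
            g.create_dataset("imag", data=self.values.imag)
            if modes is not None:
                h.create_dataset("modes", data=modes.matrix)
                h.create_dataset("modes_sv", data=modes.singular_values)

    @classmethod
    def load(cls, path):
        with h5py.File(path, "r") as h:
            freqs = h["csd/freqs"][()]
            vals = h["csd/real"][()] + 1j * h["csd/imag"][()]
            modes = None
            if "modes" in h:
                modes = SpatialModes(h["modes"][()], h["modes_sv"][()])
        cs = cls(freqs, vals)
        return (cs, modes) if modes is not None else (cs, None)


def read_edf(path, channel_names: list | None = None) -> Recording:
    """Load an EDF recording into microvolt samples via MNE."""
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    picks = channel_names or raw.ch_names
    data = raw.get_data(picks=picks) * 1e6  # volts -> microvolts
    return Recording(data, raw.info["sfreq"], list(picks))
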