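"""Labeled parameter vectors for the four-source receptor model.

All free neuronal parameters are *log-scale factors* on fixed prior means:
the natural value of parameter i is ``prior_mean_i * exp(lambda_i)`` with
``lambda_i ~ Normal(0, prior_variance_i)``.  The neuronal vector of the
default network has exactly 41 entries; observation/noise parameters
(innovations and channel noise spectra) are tracked separately and are not
part of the neuronal count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ParamSpec", "ParamVector", "ParamPartition", "OBS_LABELS"]

#: Observation-model parameters (log-scale factors), outside the neuronal set:
#: innovations amplitude/exponent, mode-noise amplitude/exponent, common-noise
#: amplitude.
OBS_LABELS = ("obs_u_amp", "obs_u_exp", "obs_n_amp", "obs_n_exp", "obs_c_amp")

# Default prior variances on the log-scale factors, keyed by label prefix.
_PRIOR_VAR = {
    "kappa_": 1.0 / 16,
    "g_": 1.0 / 8,
    "ext_": 1.0 / 8,
    "firing_variance": 1.0 / 16,
    "background": 1.0 / 16,
    "mg_": 1.0 / 16,
    "delay.": 1.0 / 32,
    "obs_u_amp": 1.0 / 4,
    "obs_n_amp": 1.0 / 4,
    "obs_c_amp": 1.0 / 4,
    "obs_u_exp": 1.0 / 16,
    "obs_n_exp": 1.0 / 16,
}


@dataclass(frozen=True)
class ParamPartition:
    """Disjoint index sets over the neuronal parameter vector by receptor."""

    nmda: np.ndarray
    ampa: np.ndarray
    gabaa: np.ndarray
    other: np.ndarray

    @property
    def sizes(self) -> dict:
        return {
            "NMDA": self.nmda.size,
            "AMPA": self.ampa.size,
            "GABAA": self.gabaa.size,
            "OTHER": self.other.size,
        }

    @property
    def total(self) -> int:
        return sum(self.sizes.values())


def _classify(label: str) -> str:
    if label.startswith(("kappa_NMDA", "g_NMDA", "mg_")):
        return "NMDA"
    if label.startswith(("kappa_AMPA", "g_AMPA", "ext_")):
        return "AMPA"
    if label.startswith(("kappa_GABAA", "g_GABAA")):
        return "GABAA"
    return "OTHER"


class ParamSpec:
    """Canonical labeling, prior variances and partition for a network.

    Parameters are ordered: per-source rate constants (3 per receptor class
    x sources), per-source intrinsic gains (AMPA, GABA_A, NMDA-to-excitatory,
    NMDA-to-inhibitory), extrinsic forward/backward log-gains, the shared
    ensemble firing variance and background current, the three magnesium
    block parameters, and per-source intra-source delays.
    """

    def __init__(self, source_names, n_forward: int = 2, n_backward: int = 2,
                 forward_names=None, backward_names=None):
        self.source_names = list(source_names)
        labels: list[str] = []
        for rec in ("AMPA", "GABAA", "NMDA"):
            labels += [f"kappa_{rec}.{s}" for s in self.source_names]
        for g in ("g_AMPA", "g_GABAA", "g_NMDA_exc", "g_NMDA_inh"):
            labels += [f"{g}.{s}" for s in self.source_names]
        fnames = forward_names or [str(i) for i in range(n_forward)]
        bnames = backward_names or [str(i) for i in range(n_backward)]
        labels += [f"ext_forward.{e}" for e in fnames]
        labels += [f"ext_backward.{e}" for e in bnames]
        labels += ["firing_variance", "background"]
        labels += ["mg_alpha", "mg_beta", "mg_gamma"]
        labels += [f"delay.{s}" for s in self.source_names]
        self.labels: tuple[str, ...] = tuple(labels)
        self._index = {lab: i for i, lab in enumerate(labels)}

    @property
    def n_params(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self._index[label]

    def indices(self, prefix: str) -> np.ndarray:
        return np.array(
            [i for i, lab in enumerate(self.labels) if lab.startswith(prefix)],
            dtype=int,
        )

    def partition(self) -> ParamPartition:
        sets: dict[str, list[int]] = {k: [] for k in ("NMDA", "AMPA", "GABAA", "OTHER")}
        for i, lab in enumerate(self.labels):
            sets[_classify(lab)].append(i)
        return ParamPartition(
            nmda=np.array(sets["NMDA"]),
            ampa=np.array(sets["AMPA"]),
            gabaa=np.array(sets["GABAA"]),
            other=np.array(sets["OTHER"]),
        )

    def prior_variances(self, overrides: dict | None = None) -> np.ndarray:
        """Per-parameter prior variance on the log-scale factors."""
        out = np.empty(self.n_params)
        for i, lab in enumerate(self.labels):
            v = None
            for prefix, var in _PRIOR_VAR.items():
                if lab.startswith(prefix):
                    v = var
                    break
            if v is None:
                raise KeyError(f"no prior variance rule for {lab}")
            out[i] = v
        if overrides:
            for lab, var in overrides.items():
                out[self._index[lab]] = var
        return out

    def zeros(self) -> "ParamVector":
        return ParamVector(self, np.zeros(self.n_params))


@dataclass
class ParamVector:
    """A concrete vector of log-scale factors tied to a :class:`ParamSpec`."""

    spec: ParamSpec
    values: np.ndarray
    obs: np.ndarray = field(default_factory=lambda: np.zeros(len(OBS_LABELS)))

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.obs = np.asarray(self.obs, dtype=float)
        if self.values.shape != (self.spec.n_params,):
            raise ValueError(
                f"expected {self.spec.n_params} neuronal parameters, "
                f"got {self.values.shape}"
            )
        if self.obs.shape != (len(OBS_LABELS),):
            raise ValueError("observation parameter vector has wrong length")

    def __getitem__(self, label: str) -> float:
        return float(self.values[self.spec.index(label)])

    def set(self, label: str, value: float) -> "ParamVector":
        self.values[self.spec.index(label)] = value
        return self

    def copy(self) -> "ParamVector":
        return ParamVector(self.spec, self.values.copy(), self.obs.copy())

    def to_series(self) -> pd.Series:
        return pd.Series(
            np.concatenate([self.values, self.obs]),
            index=list(self.spec.labels) + list(OBS_LABELS),
        )

    def to_json_dict(self) -> dict:
        return {k: float(v) for k, v in self.to_series().items()}

    @classmethod
    def from_series(cls, spec: ParamSpec, s: pd.Series) -> "ParamVector":
        vals = np.array([s[lab] for lab in spec.labels])
        obs = np.array([s.get(lab, 0.0) for lab in OBS_LABELS])
        return cls(spec, vals, obs)
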