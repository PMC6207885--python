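"""Synthetic cohort generation: the study conditions in silico.

Because no patient EEG is distributed, the cohort generator plays the role
of the clinical dataset: three groups (NMDAR-antibody encephalitis n=29,
other encephalopathy n=18, neurological controls n=18), each subject a
draw of log-scale parameters around group-specific effect vectors, with
sensor data produced either by stochastic integration of the full
nonlinear model (``timeseries`` mode) or by sampling a finite-epoch
Wishart estimate around the analytic cross-spectrum (``fast`` mode).

Group effects mirror the clinical findings: the encephalitis effect is a
negative shift on NMDA rate constants at three sources and on the
intrinsic NMDA weight onto excitatory cells at two sources; the
encephalopathy effect combines small mixed shifts across all three
receptor classes with a slowed, strengthened endogenous drive (the
classical diffuse EEG slowing of encephalopathy).  Encephalitis subjects
are themselves encephalopathic, so they receive a partial encephalopathy
load plus the NMDA-specific deficit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._cmc import CMCEngine, ModelConfig
from .containers import CHANNELS_1020, CrossSpectra, Recording, SpatialModes
from .forward import ForwardModel, NoiseParams
from .leadfield import schematic_lead_field
from .network import LeadField, NetworkModel, build_default_network
from .params import OBS_LABELS, ParamSpec, ParamVector

__all__ = [
    "CohortSpec",
    "CohortTable",
    "default_effects",
    "sample_subject_params",
    "simulate_sensor_timeseries",
    "generate_cohort",
]

#: The five NMDA parameters carrying the encephalitis deficit: channel
#: kinetics at the right parietal and both prefrontal sources, and the
#: intrinsic NMDA weight onto excitatory cells at the right parietal and
#: left prefrontal sources.
ENCEPHALITIS_TARGETS = (
    "kappa_NMDA.PR",
    "kappa_NMDA.FL",
    "kappa_NMDA.FR",
    "g_NMDA_exc.PR",
    "g_NMDA_exc.FL",
)


def default_effects(deficit: float = -1.0,
                    encephalopathy_load: float = 0.4) -> dict:
    """Calibrated group effect vectors on the log-scale parameters.

    Returns ``{group: ({neuronal label: shift}, {obs label: shift})}``.
    The encephalopathy drive shifts (stronger, steeper innovations
    spectrum) reproduce diffuse EEG slowing; its receptor shifts are mild
    and span all three receptor classes.  The encephalitis group carries
    ``encephalopathy_load`` times the encephalopathy effect plus the
    NMDA-specific deficit.
    """
    enceph_neuronal = {}
    for s in ("PL", "PR", "FL", "FR"):
        enceph_neuronal[f"kappa_AMPA.{s}"] = -0.02
        enceph_neuronal[f"kappa_GABAA.{s}"] = -0.05
        enceph_neuronal[f"kappa_NMDA.{s}"] = -0.10
        enceph_neuronal[f"g_AMPA.{s}"] = 0.03
        enceph_neuronal[f"g_GABAA.{s}"] = -0.05
        enceph_neuronal[f"g_NMDA_exc.{s}"] = -0.05
    enceph_obs = {"obs_u_amp": 0.02, "obs_u_exp": 0.55}
    nmdar_neuronal = {
        k: encephalopathy_load * v for k, v in enceph_neuronal.items()
    }
    for lab in ENCEPHALITIS_TARGETS:
        nmdar_neuronal[lab] = nmdar_neuronal.get(lab, 0.0) + deficit
    nmdar_obs = {k: encephalopathy_load * v for k, v in enceph_obs.items()}
    # cortical hyperexcitability: increased broadband endogenous drive in
    # the encephalitis group (beta elevation riding on stronger input)
    nmdar_obs["obs_u_amp"] = nmdar_obs.get("obs_u_amp", 0.0) + 0.15
    return {
        "control": ({}, {}),
        "encephalopathy": (enceph_neuronal, enceph_obs),
        "nmdar": (nmdar_neuronal, nmdar_obs),
    }


@dataclass
class CohortSpec:
    """Everything needed to generate a reproducible synthetic cohort."""

    group_sizes: dict = field(
        default_factory=lambda: {"nmdar": 29, "encephalopathy": 18,
                                 "control": 18}
    )
    effects: dict = field(default_factory=default_effects)
    between_subject_sd: float = 0.03   # on neuronal log parameters
    obs_sd: float = 0.06               # on observation log parameters
    duration: float = 600.0            # seconds (timeseries mode)
    rate: float = 250.0                # Hz
    n_epochs: int = 144                # Wishart dof in fast mode
    band: tuple = (1.0, 48.0)
    df: float = 1.0
    alpha_amplitude: float = 0.0       # occipital 10 Hz confound (power units)
    alpha_fraction: float = 0.0        # fraction of nmdar subjects confounded
    seed: int = 2026
    n_modes: int = 8
    max_resample: int = 20

    def __post_init__(self):
        if any(n < 1 for n in self.group_sizes.values()):
            raise ValueError("group sizes must be >= 1")
        if self.between_subject_sd < 0 or self.obs_sd < 0:
            raise ValueError("between-subject SDs must be >= 0")
        if not (0.0 <= self.alpha_fraction <= 1.0):
            raise ValueError("alpha_fraction must lie in [0, 1]")

    @property
    def n_subjects(self) -> int:
        return sum(self.group_sizes.values())

    def freqs(self) -> np.ndarray:
        f_lo, f_hi = self.band
        return np.arange(f_lo, f_hi + 0.5 * self.df, self.df)


@dataclass
class CohortTable:
    """Generated cohort: labels, ground truth and data per subject."""

    table: pd.DataFrame            # id, group, seed, alpha_confound, alpha_power
    params: dict                   # id -> ParamVector (ground truth)
    csd: dict                      # id -> CrossSpectra (mode space)
    modes: dict                    # id -> SpatialModes
    lead_field: LeadField
    recordings: dict = field(default_factory=dict)  # id -> Recording
    n_unstable_resampled: int = 0

    def groups(self):
        return self.table["group"].to_numpy()

    def ground_truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {sid: pv.to_series() for sid, pv in self.params.items()}
        ).T

    def save(self, out_dir) -> None:
        """Write groups CSV, ground-truth CSV and per-subject containers."""
        import pathlib

        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        try:
            self.table.to_csv(out / "groups.csv", index=False)
            self.ground_truth_frame().to_csv(out / "ground_truth.csv")
            for sid, cs in self.csd.items():
                cs.save(out / f"{sid}_csd.h5", modes=self.modes[sid])
        except OSError as err:
            raise OSError(f"failed writing cohort to {out}: {err}") from err


def sample_subject_params(spec: CohortSpec, group: str, rng,
                          param_spec: ParamSpec) -> ParamVector:
    """One subject's log-scale parameters: group effect plus Gaussian
    between-subject variability, element-wise."""
    neuronal_eff, obs_eff = spec.effects[group]
    lam = np.zeros(param_spec.n_params)
    for lab, v in neuronal_eff.items():
        lam[param_spec.index(lab)] += v
    lam += spec.between_subject_sd * rng.standard_normal(lam.size)
    obs = np.zeros(len(OBS_LABELS))
    for lab, v in obs_eff.items():
        obs[OBS_LABELS.index(lab)] += v
    obs += spec.obs_sd * rng.standard_normal(obs.size)
    return ParamVector(param_spec, lam, obs)


# --------------------------------------------------------------------- #
# noise synthesis shared by both generation modes
# --------------------------------------------------------------------- #
def _powerlaw_noise(psd_fn, n_samples: int, rate: float, rng,
                    size: int = 1, f_max: float | None = None) -> np.ndarray:
    """Gaussian series with a target one-sided PSD via spectral synthesis.

    ``f_max`` truncates the spectrum (band-limited noise); frequencies
    below 0.5 Hz reuse the 0.5 Hz density so power-law exponents stay
    integrable.
    """
    freqs = np.fft.rfftfreq(n_samples, 1.0 / rate)
    amp = np.zeros_like(freqs)
    pos = freqs > 0
    if f_max is not None:
        pos &= freqs <= f_max
    amp[pos] = np.sqrt(psd_fn(np.maximum(freqs[pos], 0.5)) * rate * n_samples / 2.0)
    X = amp * (
        rng.standard_normal((size, freqs.size))
        + 1j * rng.standard_normal((size, freqs.size))
    ) / np.sqrt(2.0)
    X[:, 0] = 0.0
    if n_samples % 2 == 0:
        X[:, -1] = X[:, -1].real * np.sqrt(2.0)
    return np.fft.irfft(X, n=n_samples, axis=1)


def _alpha_bump(freqs: np.ndarray, amplitude: float,
                center: float = 10.0, width: float = 1.0) -> np.ndarray:
    return amplitude**2 * np.exp(-((np.asarray(freqs) - center) ** 2)
                                 / (2.0 * width**2))


def _channel_csd(fm: ForwardModel, pv: ParamVector, freqs: np.ndarray,
                 lf: LeadField, alpha_amp: float) -> np.ndarray | None:
    """Analytic channel-space CSD for one subject (None if unstable)."""
    from .forward import transfer_functions

    try:
        lin = fm.linearize(pv)
    except RuntimeError:
        return None
    if lin.max_eig_real >= 0:
        return None
    eng = fm.engine
    Out_src = eng.output_matrix(lf.population_weights)
    H = np.empty((freqs.size, eng.S, eng.S), dtype=complex)
    w, U = np.linalg.eig(lin.delayed_jacobian)
    UinvB = np.linalg.solve(U, lin.input_matrix.astype(complex))
    OU = Out_src.astype(complex) @ U
    iw = 2j * np.pi * freqs
    R = 1.0 / (iw[:, None] - w[None, :])
    H = np.einsum("om,fm,mk->fok", OU, R, UinvB)
    noise = NoiseParams.from_log_scales(pv.obs)
    Gu = noise.innovations(freqs)
    S_src = np.einsum("fik,f,fjk->fij", H, Gu, H.conj())
    L = lf.gain
    S_ch = np.einsum("cs,fst,dt->fcd", L, S_src, L.conj())
    n_ch = L.shape[0]
    S_ch += noise.mode_noise(freqs)[:, None, None] * np.eye(n_ch)
    S_ch += noise.common_noise(freqs)[:, None, None] * (
        np.ones((n_ch, n_ch)) / n_ch
    )
    if alpha_amp > 0:
        names = lf.channel_names or CHANNELS_1020
        v = np.zeros(n_ch)
        v[names.index("O1")] = 1.0 / np.sqrt(2.0)
        v[names.index("O2")] = 1.0 / np.sqrt(2.0)
        S_ch += _alpha_bump(freqs, alpha_amp)[:, None, None] * np.outer(v, v)
    return 0.5 * (S_ch + np.swapaxes(S_ch, 1, 2).conj())


def _modes_from_csd(S_ch: np.ndarray, k: int) -> SpatialModes:
    C = S_ch.real.mean(axis=0)
    w, V = np.linalg.eigh(C)
    order = np.argsort(w)[::-1][:k]
    U, sv = V[:, order], np.sqrt(np.maximum(w[order], 0))
    flip = np.sign(U[np.abs(U).argmax(axis=0), np.arange(k)])
    return SpatialModes(U * flip, sv)


def _wishart_sample(S: np.ndarray, dof: int, rng) -> np.ndarray:
    """Finite-epoch CSD estimate: complex Wishart around the true CSD."""
    out = np.empty_like(S)
    m = S.shape[-1]
    for i in range(S.shape[0]):
        A = np.linalg.cholesky(S[i] + 1e-12 * np.trace(S[i].real) / m * np.eye(m))
        Z = (rng.standard_normal((m, dof))
             + 1j * rng.standard_normal((m, dof))) / np.sqrt(2.0)
        W = Z @ Z.conj().T / dof
        out[i] = A @ W @ A.conj().T
    return 0.5 * (out + np.swapaxes(out, 1, 2).conj())


# --------------------------------------------------------------------- #
# time-series simulation
# --------------------------------------------------------------------- #
def simulate_sensor_timeseries(params: ParamVector, spec: CohortSpec,
                               lf: LeadField, rng,
                               net: NetworkModel | None = None,
                               config: ModelConfig | None = None,
                               alpha_amp: float = 0.0,
                               sim_rate: float = 2000.0) -> Recording:
    """Stochastic realization of the generative model as a 21-channel EEG.

    Euler-Maruyama integration of the coupled ODEs driven by power-law
    innovations into the spiny stellate populations, projected through the
    population-weighted lead field, with additive channel and common
    noise; an optional narrowband 10 Hz component enters O1/O2.
    """
    net = net or build_default_network()
    eng = CMCEngine(net, config)
    nat = eng.materialize(params.values[None, :])
    x, ok = eng.fixed_point(nat)
    if not ok[0]:
        raise RuntimeError("no stable fixed point for the requested subject")
    noise = NoiseParams.from_log_scales(params.obs)

    n_out = int(round(spec.duration * spec.rate))
    sub = int(round(sim_rate / spec.rate))
    n_sim = n_out * sub
    dt = 1.0 / sim_rate
    # innovations: band-limited power-law drive (the synaptic input spectrum
    # is only constrained below the analysis band's upper edge; truncating
    # at 120 Hz keeps the explicit integrator well-behaved)
    u = _powerlaw_noise(noise.innovations, n_sim, sim_rate, rng, size=eng.S,
                        f_max=120.0)
    S_, P_ = eng.S, 4
    out = np.empty((n_out, eng.S))
    Wpop = lf.population_weights
    from .microcircuit import (C_MEMBRANE, G_LEAK, V_LEAK,  # noqa: F401
                               PopulationKind as P, ReceptorKind as R)
    from ._cmc import _E

    # Transmission delays enter through the same first-order compensation
    # as the linearized model: the integrated field is M f(x) with
    # M = (I + D o J(x*))^-1 evaluated at the fixed point, so the
    # stochastic realization and the analytic cross-spectrum share one
    # delay treatment by construction.
    J_star = eng.jac(x, nat)
    D = eng.delay_matrix(nat)[0]
    M = np.linalg.inv(np.eye(eng.n) + D * J_star[0])
    kap = nat["kappa"][0][:, None, :]               # (S,1,3)
    slope = nat["slope"][0]
    bg = nat["bg"][0]
    a_m, b_m, g_m = nat["mg_alpha"][0], nat["mg_beta"][0], nat["mg_gamma"][0]
    C = eng.C
    Wmix = nat["W"][0].reshape(S_ * P_ * 3, S_ * P_)
    xs = np.array(x[0]).reshape(S_, P_, 4)
    V = xs[..., 0].copy()
    g = xs[..., 1:].copy()
    u_idx = (np.arange(S_), P.SS, R.AMPA)
    dx = np.empty((S_, P_, 4))

    def field(V_, g_, u_t):
        F = 0.5 * (1.0 + np.tanh(0.5 * (V_ + 40.0) / slope))
        drive = (Wmix @ F.ravel()).reshape(S_, P_, 3)
        drive[u_idx] += u_t
        m = a_m / (1.0 + b_m * np.exp(-g_m * V_))
        cur = (G_LEAK * (V_LEAK - V_) + bg
               + g_[..., 0] * (_E[0] - V_)
               + g_[..., 1] * (_E[1] - V_)
               + g_[..., 2] * m * (_E[2] - V_))
        dx[..., 0] = cur / C
        dx[..., 1:] = kap * (drive - g_)
        return (M @ dx.ravel()).reshape(S_, P_, 4)

    # Heun (explicit trapezoid) steps: forward Euler at this step size
    # would shift the fast resonant poles noticeably
    for t in range(n_sim):
        k1 = field(V, g, u[:, t])
        k2 = field(V + dt * k1[..., 0], g + dt * k1[..., 1:], u[:, t])
        V += 0.5 * dt * (k1[..., 0] + k2[..., 0])
        g += 0.5 * dt * (k1[..., 1:] + k2[..., 1:])
        if t % sub == sub - 1:
            out[t // sub] = V @ Wpop
    y = out @ lf.gain.T  # (n_out, n_ch)
    n_ch = lf.gain.shape[0]
    y += _powerlaw_noise(noise.mode_noise, n_out, spec.rate, rng,
                         size=n_ch).T
    common = _powerlaw_noise(noise.common_noise, n_out, spec.rate, rng)[0]
    y += common[:, None] / np.sqrt(n_ch)
    if alpha_amp > 0:
        alpha = _powerlaw_noise(
            lambda f: _alpha_bump(f, alpha_amp), n_out, spec.rate, rng
        )[0]
        names = lf.channel_names or CHANNELS_1020
        for ch in ("O1", "O2"):
            y[:, names.index(ch)] += alpha / np.sqrt(2.0)
    return Recording(y.T, spec.rate,
                     list(lf.channel_names or CHANNELS_1020))


# --------------------------------------------------------------------- #
# cohort assembly
# --------------------------------------------------------------------- #
def generate_cohort(spec: CohortSpec | None = None, mode: str = "fast",
                    net: NetworkModel | None = None,
                    config: ModelConfig | None = None,
                    lf: LeadField | None = None,
                    out_dir=None) -> CohortTable:
    """Generate a full cohort; reproducible from ``spec.seed``.

    ``fast`` mode samples finite-epoch Wishart estimates around each
    subject's analytic CSD; ``timeseries`` mode integrates the stochastic
    model and runs the spectral feature path on the simulated recording.
    Unstable parameter draws are rejected and resampled (counted in the
    returned table's metadata).
    """
    from . import spectral

    spec = spec or CohortSpec()
    net = net or build_default_network()
    lf = lf or schematic_lead_field(net)
    pspec = net.param_spec()
    fm = ForwardModel(net, lf, np.eye(lf.gain.shape[0])[:, :spec.n_modes],
                      config)
    root = np.random.default_rng(spec.seed)
    freqs = spec.freqs()

    rows = []
    params: dict = {}
    csds: dict = {}
    modes: dict = {}
    recs: dict = {}
    n_resampled = 0
    sid_counter = 0
    for group in ("control", "encephalopathy", "nmdar"):
        n_g = spec.group_sizes.get(group, 0)
        for _ in range(n_g):
            sid = f"sub{sid_counter:03d}"
            sid_counter += 1
            sub_seed = int(root.integers(0, 2**31 - 1))
            rng = np.random.default_rng(sub_seed)
            confound = (
                group == "nmdar"
                and spec.alpha_amplitude > 0
                and rng.random() < spec.alpha_fraction
            )
            a_amp = spec.alpha_amplitude if confound else 0.0
            pv = None
            S_ch = None
            for _try in range(spec.max_resample):
                cand = sample_subject_params(spec, group, rng, pspec)
                S_ch = _channel_csd(fm, cand, freqs, lf, a_amp)
                if S_ch is not None:
                    pv = cand
                    break
                n_resampled += 1
            if pv is None:
                raise RuntimeError(
                    f"{spec.max_resample} consecutive unstable draws for "
                    f"group {group}"
                )
            sm = _modes_from_csd(S_ch, spec.n_modes)
            a_pow = spectral.alpha_power(
                CrossSpectra(freqs, S_ch), lf.channel_names or CHANNELS_1020
            )
            if mode == "fast":
                S_mode = np.einsum("cm,fcd,dn->fmn", sm.matrix.conj(), S_ch,
                                   sm.matrix)
                S_hat = _wishart_sample(S_mode, spec.n_epochs, rng)
                cs = CrossSpectra(freqs, S_hat)
            elif mode == "timeseries":
                rec = simulate_sensor_timeseries(
                    pv, spec, lf, rng, net=net, config=config,
                    alpha_amp=a_amp,
                )
                recs[sid] = rec
                es = spectral.preprocess(rec)
                sm = spectral.compute_spatial_modes(es, spec.n_modes)
                cs = spectral.mar_cross_spectra(
                    es, sm, band=spec.band, df=spec.df
                )
            else:
                raise ValueError("mode must be 'fast' or 'timeseries'")
            rows.append(
                {"id": sid, "group": group, "seed": sub_seed,
                 "alpha_confound": bool(confound), "alpha_power": a_pow}
            )
            params[sid] = pv
            csds[sid] = cs
            modes[sid] = sm
    table = CohortTable(
        table=pd.DataFrame(rows),
        params=params,
        csd=csds,
        modes=modes,
        lead_field=lf,
        recordings=recs,
        n_unstable_resampled=n_resampled,
    )
    if out_dir is not None:
        table.save(out_dir)
    return table
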