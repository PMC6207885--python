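"""Sensor-space data features: epoching, spatial modes, AR cross-spectra.

A recording is low-pass filtered, cut into 5-s epochs, screened with
automated amplitude/gradient thresholds, compressed to eight orthonormal
spatial modes by singular value decomposition, and summarized as a
Hermitian mode-space cross-spectral density estimated from a multivariate
autoregressive model fitted per epoch.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import signal as sp_signal
from scipy import stats as sp_stats

from .containers import CrossSpectra, EpochSet, Recording, SpatialModes

__all__ = [
    "preprocess",
    "compute_spatial_modes",
    "mar_cross_spectra",
    "count_data_points",
    "band_power_summary",
    "alpha_power",
    "group_band_anova",
    "EmptyDataError",
]


class EmptyDataError(RuntimeError):
    """No epochs survived artifact rejection."""


def preprocess(rec: Recording,
               amplitude_threshold: float = 100.0,
               gradient_threshold: float = 50.0,
               epoch_length: float = 5.0,
               lowpass_hz: float = 42.0) -> EpochSet:
    """Filter, epoch and artifact-screen a recording.

    The recording is low-pass filtered (5th-order Butterworth, zero phase)
    at ``lowpass_hz``, split into non-overlapping ``epoch_length``-second
    segments, and epochs containing any sample above
    ``amplitude_threshold`` (uV, absolute) or any sample-to-sample step
    above ``gradient_threshold`` (uV) *before filtering* are rejected.
    """
    n_per = int(round(epoch_length * rec.rate))
    n_epochs = rec.samples.shape[1] // n_per
    if n_epochs < 1:
        raise EmptyDataError("recording shorter than one epoch")
    raw = rec.samples[:, : n_epochs * n_per].reshape(
        rec.n_channels, n_epochs, n_per
    ).transpose(1, 0, 2)
    # rejection on unfiltered data (artifacts are broadband)
    amp_bad = np.abs(raw).max(axis=(1, 2)) > amplitude_threshold
    grad_bad = np.abs(np.diff(raw, axis=2)).max(axis=(1, 2)) > gradient_threshold
    keep = ~(amp_bad | grad_bad)
    if not keep.any():
        raise EmptyDataError(
            f"all {n_epochs} epochs rejected "
            f"(amplitude > {amplitude_threshold} uV or "
            f"gradient > {gradient_threshold} uV)"
        )
    sos = sp_signal.butter(5, lowpass_hz, btype="low", fs=rec.rate, output="sos")
    filtered = sp_signal.sosfiltfilt(sos, rec.samples, axis=1)
    epochs = filtered[:, : n_epochs * n_per].reshape(
        rec.n_channels, n_epochs, n_per
    ).transpose(1, 0, 2)[keep]
    return EpochSet(
        epochs=epochs,
        rate=rec.rate,
        channel_names=list(rec.channel_names),
        epoch_length=epoch_length,
        n_rejected=int((~keep).sum()),
    )


def compute_spatial_modes(es: EpochSet, k: int = 8) -> SpatialModes:
    """Top-k left singular vectors of the concatenated channel x time data.

    Each mode's sign is fixed by forcing its largest-magnitude element
    positive (the SVD sign ambiguity is otherwise arbitrary).
    """
    n_ch = es.epochs.shape[1]
    if k > n_ch:
        raise ValueError(f"k={k} exceeds channel count {n_ch}")
    X = es.epochs.transpose(1, 0, 2).reshape(n_ch, -1)
    X = X - X.mean(axis=1, keepdims=True)
    U, sv, _ = np.linalg.svd(X, full_matrices=False)
    U, sv = U[:, :k], sv[:k]
    flip = np.sign(U[np.abs(U).argmax(axis=0), np.arange(k)])
    return SpatialModes(U * flip, sv)


def _mar_spectrum(coefs: np.ndarray, sigma: np.ndarray, freqs: np.ndarray,
                  rate: float) -> np.ndarray:
    """CSD of a vector AR model: S(f) = A(f)^-1 Sigma A(f)^-H / fs."""
    p, m, _ = coefs.shape
    om = 2j * np.pi * np.asarray(freqs) / rate
    S = np.empty((len(freqs), m, m), dtype=complex)
    eye = np.eye(m)
    for i, w in enumerate(om):
        A = eye - sum(
            coefs[k] * np.exp(-w * (k + 1)) for k in range(p)
        )
        Ainv = np.linalg.inv(A)
        S[i] = Ainv @ sigma @ Ainv.conj().T / rate
    return S


def mar_cross_spectra(es: EpochSet, modes: SpatialModes, order: int = 8,
                      band=(1.0, 48.0), df: float = 1.0) -> CrossSpectra:
    """Mode-space CSD from per-epoch multivariate autoregressive fits.

    Each epoch's mode time series is fitted with a VAR(order) model by
    least squares; the model-implied cross-spectra are evaluated on the
    grid ``band[0]:df:band[1]`` and averaged over epochs (robust to
    epoch-wise non-stationarity).
    """
    if order < 1:
        raise ValueError("AR order must be >= 1")
    f_lo, f_hi = band
    nyq = es.rate / 2.0
    if not (0 < f_lo <= f_hi < nyq):
        raise ValueError(f"band {band} outside (0, {nyq})")
    from statsmodels.tsa.ar_model import AutoReg
    from statsmodels.tsa.vector_ar.var_model import VAR

    freqs = np.arange(f_lo, f_hi + 0.5 * df, df)
    Y = np.einsum("ck,ect->ekt", modes.matrix, es.epochs)  # (epochs, k, t)
    acc = np.zeros((len(freqs), modes.k, modes.k), dtype=complex)
    for ep in range(Y.shape[0]):
        y = Y[ep].T  # (t, k)
        y = y - y.mean(axis=0)
        try:
            if modes.k == 1:
                res = AutoReg(y[:, 0], lags=order, trend="n").fit()
                coefs = res.params.reshape(order, 1, 1)
                sigma = np.atleast_2d(res.sigma2)
            else:
                fit = VAR(y).fit(maxlags=order, trend="n")
                coefs, sigma = fit.coefs, fit.sigma_u
        except np.linalg.LinAlgError as err:  # pragma: no cover
            raise np.linalg.LinAlgError(
                f"VAR fit failed on epoch {ep}: ill-conditioned data ({err})"
            ) from err
        acc += _mar_spectrum(coefs, sigma, freqs, es.rate)
    S = acc / Y.shape[0]
    S = 0.5 * (S + np.swapaxes(S, 1, 2).conj())
    return CrossSpectra(freqs, S)


def count_data_points(band, df: float, n_modes: int = 8) -> int:
    """Number of real (equivalently complex) data points fitted per subject:
    n_modes^2 x n_frequencies on an inclusive grid."""
    f_lo, f_hi = band
    if f_hi < f_lo:
        raise ValueError("empty band")
    n_freq = int(round((f_hi - f_lo) / df)) + 1
    return n_modes**2 * n_freq


def band_power_summary(cs: CrossSpectra, band, mode_index: int = 0) -> float:
    """Mean |autospectrum| of one mode over a frequency band."""
    if not (0 <= mode_index < cs.n_modes):
        raise IndexError(f"mode index {mode_index} out of range")
    f_lo, f_hi = band
    sel = (cs.freqs >= f_lo) & (cs.freqs <= f_hi)
    if not sel.any():
        raise ValueError(f"band {band} not covered by frequency grid")
    return float(np.abs(cs.values[sel, mode_index, mode_index]).mean())


def alpha_power(channel_csd: CrossSpectra, channel_names,
                channels=("O1", "O2"), band=(8.0, 12.0)) -> float:
    """Occipital alpha covariate: mean 8-12 Hz autospectral power of O1/O2."""
    idx = [list(channel_names).index(c) for c in channels]
    sel = (channel_csd.freqs >= band[0]) & (channel_csd.freqs <= band[1])
    return float(
        np.mean([np.abs(channel_csd.values[sel, i, i]).mean() for i in idx])
    )


def group_band_anova(summaries, groups) -> dict:
    """One-way ANOVA over per-subject band-power summaries plus post hoc
    pairwise Welch t-tests with Bonferroni correction.

    Returns ``{"F", "p", "pairwise"}`` where pairwise maps (group_a,
    group_b) to the corrected p-value.
    """
    s = pd.Series(np.asarray(summaries, dtype=float),
                  index=pd.Index(groups, name="group"))
    labels = list(dict.fromkeys(groups))
    if len(labels) < 2 or any((s.index == g).sum() < 2 for g in labels):
        raise ValueError("need >= 2 groups with >= 2 subjects each")
    arrays = [s[s.index == g].to_numpy() for g in labels]
    F, p = sp_stats.f_oneway(*arrays)
    if all(np.ptp(a) == 0 for a in arrays) and np.ptp(s.to_numpy()) == 0:
        F, p = 0.0, 1.0
    pairs = {}
    n_comp = len(labels) * (len(labels) - 1) // 2
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            t, pp = sp_stats.ttest_ind(arrays[i], arrays[j], equal_var=False)
            pairs[(labels[i], labels[j])] = float(min(1.0, pp * n_comp))
    return {"F": float(F), "p": float(p), "pairwise": pairs}
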