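"""Quantitative EEG measures: z-scored band power, dominant frequency,
permutation entropy, and mean amplitude.

The spectrum is an average of per-epoch, per-channel Hann-tapered
periodograms (µV²/Hz), restricted to the 1–30 Hz analysis band and then
z-scored across frequency bins; z-scoring makes the dominant-frequency
peak and the band summaries invariant to overall signal scale. Band
means use the clinical partition delta 1–3, theta 4–7, alpha 8–13,
beta 14–30 Hz; a bin falling on a shared band boundary is assigned to
the lower band.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.signal

from .core import ConfigurationError, EmptyDataError, EpochedEEG

#: Band partition boundaries (upper inclusive edge of delta/theta/alpha),
#: placed midway between the printed integer band edges.
_BAND_SPLITS = {"delta": (1.0, 3.5), "theta": (3.5, 7.5),
                "alpha": (7.5, 13.5), "beta": (13.5, 30.0)}
BAND_NAMES = tuple(_BAND_SPLITS)


@dataclass
class Spectrum:
    """Cohort-convention power spectrum averaged over epochs and electrodes."""

    freqs_hz: np.ndarray
    power: np.ndarray  # µV²/Hz
    z_power: np.ndarray

    def __post_init__(self) -> None:
        if len(self.freqs_hz) != len(self.power):
            raise ConfigurationError("freqs and power length mismatch")


@dataclass
class QeegFeatures:
    dominant_freq_hz: float
    z_psd_delta: float
    z_psd_theta: float
    z_psd_alpha: float
    z_psd_beta: float
    peen_mean: float
    peen_per_electrode: np.ndarray
    amp_mean_uv: float


def compute_spectrum(ep: EpochedEEG, band: tuple[float, float] = (1.0, 30.0)
                     ) -> Spectrum:
    """Hann-tapered periodogram per epoch/channel, averaged, band-restricted."""
    if ep.n_kept < 1:
        raise EmptyDataError("no kept epochs")
    data = ep.data[ep.kept_mask]
    freqs, pxx = scipy.signal.periodogram(
        data, fs=ep.sfreq, window="hann", detrend=False,
        scaling="density", axis=-1,
    )
    power = pxx.mean(axis=(0, 1))  # over epochs then channels
    keep = (freqs >= band[0]) & (freqs <= band[1])
    freqs, power = freqs[keep], power[keep]
    sd = power.std()
    if sd == 0:
        raise EmptyDataError("degenerate spectrum (zero variance)")
    z = (power - power.mean()) / sd
    return Spectrum(freqs_hz=freqs, power=power, z_power=z)


def dominant_frequency(spectrum: Spectrum) -> float:
    """Frequency of the global maximum of the z-scored spectrum.

    Ties break toward the lower frequency (argmax on an increasing grid).
    """
    return float(spectrum.freqs_hz[int(np.argmax(spectrum.z_power))])


def band_z_power(spectrum: Spectrum) -> dict[str, float]:
    """Mean z-scored power per clinical band; every bin joins exactly one band."""
    out = {}
    for name, (lo, hi) in _BAND_SPLITS.items():
        if name == "delta":
            mask = (spectrum.freqs_hz >= lo) & (spectrum.freqs_hz <= hi)
        else:
            mask = (spectrum.freqs_hz > lo) & (spectrum.freqs_hz <= hi)
        out[name] = float(spectrum.z_power[mask].mean()) if mask.any() else float("nan")
    return out


def _pattern_codes(data: np.ndarray, order: int, delay: int) -> np.ndarray:
    """Ordinal pattern code of every window along the last axis.

    Ties between equal samples break by order of occurrence (stable sort).
    Output shape = data.shape[:-1] + (n_windows,), values in [0, order!).
    """
    n = data.shape[-1]
    n_win = n - (order - 1) * delay
    if n_win < 1:
        raise ConfigurationError("epoch too short for the requested order/delay")
    idx = np.arange(n_win)[:, None] + delay * np.arange(order)[None, :]
    windows = data[..., idx]  # (..., n_win, order)
    ranks = np.argsort(np.argsort(windows, axis=-1, kind="stable"),
                       axis=-1, kind="stable")
    # base-`order` positional code: injective over rank vectors
    weights = order ** np.arange(order)
    return (ranks * weights).sum(axis=-1)


def permutation_entropy(ep: EpochedEEG, order: int = 3, delay: int = 1
                        ) -> tuple[np.ndarray, float]:
    """Normalized permutation entropy per electrode and its channel mean.

    Ordinal patterns of length ``order`` (lag ``delay``) are pooled over
    all kept epochs per channel; the Shannon entropy of the pattern
    distribution is normalized by log(order!) so values lie in [0, 1].
    """
    if order < 2:
        raise ConfigurationError("order must be >= 2")
    if delay < 1:
        raise ConfigurationError("delay must be >= 1")
    if ep.n_kept < 1:
        raise EmptyDataError("no kept epochs")
    data = ep.data[ep.kept_mask]  # (k, ch, t)
    codes = _pattern_codes(data, order, delay)  # (k, ch, w)
    n_codes = order**order  # code space; only order! patterns can occur
    n_ch = data.shape[1]
    offsets = (np.arange(n_ch) * n_codes)[None, :, None]
    counts = np.bincount((codes + offsets).ravel(),
                         minlength=n_ch * n_codes).reshape(n_ch, n_codes)
    p = counts / counts.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    h = -plogp.sum(axis=1) / np.log(math.factorial(order))
    return h, float(h.mean())


def mean_amplitude(ep: EpochedEEG) -> float:
    """Mean absolute amplitude (µV) over kept epochs, channels, samples.

    The rectified mean is used because the detrended signal's plain mean
    is ~0 by construction; the absolute value keeps the statistic
    scale-informative.
    """
    if ep.n_kept < 1:
        raise EmptyDataError("no kept epochs")
    return float(np.abs(ep.data[ep.kept_mask]).mean())


def qeeg_features(ep: EpochedEEG, peen_order: int = 3, peen_delay: int = 1
                  ) -> QeegFeatures:
    """All four qEEG measures from one subject's clean 1-s epochs."""
    spectrum = compute_spectrum(ep)
    bands = band_z_power(spectrum)
    peen_el, peen_m = permutation_entropy(ep, order=peen_order, delay=peen_delay)
    return QeegFeatures(
        dominant_freq_hz=dominant_frequency(spectrum),
        z_psd_delta=bands["delta"],
        z_psd_theta=bands["theta"],
        z_psd_alpha=bands["alpha"],
        z_psd_beta=bands["beta"],
        peen_mean=peen_m,
        peen_per_electrode=peen_el,
        amp_mean_uv=mean_amplitude(ep),
    )
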