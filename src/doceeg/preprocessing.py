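"""Raw-recording conditioning: resample, bandpass, epoch, reject, detrend.

The cleaning chain mirrors standard clinical resting-state practice:
resample to 500 Hz, zero-phase 1–30 Hz bandpass, cut into 1-s epochs,
reject artefact epochs in two passes (absolute peak-to-peak amplitude,
then iterative 3-SD outlier screening), and remove per-epoch linear
trends. Zero-phase filtering is used deliberately: phase distortion would
bias the phase-lag connectivity computed downstream.
"""
from __future__ import annotations

from fractions import Fraction

import numpy as np
import scipy.signal

from .core import ConfigurationError, EEGRecording, EmptyDataError, EpochedEEG

DEFAULT_BAND = (1.0, 30.0)
#: Default absolute peak-to-peak rejection threshold, µV.
DEFAULT_ABS_THRESHOLD_UV = 500.0


def standardize(
    rec: EEGRecording,
    target_rate_hz: float = 500.0,
    band: tuple[float, float] = DEFAULT_BAND,
    filter_order: int = 6,
) -> EEGRecording:
    """Resample to ``target_rate_hz`` and zero-phase bandpass to ``band``.

    Resampling is polyphase (anti-aliased) and supports non-integer
    ratios such as 1024 -> 500 Hz. The bandpass is a forward–backward
    Butterworth filter, so stop-band attenuation is at least twice the
    single-pass design and the passband stays phase-neutral.
    """
    lo, hi = band
    if not 0 < lo < hi:
        raise ConfigurationError("band edges must satisfy 0 < low < high")
    if hi >= target_rate_hz / 2:
        raise ConfigurationError("band upper edge must be below Nyquist")
    if target_rate_hz > rec.sfreq + 1e-9:
        raise ConfigurationError("upsampling above the original rate is not supported")

    data = rec.data
    if abs(target_rate_hz - rec.sfreq) > 1e-9:
        ratio = Fraction(target_rate_hz / rec.sfreq).limit_denominator(1000)
        data = scipy.signal.resample_poly(data, ratio.numerator,
                                          ratio.denominator, axis=-1)
    sos = scipy.signal.butter(filter_order, [lo, hi], btype="bandpass",
                              fs=target_rate_hz, output="sos")
    data = scipy.signal.sosfiltfilt(sos, data, axis=-1)
    return EEGRecording(data=data, sfreq=target_rate_hz,
                        ch_names=rec.ch_names, subject_id=rec.subject_id)


def epoch(rec: EEGRecording, epoch_length_s: float = 1.0) -> EpochedEEG:
    """Cut into non-overlapping epochs; a trailing partial segment is dropped."""
    if epoch_length_s <= 0:
        raise ConfigurationError("epoch length must be positive")
    samples = int(round(epoch_length_s * rec.sfreq))
    n_epochs = rec.n_samples // samples
    if n_epochs < 1:
        raise ConfigurationError("epoch longer than the recording")
    cut = rec.data[:, : n_epochs * samples]
    data = cut.reshape(rec.data.shape[0], n_epochs, samples).transpose(1, 0, 2)
    return EpochedEEG(data=data.copy(), epoch_length_s=epoch_length_s,
                      sfreq=rec.sfreq, ch_names=rec.ch_names,
                      subject_id=rec.subject_id)


def reject_artifacts(
    ep: EpochedEEG,
    abs_threshold_uv: float = DEFAULT_ABS_THRESHOLD_UV,
    sd_multiplier: float = 3.0,
    max_iter: int = 8,
) -> EpochedEEG:
    """Two-pass automatic artefact rejection.

    Pass 1 drops epochs whose peak-to-peak amplitude on any channel exceeds
    ``abs_threshold_uv``. Pass 2 screens the per-epoch amplitude statistic:
    for each channel, the epoch's largest absolute deviation from the
    channel mean is compared against the distribution of that statistic
    over the epochs still retained, and epochs lying more than
    ``sd_multiplier`` standard deviations above its mean on any channel are
    dropped; the sweep repeats until stable (or ``max_iter`` sweeps). The
    epoch-level statistic is what makes a 3-SD criterion selective: raw
    samples of bandlimited noise exceed 3 SD in essentially every 1-s
    epoch, whereas the epoch peak statistic is tightly concentrated unless
    an artefact is present. Kept epochs are returned unchanged in value.
    """
    if ep.n_kept < 2:
        raise ConfigurationError("need at least 2 epochs for rejection")
    kept = ep.kept_mask.copy()
    log = list(ep.rejection_log)

    ptp = ep.data.max(axis=-1) - ep.data.min(axis=-1)  # (epochs, channels)
    bad_abs = (ptp > abs_threshold_uv).any(axis=-1) & kept
    for i in np.nonzero(bad_abs)[0]:
        log.append((int(i), "amplitude"))
    kept &= ~bad_abs
    if not kept.any():
        raise EmptyDataError("all epochs rejected (amplitude pass)")

    for _ in range(max_iter):
        sub = ep.data[kept]  # (k, ch, t)
        mean = sub.mean(axis=(0, 2))
        # per-epoch, per-channel peak absolute deviation from the channel mean
        peak = np.abs(ep.data - mean[None, :, None]).max(axis=-1)
        ref_mean = peak[kept].mean(axis=0)
        ref_sd = peak[kept].std(axis=0)
        # zero-variance statistics cannot flag anything (constant data guard)
        ref_sd = np.where(ref_sd > 0, ref_sd, np.inf)
        bad = ((peak > ref_mean + sd_multiplier * ref_sd).any(axis=1)) & kept
        if not bad.any():
            break
        for i in np.nonzero(bad)[0]:
            log.append((int(i), "deviation"))
        kept &= ~bad
        if not kept.any():
            raise EmptyDataError("all epochs rejected (deviation pass)")

    return EpochedEEG(data=ep.data, epoch_length_s=ep.epoch_length_s,
                      sfreq=ep.sfreq, ch_names=ep.ch_names, kept_mask=kept,
                      rejection_log=log, subject_id=ep.subject_id)


def detrend(ep: EpochedEEG) -> EpochedEEG:
    """Remove the least-squares line from every epoch and channel."""
    data = scipy.signal.detrend(ep.data, axis=-1, type="linear")
    return EpochedEEG(data=data, epoch_length_s=ep.epoch_length_s,
                      sfreq=ep.sfreq, ch_names=ep.ch_names,
                      kept_mask=ep.kept_mask.copy(),
                      rejection_log=list(ep.rejection_log),
                      subject_id=ep.subject_id)


def preprocess(
    rec: EEGRecording,
    target_rate_hz: float = 500.0,
    band: tuple[float, float] = DEFAULT_BAND,
    epoch_length_s: float = 1.0,
    abs_threshold_uv: float = DEFAULT_ABS_THRESHOLD_UV,
    sd_multiplier: float = 3.0,
) -> EpochedEEG:
    """Full conditioning chain: standardize -> epoch -> reject -> detrend."""
    clean = standardize(rec, target_rate_hz=target_rate_hz, band=band)
    ep = epoch(clean, epoch_length_s=epoch_length_s)
    ep = reject_artifacts(ep, abs_threshold_uv=abs_threshold_uv,
                          sd_multiplier=sd_multiplier)
    return detrend(ep)


def rejection_report(ep: EpochedEEG) -> dict:
    """JSON-serializable audit of the rejection outcome."""
    return {
        "subject_id": ep.subject_id,
        "n_epochs": int(ep.n_epochs),
        "n_kept": int(ep.n_kept),
        "rejected": [{"epoch": i, "reason": r} for i, r in ep.rejection_log],
    }
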