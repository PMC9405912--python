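"""Pairwise functional-connectivity estimators on Laplacian-referenced EEG.

Three estimators produce 19x19 symmetric matrices (diagonal fixed at 0):

* **wPLI** — weighted phase lag index at the subject's dominant frequency,
  from complex Morlet time–frequency data on 2-s epochs:
  ``|E[Im Sxy]| / E[|Im Sxy|]`` pooled over epochs and retained (non-edge)
  samples. Zero-lag (volume-conducted) coupling has Im Sxy = 0 and is
  discounted. An optional per-subject surrogate threshold zeroes pairs that
  do not exceed the null built from circular time-shifts.
* **PCoh** — magnitude-squared coherence from epoch-averaged cross- and
  auto-spectra (Hann taper, zero-padding for finer frequency resolution),
  either averaged over the full 1–30 Hz band or read at the dominant
  frequency. The surface Laplacian applied beforehand supplies the
  "partial" removal of shared neighboring activity.
* **MI** — histogram mutual information of the amplitude distributions,
  equal-width bins per channel over its observed range, in bits.

ROI summaries average each matrix over five electrode-pair regions
(left/right frontoparietal, frontal/central/posterior interhemispheric)
and report the mean of the five ROI values as the global index.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import CHANNELS_1020, ConfigurationError, EmptyDataError, EpochedEEG
from .montage import ADJACENCY, ROI_NAMES, roi_pairs, validate_adjacency


@dataclass
class ConnectivityMatrix:
    """Symmetric 19x19 estimator output with its frequency context."""

    values: np.ndarray
    estimator: str  # "wPLI" | "PCoh" | "MI"
    freq_context: str  # "dominant_frequency" | "full_band"
    freq_hz: float | None = None
    thresholded: bool = False
    ch_names: tuple[str, ...] = CHANNELS_1020

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ConfigurationError("connectivity matrix must be square")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ConfigurationError("connectivity matrix must be symmetric")
        self.values = v


@dataclass
class RoiSummary:
    left_frontoparietal: float
    right_frontoparietal: float
    frontal_inter: float
    central_inter: float
    posterior_inter: float
    global_mean: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in
                (*ROI_NAMES, "global_mean")}


# ---------------------------------------------------------------------------
# spatial referencing
# ---------------------------------------------------------------------------

def laplacian_filter(ep: EpochedEEG,
                     adjacency: dict[str, tuple[str, ...]] | None = None
                     ) -> EpochedEEG:
    """Subtract from each channel the mean of its montage neighbors."""
    if adjacency is None:
        adjacency = ADJACENCY
        validate_adjacency(adjacency)
    n_ch = ep.n_channels
    index = {c: i for i, c in enumerate(ep.ch_names)}
    mat = np.eye(n_ch)
    for ch in ep.ch_names:
        nbrs = adjacency.get(ch)
        if not nbrs:
            raise ConfigurationError(f"channel {ch} missing from adjacency")
        for n in nbrs:
            mat[index[ch], index[n]] -= 1.0 / len(nbrs)
    data = np.einsum("ij,ejt->eit", mat, ep.data)
    return EpochedEEG(data=data, epoch_length_s=ep.epoch_length_s,
                      sfreq=ep.sfreq, ch_names=ep.ch_names,
                      kept_mask=ep.kept_mask.copy(),
                      rejection_log=list(ep.rejection_log),
                      subject_id=ep.subject_id)


# ---------------------------------------------------------------------------
# Morlet time-frequency and wPLI
# ---------------------------------------------------------------------------

@dataclass
class MorletTF:
    """Complex time–frequency data at one frequency.

    data : (epochs, channels, samples); ``valid`` masks samples beyond the
    wavelet's half-length at each edge (excluded from downstream pooling).
    """

    data: np.ndarray
    valid: np.ndarray
    freq_hz: float
    sfreq: float


def morlet_tf(ep2s: EpochedEEG, freq_hz: float, n_cycles: int = 6,
              truncate_sd: float = 2.5) -> MorletTF:
    """Convolve each 2-s epoch with a complex Morlet wavelet at ``freq_hz``.

    Convolution is done by frequency-domain multiplication. The Gaussian
    envelope is truncated at ``truncate_sd`` standard deviations; samples
    within half a wavelet of either epoch edge are flagged invalid.
    """
    if not 1.0 <= freq_hz <= 30.0:
        raise ConfigurationError("frequency must lie in [1, 30] Hz")
    if ep2s.n_kept < 1:
        raise EmptyDataError("no kept epochs")
    sfreq = ep2s.sfreq
    n_samples = ep2s.data.shape[2]
    sigma_t = n_cycles / (2.0 * np.pi * freq_hz)
    half = int(np.ceil(truncate_sd * sigma_t * sfreq))
    if 2 * half + 1 > n_samples:
        raise ConfigurationError(
            f"wavelet ({2 * half + 1} samples) longer than the epoch "
            f"({n_samples} samples)"
        )
    t = np.arange(-half, half + 1) / sfreq
    wavelet = np.exp(2j * np.pi * freq_hz * t) * np.exp(-(t**2) / (2 * sigma_t**2))
    wavelet /= np.abs(wavelet).sum() / 2.0  # unit gain for an on-frequency sinusoid

    data = ep2s.data[ep2s.kept_mask]
    n_fft = int(2 ** np.ceil(np.log2(n_samples + len(wavelet) - 1)))
    spec = np.fft.fft(data, n_fft, axis=-1) * np.fft.fft(wavelet, n_fft)
    conv = np.fft.ifft(spec, axis=-1)[..., half: half + n_samples]
    valid = np.zeros(n_samples, dtype=bool)
    valid[half: n_samples - half] = True
    return MorletTF(data=conv, valid=valid, freq_hz=freq_hz, sfreq=sfreq)


def _wpli_from_tf(x: np.ndarray) -> np.ndarray:
    """wPLI matrix from complex TF data (epochs, channels, samples)."""
    n_ch = x.shape[1]
    xc = np.conj(x)
    w = np.zeros((n_ch, n_ch))
    for a in range(n_ch):
        # Im Sxy for all partners of channel a at once: (epochs, pairs, t)
        s = x[:, a, None, :] * xc[:, a + 1:, :]
        im = s.imag
        num = np.abs(im.mean(axis=(0, 2)))
        den = np.abs(im).mean(axis=(0, 2))
        # zero-lag guard: Im S that is zero up to round-off (identical or
        # purely instantaneously coupled signals) must yield wPLI = 0
        floor = 1e-12 * np.abs(s).mean(axis=(0, 2))
        ok = den > floor
        vals = np.where(ok, num / np.where(ok, den, 1.0), 0.0)
        w[a, a + 1:] = vals
        w[a + 1:, a] = vals
    return w


def wpli_matrix(tf: MorletTF, min_epochs: int = 10) -> ConnectivityMatrix:
    """Weighted phase lag index pooled over epochs and retained samples."""
    x = tf.data[:, :, tf.valid]
    if x.shape[0] < min_epochs:
        raise ConfigurationError(f"need >= {min_epochs} epochs of TF data")
    if x.shape[1] < 2:
        raise ConfigurationError("need at least 2 channels")
    w = _wpli_from_tf(x)
    return ConnectivityMatrix(values=w, estimator="wPLI",
                              freq_context="dominant_frequency",
                              freq_hz=tf.freq_hz,
                              ch_names=CHANNELS_1020 if len(w) == 19 else
                              tuple(f"ch{i}" for i in range(len(w))))


def wpli_threshold(
    ep2s: EpochedEEG,
    freq_hz: float,
    n_surrogates: int = 200,
    alpha: float = 0.05,
    seed: int | None = 0,
    n_cycles: int = 6,
) -> ConnectivityMatrix:
    """Per-subject surrogate-thresholded wPLI matrix.

    The null is built by independently circular-shifting each channel's
    time–frequency series within every epoch (spectra preserved,
    cross-channel phase relations destroyed) and recomputing the wPLI;
    observed pair values at or below the null's (1 - alpha) quantile are
    set to zero.
    """
    if n_surrogates < 20:
        raise ConfigurationError("need at least 20 surrogates")
    if not 0 < alpha < 1:
        raise ConfigurationError("alpha must lie in (0, 1)")
    tf = morlet_tf(ep2s, freq_hz, n_cycles=n_cycles)
    observed = wpli_matrix(tf)
    x = tf.data[:, :, tf.valid]
    n_ep, n_ch, n_t = x.shape
    rng = np.random.default_rng(seed)

    null = np.empty((n_surrogates, n_ch, n_ch))
    cols = np.arange(n_t)
    for s in range(n_surrogates):
        shifts = rng.integers(0, n_t, size=(n_ep, n_ch))
        xs = x[np.arange(n_ep)[:, None, None],
               np.arange(n_ch)[None, :, None],
               (cols[None, None, :] + shifts[:, :, None]) % n_t]
        null[s] = _wpli_from_tf(xs)

    cutoff = np.quantile(null, 1.0 - alpha, axis=0)
    values = np.where(observed.values > cutoff, observed.values, 0.0)
    np.fill_diagonal(values, 0.0)
    return ConnectivityMatrix(values=values, estimator="wPLI",
                              freq_context="dominant_frequency",
                              freq_hz=freq_hz, thresholded=True,
                              ch_names=observed.ch_names)


# ---------------------------------------------------------------------------
# coherence
# ---------------------------------------------------------------------------

def coherence_matrix(
    ep: EpochedEEG,
    mode: str = "full_band",
    freq_hz: float | None = None,
    pad_ratio: int = 8,
    band: tuple[float, float] = (1.0, 30.0),
) -> ConnectivityMatrix:
    """Magnitude-squared coherence from epoch-averaged spectra.

    ``full_band`` averages the per-bin coherence over the analysis band;
    ``at_frequency`` reads the bin nearest ``freq_hz`` (zero-padding by
    ``pad_ratio`` refines the bin grid).
    """
    if mode not in ("full_band", "at_frequency"):
        raise ConfigurationError(f"unknown coherence mode {mode!r}")
    if mode == "at_frequency" and freq_hz is None:
        raise ConfigurationError("at_frequency mode requires freq_hz")
    if pad_ratio < 1:
        raise ConfigurationError("pad_ratio must be >= 1")
    if ep.n_kept < 2:
        raise ConfigurationError("need at least 2 epochs for coherence")
    data = ep.data[ep.kept_mask]
    n_ep, n_ch, n_t = data.shape
    window = np.hanning(n_t)
    n_fft = int(pad_ratio * n_t)
    spec = np.fft.rfft(data * window, n_fft, axis=-1)
    freqs = np.fft.rfftfreq(n_fft, d=1.0 / ep.sfreq)
    keep = (freqs >= band[0]) & (freqs <= band[1])
    spec = spec[:, :, keep]
    freqs = freqs[keep]

    sxy = np.einsum("ecf,edf->cdf", spec, np.conj(spec)) / n_ep
    auto = np.real(np.einsum("ecf,ecf->cf", spec, np.conj(spec))) / n_ep
    denom = auto[:, None, :] * auto[None, :, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        coh = np.abs(sxy) ** 2 / np.where(denom > 0, denom, np.inf)
    coh = np.clip(np.real(coh), 0.0, 1.0)

    if mode == "full_band":
        values = coh.mean(axis=-1)
        ctx, fval = "full_band", None
    else:
        j = int(np.argmin(np.abs(freqs - freq_hz)))
        values = coh[:, :, j]
        ctx, fval = "dominant_frequency", float(freqs[j])
    values = (values + values.T) / 2.0
    np.fill_diagonal(values, 0.0)
    return ConnectivityMatrix(values=values, estimator="PCoh",
                              freq_context=ctx, freq_hz=fval,
                              ch_names=CHANNELS_1020 if n_ch == 19 else
                              tuple(f"ch{i}" for i in range(n_ch)))


# ---------------------------------------------------------------------------
# mutual information
# ---------------------------------------------------------------------------

def _entropy_bits(counts: np.ndarray) -> float:
    p = counts[counts > 0].astype(float)
    p /= p.sum()
    return float(-(p * np.log2(p)).sum())


def freedman_diaconis_bins(x: np.ndarray) -> int:
    """Freedman–Diaconis bin count for one channel's amplitude distribution."""
    q75, q25 = np.percentile(x, [75, 25])
    iqr = q75 - q25
    if iqr <= 0:
        return 1
    width = 2.0 * iqr / len(x) ** (1.0 / 3.0)
    return max(1, int(np.ceil((x.max() - x.min()) / width)))


def mutual_information_matrix(
    ep: EpochedEEG,
    n_bins: int | str = 10,
    min_samples: int = 1000,
) -> ConnectivityMatrix:
    """Histogram mutual information (bits) between all channel pairs.

    Kept epochs are concatenated per channel; each channel is binned into
    ``n_bins`` equal-width bins over its observed range (``n_bins="fd"``
    derives the count from the Freedman–Diaconis rule, median over
    channels). MI = H(X) + H(Y) - H(X, Y).
    """
    x = ep.concatenated()
    n_ch, n = x.shape
    if n < min_samples:
        raise ConfigurationError(
            f"need >= {min_samples} samples per channel, got {n}"
        )
    if n_bins == "fd":
        n_bins = int(np.median([freedman_diaconis_bins(x[c]) for c in range(n_ch)]))
    if not isinstance(n_bins, (int, np.integer)) or n_bins < 2:
        raise ConfigurationError("n_bins must be an integer >= 2 or 'fd'")

    lo = x.min(axis=1)
    rng_width = x.max(axis=1) - lo
    constant = rng_width <= 0
    if constant.any():
        warnings.warn("constant channel(s); their MI is defined as 0",
                      RuntimeWarning, stacklevel=2)
        rng_width = np.where(constant, 1.0, rng_width)
    idx = np.floor((x - lo[:, None]) / rng_width[:, None] * n_bins).astype(int)
    idx = np.clip(idx, 0, n_bins - 1)

    h = np.array([_entropy_bits(np.bincount(idx[c], minlength=n_bins))
                  for c in range(n_ch)])
    values = np.zeros((n_ch, n_ch))
    for a in range(n_ch):
        for b in range(a + 1, n_ch):
            if constant[a] or constant[b]:
                continue
            joint = np.bincount(idx[a] * n_bins + idx[b],
                                minlength=n_bins * n_bins)
            mi = h[a] + h[b] - _entropy_bits(joint)
            values[a, b] = values[b, a] = max(mi, 0.0)
    return ConnectivityMatrix(values=values, estimator="MI",
                              freq_context="full_band",
                              ch_names=CHANNELS_1020 if n_ch == 19 else
                              tuple(f"ch{i}" for i in range(n_ch)))


def self_information_bits(ep: EpochedEEG, n_bins: int = 10) -> np.ndarray:
    """Per-channel marginal entropies H(X) in bits (the MI diagonal analogue)."""
    x = ep.concatenated()
    out = []
    for c in range(x.shape[0]):
        lo, hi = x[c].min(), x[c].max()
        if hi <= lo:
            out.append(0.0)
            continue
        idx = np.clip(np.floor((x[c] - lo) / (hi - lo) * n_bins).astype(int),
                      0, n_bins - 1)
        out.append(_entropy_bits(np.bincount(idx, minlength=n_bins)))
    return np.array(out)


# ---------------------------------------------------------------------------
# ROI summaries
# ---------------------------------------------------------------------------

def roi_summarize(m: ConnectivityMatrix,
                  roi_definition: dict | None = None) -> RoiSummary:
    """Average a connectivity matrix over each ROI's electrode pairs."""
    pairs_by_roi = roi_pairs(roi_definition)
    index = {c: i for i, c in enumerate(m.ch_names)}
    values = {}
    for roi, pairs in pairs_by_roi.items():
        vals = [m.values[index[a], index[b]] for a, b in pairs]
        values[roi] = float(np.mean(vals))
    return RoiSummary(**values, global_mean=float(np.mean(list(values.values()))))
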