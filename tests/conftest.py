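import numpy as np
import pytest

from doceeg.core import CHANNELS_1020, EEGRecording, EpochedEEG


def make_epochs(data: np.ndarray, sfreq: float = 250.0,
                ch_names=None) -> EpochedEEG:
    """Wrap an (epochs, channels, samples) array for estimator tests."""
    n_ch = data.shape[1]
    if ch_names is None:
        ch_names = (CHANNELS_1020 if n_ch == 19
                    else tuple(f"ch{i}" for i in range(n_ch)))
    return EpochedEEG(data=data, epoch_length_s=data.shape[2] / sfreq,
                      sfreq=sfreq, ch_names=ch_names)


def make_recording(data: np.ndarray, sfreq: float = 500.0,
                   subject_id: str = "test") -> EEGRecording:
    return EEGRecording(data=data, sfreq=sfreq, ch_names=CHANNELS_1020,
                        subject_id=subject_id)


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def small_tf_fixture(rng):
    """4-channel, 20-epoch bandlimited data for oracle-equivalence tests."""
    n_ep, n_ch, n_t = 20, 4, 250
    white = rng.standard_normal((n_ep, n_ch, n_t * 3))
    # crude band-limit by FFT masking so values are smooth but generic
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(white.shape[-1], d=1.0 / 250.0)
    spec[..., (freqs < 1) | (freqs > 30)] = 0
    smooth = np.fft.irfft(spec, n=white.shape[-1], axis=-1)[..., n_t:2 * n_t]
    return make_epochs(smooth.copy(), sfreq=250.0)
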