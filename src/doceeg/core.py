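"""Shared containers and error types for the EEG biomarker pipeline.

All signal amplitudes are in microvolts (µV) throughout the package.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: The 19 scalp electrodes of the international 10–20 montage, in the
#: canonical anterior-to-posterior, left-to-right order used everywhere
#: in this package.
CHANNELS_1020: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "Cz", "C4", "T4",
    "T5", "P3", "Pz", "P4", "T6", "O1", "O2",
)

_CANON = {name.lower(): name for name in CHANNELS_1020}


class ConfigurationError(ValueError):
    """Invalid parameterization of an operation (bad band edges, bin counts, ...)."""


class EmptyDataError(RuntimeError):
    """No data left to analyze (e.g. every epoch rejected)."""


def canonical_channel_name(name: str) -> str:
    """Map a channel label onto the 10–20 set, case-insensitively.

    Raises ``ConfigurationError`` for labels outside the montage.
    """
    key = name.strip().lower()
    # common clinical aliases for the temporal row
    aliases = {"t7": "t3", "t8": "t4", "p7": "t5", "p8": "t6"}
    key = aliases.get(key, key)
    if key not in _CANON:
        raise ConfigurationError(f"channel {name!r} is not a 10-20 montage label")
    return _CANON[key]


@dataclass
class EEGRecording:
    """Continuous multichannel EEG.

    data : (n_channels, n_samples) array in µV
    """

    data: np.ndarray
    sfreq: float
    ch_names: tuple[str, ...] = CHANNELS_1020
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ConfigurationError("recording data must be 2-D (channels x samples)")
        if self.sfreq <= 0:
            raise ConfigurationError("sampling rate must be positive")
        self.ch_names = tuple(canonical_channel_name(c) for c in self.ch_names)
        if len(self.ch_names) != len(set(self.ch_names)):
            raise ConfigurationError("duplicate channel labels")
        if self.data.shape[0] != 19 or len(self.ch_names) != 19:
            raise ConfigurationError(
                f"expected 19 channels, got {self.data.shape[0]}"
            )

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sfreq


@dataclass
class EpochedEEG:
    """Fixed-length, non-overlapping epochs cut from one recording.

    data : (n_epochs, n_channels, n_samples_per_epoch) array in µV.
    kept_mask refers to the epoch grid at epoching time; rejection updates it
    in place of dropping information, and rejection_log records (index, reason).
    """

    data: np.ndarray
    epoch_length_s: float
    sfreq: float
    ch_names: tuple[str, ...] = CHANNELS_1020
    kept_mask: np.ndarray | None = None
    rejection_log: list[tuple[int, str]] = field(default_factory=list)
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ConfigurationError("epoched data must be 3-D")
        expected = int(round(self.epoch_length_s * self.sfreq))
        if self.data.shape[2] != expected:
            raise ConfigurationError(
                f"samples per epoch {self.data.shape[2]} != "
                f"round(epoch_length_s * sfreq) = {expected}"
            )
        if self.kept_mask is None:
            self.kept_mask = np.ones(self.data.shape[0], dtype=bool)
        self.kept_mask = np.asarray(self.kept_mask, dtype=bool)

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_kept(self) -> int:
        return int(self.kept_mask.sum())

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    def concatenated(self) -> np.ndarray:
        """Kept epochs joined back into a (n_channels, n) array."""
        if self.n_kept == 0:
            raise EmptyDataError("no kept epochs")
        kept = self.data[self.kept_mask]
        return kept.transpose(1, 0, 2).reshape(self.n_channels, -1)
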