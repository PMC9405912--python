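"""EDF input/output for 19-channel recordings.

Reading goes through :func:`mne.io.read_raw_edf`. Writing uses a minimal
EDF encoder (16-bit samples, 1-second data records) sufficient for the
synthetic cohorts this package generates; amplitudes are stored in µV with
per-channel physical scaling.
"""
from __future__ import annotations

import datetime as _dt
from pathlib import Path

import numpy as np

from .core import CHANNELS_1020, ConfigurationError, EEGRecording


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii", errors="replace")[:width]
    return b + b" " * (width - len(b))


def write_edf(rec: EEGRecording, path: str | Path) -> Path:
    """Write a recording to an EDF file (one 1-s data record per second).

    The sampling rate must be integer-valued; a trailing partial second is
    truncated.
    """
    path = Path(path)
    sfreq = rec.sfreq
    if abs(sfreq - round(sfreq)) > 1e-9:
        raise ConfigurationError("EDF writer requires an integer sampling rate")
    spr = int(round(sfreq))  # samples per 1-s record
    n_records = rec.n_samples // spr
    if n_records < 1:
        raise ConfigurationError("recording shorter than one data record")
    data = rec.data[:, : n_records * spr]
    n_ch = data.shape[0]

    phys_min = data.min(axis=1)
    phys_max = data.max(axis=1)
    flat = phys_max - phys_min < 1e-12
    phys_min = np.where(flat, phys_min - 1.0, phys_min)
    phys_max = np.where(flat, phys_max + 1.0, phys_max)
    dig_min, dig_max = -32768, 32767
    scale = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.round((data - phys_min[:, None]) * scale[:, None] + dig_min)
    digital = np.clip(digital, dig_min, dig_max).astype("<i2")

    now = _dt.datetime(2000, 1, 1)
    header = b"".join(
        [
            _pad("0", 8),
            _pad(rec.subject_id or "X", 80),
            _pad("Startdate 01-JAN-2000", 80),
            _pad(now.strftime("%d.%m.%y"), 8),
            _pad(now.strftime("%H.%M.%S"), 8),
            _pad(str(256 * (1 + n_ch)), 8),
            _pad("", 44),
            _pad(str(n_records), 8),
            _pad("1", 8),
            _pad(str(n_ch), 4),
        ]
    )

    def field(values: list[str], width: int) -> bytes:
        return b"".join(_pad(v, width) for v in values)

    labels = [f"EEG {c}" for c in rec.ch_names]
    sig_header = b"".join(
        [
            field(labels, 16),
            field(["AgAgCl electrode"] * n_ch, 80),
            field(["uV"] * n_ch, 8),
            field([f"{v:.8g}"[:8] for v in phys_min], 8),
            field([f"{v:.8g}"[:8] for v in phys_max], 8),
            field([str(dig_min)] * n_ch, 8),
            field([str(dig_max)] * n_ch, 8),
            field([""] * n_ch, 80),
            field([str(spr)] * n_ch, 8),
            field([""] * n_ch, 32),
        ]
    )

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig_header)
        # records: for each second, all channels sequentially
        chunks = digital.reshape(n_ch, n_records, spr).transpose(1, 0, 2)
        fh.write(np.ascontiguousarray(chunks).tobytes())
    return path


def read_edf(path: str | Path, subject_id: str | None = None) -> EEGRecording:
    """Load an EDF/EDF+ file and map channels onto the 10–20 label set.

    Channel-name matching is case-insensitive and tolerates an ``EEG ``
    prefix and reference suffixes (``-A1``, ``-REF``). Raises
    ``ConfigurationError`` if the 19 montage channels cannot be assembled.
    """
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    available: dict[str, int] = {}
    for idx, name in enumerate(raw.ch_names):
        clean = name.strip()
        if clean.upper().startswith("EEG "):
            clean = clean[4:]
        clean = clean.split("-")[0].strip().lower()
        aliases = {"t7": "t3", "t8": "t4", "p7": "t5", "p8": "t6"}
        clean = aliases.get(clean, clean)
        available.setdefault(clean, idx)
    try:
        order = [available[c.lower()] for c in CHANNELS_1020]
    except KeyError as err:
        raise ConfigurationError(f"EDF file lacks montage channel {err}") from None
    data_uv = raw.get_data()[order] * 1e6  # mne returns volts
    return EEGRecording(
        data=data_uv,
        sfreq=float(raw.info["sfreq"]),
        ch_names=CHANNELS_1020,
        subject_id=subject_id or Path(path).stem,
    )
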