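"""Synthetic resting-state EEG cohorts with controllable biomarker structure.

Each subject's 19-channel recording is built from:

* per-channel 1/f background noise (the aperiodic EEG floor),
* a narrowband oscillator at the subject's dominant frequency,
* lagged linear coupling between designated channel pairs — the receiving
  channel's oscillation is partially replaced by a quarter-cycle-delayed
  copy of the driver's, which drives phase-lag connectivity (wPLI) while
  leaving instantaneous correlation near zero,
* a shared broadband source mixed with heterogeneous gains into the
  posterior electrodes, driving amplitude coupling (mutual information)
  and spectral coherence at zero lag (so wPLI discounts it),
* occasional artefact epochs with square-pulse + drift excursions well
  above 5x the background standard deviation.

Cohort-level group effects mirror the clinical contrasts the analysis
screens for: traumatic-etiology subjects get a slower dominant frequency
and weaker pairwise coupling; improved-outcome subjects get a stronger
shared source (more coherence and mutual information).
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import CHANNELS_1020, ConfigurationError, EEGRecording

#: RMS of the 1/f background at noise_gain = 1, in µV.
BACKGROUND_RMS_UV = 10.0
#: Oscillator RMS relative to the background RMS (SNR = ratio**2 = 2.25).
OSC_RMS_RATIO = 1.5
#: Spectral half-width (Gaussian sigma, Hz) of the narrowband oscillator.
OSC_BANDWIDTH_HZ = 0.25

#: Driver -> receiver pairs carrying lagged phase coupling; one pair lands
#: in each connectivity ROI so pair-level coupling moves the global mean.
COUPLED_PAIRS: tuple[tuple[str, str], ...] = (
    ("F3", "P3"),
    ("F4", "P4"),
    ("Fp1", "Fp2"),
    ("C3", "C4"),
    ("T5", "T6"),
)

#: Channels receiving the shared broadband source. The mixing gains
#: alternate in sign across neighboring electrodes (a dipolar-like scalp
#: pattern), so the surface Laplacian — which subtracts neighbor means —
#: cannot cancel the source before the connectivity stage sees it.
SHARED_SOURCE_GAINS: dict[str, float] = {
    "P3": 1.5, "T5": -0.8, "O1": 1.2, "P4": -1.0, "T6": 0.9, "O2": -1.3,
}


@dataclass
class SubjectProfile:
    """Generative parameters for one subject's recording."""

    subject_id: str
    etiology: str  # "TBI" | "nonTBI"
    outcome: str  # "improved" | "nonimproved"
    age_years: float
    dominant_freq_hz: float
    coupling_strength: float
    shared_source_gain: float
    noise_gain: float = 1.0
    artefact_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1.0 <= self.dominant_freq_hz <= 30.0:
            raise ConfigurationError("dominant_freq_hz must lie in [1, 30]")
        if not 0.0 <= self.coupling_strength <= 1.0:
            raise ConfigurationError("coupling_strength must lie in [0, 1]")
        if self.shared_source_gain < 0:
            raise ConfigurationError("shared_source_gain must be >= 0")
        if self.noise_gain <= 0:
            raise ConfigurationError("noise_gain must be > 0")
        if not 0.0 <= self.artefact_rate <= 1.0:
            raise ConfigurationError("artefact_rate must lie in [0, 1]")
        if self.etiology not in ("TBI", "nonTBI"):
            raise ConfigurationError(f"unknown etiology {self.etiology!r}")
        if self.outcome not in ("improved", "nonimproved"):
            raise ConfigurationError(f"unknown outcome {self.outcome!r}")


@dataclass
class SubjectRecord:
    """Clinical row: etiology, age, GCS at admission, GOS at T0/T1."""

    subject_id: str
    etiology: str
    age_years: float
    gcs_baseline: int
    gos_t0: int
    gos_t1: int

    @property
    def outcome(self) -> str:
        """Improved iff the GOS gained at least one point between T0 and T1."""
        return "improved" if self.gos_t1 - self.gos_t0 >= 1 else "nonimproved"


@dataclass
class EffectSpec:
    """Group-level means and shifts of the injected generative parameters.

    Shifts are (non-TBI minus TBI) for etiology-linked parameters and
    (improved minus nonimproved) for outcome-linked ones; each group mean
    is base ± shift/2. The defaults are deliberately strong standardized
    effects (about 2 SD and larger on the injected parameter scale) so the
    screening contrasts are detectable at a 33-subject cohort.
    """

    dominant_freq_base_hz: float = 5.0
    dominant_freq_shift_hz: float = 2.0
    dominant_freq_sd_hz: float = 0.8
    coupling_base: float = 0.5
    coupling_shift: float = 0.5
    coupling_sd: float = 0.12
    shared_gain_base: float = 1.0
    shared_gain_shift: float = 1.2
    shared_gain_sd: float = 0.3

    @classmethod
    def null(cls) -> "EffectSpec":
        """All between-group shifts zero (type-I error studies)."""
        return cls(dominant_freq_shift_hz=0.0, coupling_shift=0.0,
                   shared_gain_shift=0.0)


@dataclass
class CohortConfig:
    """Cohort composition and recording parameters.

    The default composition has 15 traumatic and 18 nontraumatic subjects.
    The improved fraction defaults to one scalar applied to both etiology
    groups (0.4, i.e. 6/15 + 7/18 = 13/33 improved), which keeps the
    outcome contrast orthogonal to etiology; a per-group pair may be
    supplied instead to emulate a specific clinical composition.
    """

    n_tbi: int = 15
    n_nontbi: int = 18
    improved_fraction_per_group: float | tuple[float, float] = 0.4
    effects: EffectSpec = field(default_factory=EffectSpec)
    recording_length_s: float = 1200.0
    sampling_rate_hz: float = 500.0
    noise_gain: float = 1.0
    artefact_rate: float = 0.05
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tbi < 0 or self.n_nontbi < 0:
            raise ConfigurationError("group sizes must be non-negative")
        fr = self.improved_fraction_per_group
        fracs = (fr, fr) if np.isscalar(fr) else tuple(fr)
        if len(fracs) != 2 or any(not 0.0 <= f <= 1.0 for f in fracs):
            raise ConfigurationError(
                "improved_fraction_per_group must be in [0, 1] "
                "(scalar or one value per group)"
            )
        self._fracs = (float(fracs[0]), float(fracs[1]))
        if self.recording_length_s <= 0 or self.sampling_rate_hz <= 0:
            raise ConfigurationError("recording length and rate must be positive")

    @property
    def n_total(self) -> int:
        return self.n_tbi + self.n_nontbi


# ---------------------------------------------------------------------------
# single-subject signal synthesis
# ---------------------------------------------------------------------------

def _pink_noise(rng: np.random.Generator, n_ch: int, n: int) -> np.ndarray:
    """Unit-RMS 1/f noise per channel (power flat below 1 Hz)."""
    white = rng.standard_normal((n_ch, n))
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n, d=1.0)  # units cancel in the 1/f shape
    spec *= 1.0 / np.sqrt(np.maximum(freqs, freqs[1]))
    x = np.fft.irfft(spec, n=n, axis=-1)
    x /= x.std(axis=-1, keepdims=True)
    return x


def _narrowband(rng: np.random.Generator, n_ch: int, n: int, sfreq: float,
                f0: float, bw: float) -> np.ndarray:
    """Unit-RMS Gaussian narrowband processes centered on f0."""
    white = rng.standard_normal((n_ch, n))
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n, d=1.0 / sfreq)
    spec *= np.exp(-0.5 * ((freqs - f0) / bw) ** 2)
    x = np.fft.irfft(spec, n=n, axis=-1)
    x /= x.std(axis=-1, keepdims=True)
    return x


def _broadband(rng: np.random.Generator, n: int, sfreq: float,
               band: tuple[float, float] = (1.0, 30.0)) -> np.ndarray:
    """Unit-RMS broadband noise restricted to the analysis band."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / sfreq)
    spec[(freqs < band[0]) | (freqs > band[1])] = 0.0
    x = np.fft.irfft(spec, n=n)
    return x / x.std()


def generate_subject_eeg(
    profile: SubjectProfile,
    duration_s: float = 60.0,
    sfreq: float = 500.0,
    coupling_mode: str = "lagged",
) -> EEGRecording:
    """Synthesize one continuous 19-channel recording.

    coupling_mode="lagged" delays the driver's oscillation by a quarter
    cycle before mixing it into the receiver (drives wPLI);
    "zero_lag" mixes without delay (a volume-conduction control that wPLI
    should discount).
    """
    if sfreq <= 0:
        raise ConfigurationError("sampling rate must be positive")
    if coupling_mode not in ("lagged", "zero_lag"):
        raise ConfigurationError(f"unknown coupling_mode {coupling_mode!r}")
    n = int(round(duration_s * sfreq))
    if n < sfreq:
        raise ConfigurationError("recording must be at least 1 s long")
    rng = np.random.default_rng(profile.seed)
    n_ch = len(CHANNELS_1020)
    idx = {c: i for i, c in enumerate(CHANNELS_1020)}

    noise_rms = BACKGROUND_RMS_UV * profile.noise_gain
    background = _pink_noise(rng, n_ch, n) * noise_rms

    f0 = profile.dominant_freq_hz
    osc = _narrowband(rng, n_ch, n, sfreq, f0, OSC_BANDWIDTH_HZ)
    c = profile.coupling_strength
    if c > 0:
        lag = int(round(sfreq / (4.0 * f0)))
        if coupling_mode == "zero_lag":
            lag = 0
        for drv, rcv in COUPLED_PAIRS:
            delayed = np.roll(osc[idx[drv]], lag)
            osc[idx[rcv]] = np.sqrt(1.0 - c**2) * osc[idx[rcv]] + c * delayed
    osc *= OSC_RMS_RATIO * noise_rms

    data = background + osc

    if profile.shared_source_gain > 0:
        source = _broadband(rng, n, sfreq)
        for ch, gain in SHARED_SOURCE_GAINS.items():
            data[idx[ch]] += profile.shared_source_gain * gain * noise_rms * source

    # artefact epochs: square pulse + linear drift, amplitude well above
    # 5x the per-channel background SD so the rejection stage must remove them
    if profile.artefact_rate > 0:
        epoch_samples = int(round(sfreq))
        n_epochs = n // epoch_samples
        channel_sd = data.std(axis=-1)
        hit = rng.random(n_epochs) < profile.artefact_rate
        for ep in np.nonzero(hit)[0]:
            sl = slice(ep * epoch_samples, (ep + 1) * epoch_samples)
            chans = rng.choice(n_ch, size=rng.integers(1, 4), replace=False)
            start = rng.integers(0, epoch_samples // 2)
            width = epoch_samples // 4
            for ch in chans:
                pulse = np.zeros(epoch_samples)
                pulse[start:start + width] = 6.0 * channel_sd[ch]
                drift = np.linspace(0.0, 5.0 * channel_sd[ch], epoch_samples)
                data[ch, sl] += pulse + drift

    return EEGRecording(data=data, sfreq=sfreq, ch_names=CHANNELS_1020,
                        subject_id=profile.subject_id)


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------

#: Demographics used when sampling ages / GCS per group (mean, SD), matching
#: the reference cohort's summary table.
_AGE_PARAMS = {"TBI": (34.3, 17.0), "nonTBI": (49.1, 15.2)}
_GCS_PARAMS = {"TBI": (4.73, 1.94), "nonTBI": (4.22, 2.97)}


def generate_profiles(config: CohortConfig) -> list[SubjectProfile]:
    """Draw per-subject generative parameters for a full cohort.

    Etiology-linked parameters (dominant frequency, coupling) and
    outcome-linked parameters (shared-source gain) are drawn independently,
    so each contrast is specific to its own biomarker family.
    """
    rng = np.random.default_rng(config.master_seed)
    eff = config.effects
    profiles: list[SubjectProfile] = []
    group_specs = [("TBI", config.n_tbi, config._fracs[0]),
                   ("nonTBI", config.n_nontbi, config._fracs[1])]
    for etiology, n_group, frac in group_specs:
        n_improved = int(round(frac * n_group))
        outcomes = np.array(["improved"] * n_improved
                            + ["nonimproved"] * (n_group - n_improved))
        rng.shuffle(outcomes)
        sign = +0.5 if etiology == "nonTBI" else -0.5
        for k in range(n_group):
            outcome = str(outcomes[k])
            osign = +0.5 if outcome == "improved" else -0.5
            f0 = rng.normal(eff.dominant_freq_base_hz
                            + sign * eff.dominant_freq_shift_hz,
                            eff.dominant_freq_sd_hz)
            coupling = rng.normal(eff.coupling_base + sign * eff.coupling_shift,
                                  eff.coupling_sd)
            shared = rng.normal(eff.shared_gain_base + osign * eff.shared_gain_shift,
                                eff.shared_gain_sd)
            age_m, age_sd = _AGE_PARAMS[etiology]
            profiles.append(SubjectProfile(
                subject_id=f"sub-{etiology.lower()}-{k + 1:02d}",
                etiology=etiology,
                outcome=outcome,
                age_years=float(np.clip(rng.normal(age_m, age_sd), 18.0, 80.0)),
                # dominant frequency kept >= 2.5 Hz so a 6-cycle wavelet
                # fits a 2-s epoch
                dominant_freq_hz=float(np.clip(f0, 2.5, 12.0)),
                coupling_strength=float(np.clip(coupling, 0.0, 1.0)),
                shared_source_gain=float(max(shared, 0.0)),
                noise_gain=config.noise_gain,
                artefact_rate=config.artefact_rate,
                seed=int(rng.integers(0, 2**31 - 1)),
            ))
    return profiles


def clinical_record(profile: SubjectProfile,
                    rng: np.random.Generator) -> SubjectRecord:
    """Assign GCS/GOS scores consistent with the profile's outcome label."""
    gcs_m, gcs_sd = _GCS_PARAMS[profile.etiology]
    gcs = int(np.clip(round(rng.normal(gcs_m, gcs_sd)), 3, 15))
    gos_t0 = int(rng.integers(1, 4))
    if profile.outcome == "improved":
        gos_t1 = int(min(5, gos_t0 + rng.integers(1, 3)))
    else:
        gos_t1 = int(max(1, gos_t0 - rng.choice([0, 0, 0, 1])))
    return SubjectRecord(
        subject_id=profile.subject_id,
        etiology=profile.etiology,
        age_years=round(profile.age_years, 1),
        gcs_baseline=gcs,
        gos_t0=gos_t0,
        gos_t1=gos_t1,
    )


def generate_cohort(
    config: CohortConfig,
    duration_s: float | None = None,
) -> tuple[list[SubjectRecord], list[EEGRecording]]:
    """Generate the cohort table and all recordings.

    ``duration_s`` overrides ``config.recording_length_s`` (tests use short
    recordings; the clinical default is 20 min).
    """
    duration = config.recording_length_s if duration_s is None else duration_s
    profiles = generate_profiles(config)
    rng = np.random.default_rng(
        np.random.SeedSequence([config.master_seed, 929]).generate_state(1)[0]
    )
    records = [clinical_record(p, rng) for p in profiles]
    recordings = [
        generate_subject_eeg(p, duration_s=duration,
                             sfreq=config.sampling_rate_hz)
        for p in profiles
    ]
    return records, recordings


def cohort_table(records: list[SubjectRecord]) -> pd.DataFrame:
    """Cohort CSV layout: one clinical row per subject."""
    return pd.DataFrame([dataclasses.asdict(r) for r in records],
                        columns=["subject_id", "etiology", "age_years",
                                 "gcs_baseline", "gos_t0", "gos_t1"])


def write_cohort(config: CohortConfig, out_dir: str | Path,
                 duration_s: float | None = None) -> Path:
    """Write one EDF per subject plus ``cohort.csv``; returns the directory."""
    from .edf import write_edf

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records, recordings = generate_cohort(config, duration_s=duration_s)
    for rec in recordings:
        write_edf(rec, out_dir / f"{rec.subject_id}.edf")
    table = cohort_table(records)
    table = table.rename(columns={"age_years": "age"})
    table.to_csv(out_dir / "cohort.csv", index=False)
    return out_dir
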