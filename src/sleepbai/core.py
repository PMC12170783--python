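"""Core domain types shared across the pipeline.

The pipeline works with overnight EEG from one of two device classes:

* ``wearable`` — a reduced-montage home headband with two bipolar
  frontal–occipital channels (F7-O1, F8-O2) sampled at 250 Hz;
* ``psg`` — laboratory polysomnography with six referential channels
  (F3-M2, F4-M1, C3-M2, C4-M1, O1-M2, O2-M1) sampled at 200 Hz.

Amplitudes are always carried in microvolts. Sleep stages follow the AASM
five-class scheme ``W, N1, N2, N3, REM`` scored in 30-s epochs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

EPOCH_SECONDS = 30
STAGES = ("W", "N1", "N2", "N3", "REM")
UNKNOWN_STAGE = "UNKNOWN"

WEARABLE_CHANNELS = ("F7-O1", "F8-O2")
PSG_CHANNELS = ("F3-M2", "F4-M1", "C3-M2", "C4-M1", "O1-M2", "O2-M1")
#: referential PSG channels used to approximate the wearable's frontal pair
PSG_FRONTAL_CHANNELS = ("F3-M2", "F4-M1")

WEARABLE_FS = 250.0
PSG_FS = 200.0

#: mapping of PSG frontal channels onto the wearable channel slots, used when
#: a model trained on one montage is applied across devices
CHANNEL_PAIRING = {"F3-M2": "F7-O1", "F4-M1": "F8-O2"}


class ValidationError(ValueError):
    """Input violates a documented precondition."""


class FormatError(ValueError):
    """A file could not be parsed in the declared dialect."""


class VersionError(ValueError):
    """Serialized object does not match the expected catalog/feature version."""


class AlignmentError(ValueError):
    """Recording and hypnogram lengths disagree beyond tolerance."""


def normalize_channel_label(label: str) -> str:
    """Map channel-label variants onto canonical montage names.

    Case-insensitive; tolerates missing hyphens (``"f7o1"`` → ``"F7-O1"``)
    and surrounding whitespace or an ``EEG`` prefix.
    """
    s = label.strip().upper().replace(" ", "")
    if s.startswith("EEG"):
        s = s[3:]
    compact = s.replace("-", "")
    for canon in WEARABLE_CHANNELS + PSG_CHANNELS:
        if compact == canon.replace("-", ""):
            return canon
    return s


def infer_device(channels: Sequence[str]) -> str:
    """Infer the device class from a set of canonical channel labels."""
    chs = set(channels)
    if chs and chs <= set(WEARABLE_CHANNELS):
        return "wearable"
    if chs and chs <= set(PSG_CHANNELS):
        return "psg"
    raise ValidationError(f"channel set {sorted(chs)} matches no known montage")


@dataclass
class EEGRecording:
    """One night of multichannel EEG in microvolts."""

    subject_id: str
    night_index: int
    device: str  # "wearable" | "psg"
    channels: tuple[str, ...]
    fs: float
    signal: np.ndarray  # shape (n_channels, n_samples), µV
    start_clock: str = "23:00"  # HH:MM, 24-h clock of first sample

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise ValidationError("signal must be 2-D (channels × samples)")
        if self.signal.shape[0] != len(self.channels):
            raise ValidationError("channel count does not match signal rows")
        if self.fs <= 40.0:
            raise ValidationError("sampling rate must exceed 2×20 Hz")
        if self.device not in ("wearable", "psg"):
            raise ValidationError(f"unknown device {self.device!r}")
        hh, mm = self.start_clock.split(":")
        if not (0 <= int(hh) < 24 and 0 <= int(mm) < 60):
            raise ValidationError(f"bad start_clock {self.start_clock!r}")

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_seconds(self) -> float:
        return self.n_samples / self.fs

    @property
    def n_epochs(self) -> int:
        return int(self.duration_seconds // EPOCH_SECONDS)

    def copy_with(self, **changes) -> "EEGRecording":
        return replace(self, **changes)


@dataclass
class Hypnogram:
    """Sequence of 30-s sleep-stage labels for one recording."""

    stages: tuple[str, ...]
    epoch_seconds: int = EPOCH_SECONDS

    def __post_init__(self) -> None:
        self.stages = tuple(self.stages)
        bad = [s for s in self.stages if s not in STAGES + (UNKNOWN_STAGE,)]
        if bad:
            raise ValidationError(f"unknown stage labels {sorted(set(bad))}")
        if self.epoch_seconds != EPOCH_SECONDS:
            raise ValidationError("epoch_seconds is fixed at 30")

    def __len__(self) -> int:
        return len(self.stages)

    def check_against(self, rec: EEGRecording) -> None:
        """Assert the length contract len(stages) == floor(N / (30·fs))."""
        if len(self.stages) != rec.n_epochs:
            raise AlignmentError(
                f"hypnogram has {len(self.stages)} epochs, recording has {rec.n_epochs}"
            )


@dataclass
class Epoch:
    """A single 30-s segment of a recording with its stage label."""

    subject_id: str
    night_index: int
    epoch_index: int
    stage: str
    signal: np.ndarray  # (n_channels, 30·fs) µV
    fs: float
    channels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        n_expected = int(round(EPOCH_SECONDS * self.fs))
        if self.signal.shape[-1] != n_expected:
            raise ValidationError(
                f"epoch must hold exactly {n_expected} samples, got {self.signal.shape[-1]}"
            )


def substream(seed: int, *names) -> np.random.Generator:
    """Named, reproducible child random stream of a master seed.

    A single pipeline seed governs all stochastic stages; each stage draws
    from its own named substream so stage-local reruns are stable.
    """
    tokens = [abs(hash_name(str(n))) if isinstance(n, str) else int(n) for n in names]
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=tuple(tokens)))


def hash_name(name: str) -> int:
    # stable across processes (unlike built-in hash)
    h = 2166136261
    for b in name.encode():
        h = ((h ^ b) * 16777619) % (2**31)
    return h
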