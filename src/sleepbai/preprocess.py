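"""Filtering, epoching and recording-level inclusion screening.

The conditioning chain is the standard one for sleep EEG microstructure
analysis: a 60 Hz notch against mains interference, a 0.5–20 Hz bandpass
against drift and myogenic contamination, then segmentation into
non-overlapping 30-s epochs carrying their hypnogram stage.

Recordings are screened before analysis: shorter than 3 h or longer than
10 h, more than 50% artifact-contaminated epochs, or a start time at an
unusual hour (04:00–18:00) each exclude the whole night.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import signal as sps

from .core import (
    EPOCH_SECONDS,
    AlignmentError,
    EEGRecording,
    Epoch,
    Hypnogram,
    UNKNOWN_STAGE,
    ValidationError,
)

BANDPASS_LOW_HZ = 0.5
BANDPASS_HIGH_HZ = 20.0
NOTCH_HZ = 60.0
NOTCH_Q = 30.0


@lru_cache(maxsize=8)
def _bandpass_sos(fs: float):
    # Minimal-order elliptic bandpass applied forward-backward (zero phase).
    # Spec targets after the two-pass application: ≤1 dB ripple over 1–18 Hz
    # and ≥20 dB attenuation at ≥25 Hz; 0.4/12 dB per pass satisfies both.
    order, wn = sps.ellipord(
        [BANDPASS_LOW_HZ, BANDPASS_HIGH_HZ], [0.15, 25.0], gpass=0.4, gstop=12.0, fs=fs
    )
    return sps.ellip(order, 0.4, 12.0, wn, btype="bandpass", output="sos", fs=fs)


@lru_cache(maxsize=8)
def _notch_ba(fs: float):
    return sps.iirnotch(NOTCH_HZ, NOTCH_Q, fs=fs)


def filter_signal(rec: EEGRecording) -> EEGRecording:
    """Zero-phase 60 Hz notch + 0.5–20 Hz bandpass, per channel."""
    if rec.fs < 100.0:
        raise ValidationError("sampling rate too low for the 0.5–20 Hz band")
    x = rec.signal
    if rec.fs > 2 * NOTCH_HZ:
        b, a = _notch_ba(rec.fs)
        x = sps.filtfilt(b, a, x, axis=-1)
    x = sps.sosfiltfilt(_bandpass_sos(rec.fs), x, axis=-1)
    return rec.copy_with(signal=x)


def segment_epochs(rec: EEGRecording, hypnogram: Hypnogram) -> list[Epoch]:
    """Cut a filtered recording into consecutive 30-s epochs with stages.

    The trailing partial window is dropped. A hypnogram shorter by exactly
    one epoch is tolerated (padded with UNKNOWN); larger mismatches are an
    alignment error.
    """
    n_epochs = rec.n_epochs
    stages = list(hypnogram.stages)
    if len(stages) == n_epochs - 1:
        stages.append(UNKNOWN_STAGE)
    if len(stages) < n_epochs:
        raise AlignmentError(
            f"hypnogram has {len(hypnogram.stages)} epochs for a {n_epochs}-epoch recording"
        )
    n_per = int(round(EPOCH_SECONDS * rec.fs))
    return [
        Epoch(
            subject_id=rec.subject_id,
            night_index=rec.night_index,
            epoch_index=i,
            stage=stages[i],
            signal=rec.signal[:, i * n_per:(i + 1) * n_per],
            fs=rec.fs,
            channels=rec.channels,
        )
        for i in range(n_epochs)
    ]


def epoch_array(rec: EEGRecording) -> np.ndarray:
    """All complete epochs as one array of shape (n_epochs, n_channels, 30·fs)."""
    n_per = int(round(EPOCH_SECONDS * rec.fs))
    n_epochs = rec.n_epochs
    return rec.signal[:, : n_epochs * n_per].reshape(
        rec.signal.shape[0], n_epochs, n_per
    ).transpose(1, 0, 2)


@dataclass
class InclusionDecision:
    """Outcome of recording-level screening."""

    included: bool
    reasons: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.reasons = frozenset(self.reasons)
        assert self.included == (not self.reasons)


MIN_DURATION_HR = 3.0
MAX_DURATION_HR = 10.0
MAX_ARTIFACT_FRACTION = 0.5
UNUSUAL_START = ("04:00", "18:00")  # half-open interval of start clock times


def screen_recording(rec: EEGRecording, artifact_fraction: float) -> InclusionDecision:
    """Apply the four exclusion rules to one recording.

    ``artifact_fraction`` is the fraction of epochs flagged by the artifact
    module. "Unusual sleep time" is operationalized as the recording *start*
    falling within [04:00, 18:00).
    """
    if not 0.0 <= artifact_fraction <= 1.0:
        raise ValidationError("artifact_fraction must lie in [0, 1]")
    reasons = set()
    hours = rec.duration_seconds / 3600.0
    if hours < MIN_DURATION_HR:
        reasons.add("too_short")
    if hours > MAX_DURATION_HR:
        reasons.add("too_long")
    if artifact_fraction > MAX_ARTIFACT_FRACTION:
        reasons.add("excess_artifact")
    if UNUSUAL_START[0] <= rec.start_clock < UNUSUAL_START[1]:
        reasons.add("unusual_time")
    return InclusionDecision(included=not reasons, reasons=frozenset(reasons))
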