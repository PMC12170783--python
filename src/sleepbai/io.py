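"""File formats: EDF signals, hypnogram tables, feature tables, model files.

Dialects
--------
* EDF/EDF+ for signals. Writing produces plain EDF with 1-s data records,
  16-bit samples and a fixed physical range of ±8000 µV, so the quantization
  step is deterministic (16000/65535 ≈ 0.244 µV). Reading goes through
  :mod:`mne`; amplitudes are returned in microvolts.
* Hypnograms are per-epoch delimited tables (columns ``epoch_index, stage``),
  one row per 30-s epoch, comma- or tab-separated.
* Feature tables are CSV with a leading manifest comment line
  ``#catalog=<name>;n_features=<n>``.
* Models serialize to a JSON manifest with embedded numeric arrays.
"""

from __future__ import annotations

import datetime
import json
import struct
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    EEGRecording,
    FormatError,
    Hypnogram,
    UNKNOWN_STAGE,
    ValidationError,
    VersionError,
    infer_device,
    normalize_channel_label,
)

PHYSICAL_MAX_UV = 8000.0
# symmetric digital range so that 0 µV is exactly representable
DIGITAL_MAX = 32767
DIGITAL_MIN = -32767
#: one analog-to-digital step of the EDF dialect written here, in µV
EDF_QUANT_STEP = 2 * PHYSICAL_MAX_UV / (DIGITAL_MAX - DIGITAL_MIN)

STAGE_TOKEN_MAP = {
    "W": "W", "WAKE": "W",
    "N1": "N1", "1": "N1",
    "N2": "N2", "2": "N2",
    "N3": "N3", "3": "N3", "N4": "N3", "4": "N3",
    "R": "REM", "REM": "REM",
    "?": UNKNOWN_STAGE, "U": UNKNOWN_STAGE, "UNKNOWN": UNKNOWN_STAGE,
}


class UnsupportedLayoutError(FormatError):
    """EDF layout the pipeline cannot use (e.g. mixed sampling rates)."""


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii", errors="replace")[:width]
    return b + b" " * (width - len(b))


def write_edf(rec: EEGRecording, path) -> Path:
    """Write a recording to plain EDF (16-bit, 1-s records, ±8000 µV range).

    Signals whose length is not a whole number of seconds are zero-padded to
    the next full data record. Non-finite or out-of-range samples are a
    validation error.
    """
    path = Path(path)
    sig = np.asarray(rec.signal, dtype=float)
    if not np.all(np.isfinite(sig)):
        raise ValidationError("EDF writer requires finite samples")
    if np.abs(sig).max(initial=0.0) >= PHYSICAL_MAX_UV:
        raise ValidationError(f"|amplitude| must stay below {PHYSICAL_MAX_UV} µV")
    if abs(rec.fs - round(rec.fs)) > 1e-9:
        raise ValidationError("EDF writer requires an integer sampling rate")
    fs = int(round(rec.fs))
    n_ch, n_samp = sig.shape
    n_records = int(np.ceil(n_samp / fs)) if n_samp else 0
    padded = np.zeros((n_ch, n_records * fs))
    padded[:, :n_samp] = sig

    hh, mm = rec.start_clock.split(":")
    header = b"".join([
        _pad("0", 8),
        _pad(rec.subject_id, 80),
        _pad(f"night={rec.night_index} device={rec.device}", 80),
        _pad("01.09.21", 8),
        _pad(f"{int(hh):02d}.{int(mm):02d}.00", 8),
        _pad(str(256 * (1 + n_ch)), 8),
        _pad("", 44),
        _pad(str(n_records), 8),
        _pad("1", 8),
        _pad(str(n_ch), 4),
    ])
    fields = [
        [_pad(ch, 16) for ch in rec.channels],
        [_pad("AgAgCl electrode", 80)] * n_ch,
        [_pad("uV", 8)] * n_ch,
        [_pad(str(-PHYSICAL_MAX_UV), 8)] * n_ch,
        [_pad(str(PHYSICAL_MAX_UV), 8)] * n_ch,
        [_pad(str(DIGITAL_MIN), 8)] * n_ch,
        [_pad(str(DIGITAL_MAX), 8)] * n_ch,
        [_pad("", 80)] * n_ch,
        [_pad(str(fs), 8)] * n_ch,
        [_pad("", 32)] * n_ch,
    ]
    gain = 2 * PHYSICAL_MAX_UV / (DIGITAL_MAX - DIGITAL_MIN)
    digital = np.round((padded + PHYSICAL_MAX_UV) / gain).astype(np.int64) + DIGITAL_MIN
    digital = np.clip(digital, DIGITAL_MIN, DIGITAL_MAX).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        for fld in fields:
            fh.write(b"".join(fld))
        # record-major, signal-contiguous layout
        records = digital.reshape(n_ch, n_records, fs).transpose(1, 0, 2)
        fh.write(records.tobytes())
    return path


def _scan_edf_header(path: Path) -> dict:
    with open(path, "rb") as fh:
        head = fh.read(256)
        if len(head) < 256:
            raise FormatError(f"{path}: truncated EDF header")
        try:
            n_ch = int(head[252:256].decode("ascii").strip())
            n_records = int(head[236:244].decode("ascii").strip())
        except (UnicodeDecodeError, ValueError) as exc:
            raise FormatError(f"{path}: malformed EDF header") from exc
        if n_ch <= 0:
            raise FormatError(f"{path}: EDF header declares {n_ch} signals")
        sig_head = fh.read(256 * n_ch)
        if len(sig_head) < 256 * n_ch:
            raise FormatError(f"{path}: truncated EDF signal headers")

    def field(offset: int, width: int) -> list[str]:
        base = offset * n_ch
        return [
            sig_head[base + i * width: base + (i + 1) * width].decode("ascii", "replace").strip()
            for i in range(n_ch)
        ]

    labels = field(0, 16)
    # samples-per-record column starts after label/transducer/dim/phys/dig/prefilter
    spr_base = n_ch * (16 + 80 + 8 + 8 + 8 + 8 + 8 + 80)
    spr = [
        int(sig_head[spr_base + i * 8: spr_base + (i + 1) * 8].decode("ascii").strip())
        for i in range(n_ch)
    ]
    return {
        "subject_id": head[8:88].decode("ascii", "replace").strip(),
        "recording_id": head[88:168].decode("ascii", "replace").strip(),
        "start_time": head[176:184].decode("ascii", "replace").strip(),
        "n_records": n_records,
        "labels": labels,
        "samples_per_record": spr,
    }


def read_edf(path) -> EEGRecording:
    """Read an EDF/EDF+ file into an :class:`EEGRecording` (µV).

    Channel labels are normalized to canonical montage names and the device
    class is inferred from the montage. All EEG channels must share one
    sampling rate.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    meta = _scan_edf_header(path)
    eeg_idx = [
        i for i, lab in enumerate(meta["labels"])
        if not lab.upper().startswith("EDF ANNOTATIONS")
    ]
    rates = {meta["samples_per_record"][i] for i in eeg_idx}
    if len(rates) > 1:
        raise UnsupportedLayoutError(
            f"{path}: EEG channels carry mixed sampling rates {sorted(rates)}"
        )
    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:  # mne raises various types on malformed input
        raise FormatError(f"{path}: not a readable EDF file ({exc})") from exc

    channels = tuple(normalize_channel_label(ch) for ch in raw.ch_names)
    signal = raw.get_data() * 1e6  # V -> µV
    device = infer_device(channels)

    start_clock = "23:00"
    ts = meta["start_time"].replace(".", ":")
    if len(ts) >= 5:
        start_clock = ts[:5]
    elif isinstance(raw.info.get("meas_date"), datetime.datetime):
        start_clock = raw.info["meas_date"].strftime("%H:%M")

    night_index = 1
    for token in meta["recording_id"].split():
        if token.startswith("night="):
            night_index = int(token.split("=", 1)[1])
    return EEGRecording(
        subject_id=meta["subject_id"] or path.stem,
        night_index=night_index,
        device=device,
        channels=channels,
        fs=float(raw.info["sfreq"]),
        signal=signal,
        start_clock=start_clock,
    )


def edf_night_path(directory, subject_id: str, night_index: int) -> Path:
    """Canonical file name for one subject-night."""
    return Path(directory) / f"{subject_id}_night{night_index}.edf"


# ---------------------------------------------------------------------------
# hypnograms
# ---------------------------------------------------------------------------

def write_hypnogram(hyp: Hypnogram, path, delimiter: str = ",") -> Path:
    path = Path(path)
    df = pd.DataFrame({"epoch_index": np.arange(len(hyp)), "stage": list(hyp.stages)})
    df.to_csv(path, sep=delimiter, index=False)
    return path


def read_hypnogram(path) -> Hypnogram:
    """Parse a per-epoch stage table; tokens are mapped case-insensitively.

    Accepted tokens: W/WAKE, N1/1, N2/2, N3/3/N4/4 (R&K stage 4 merged into
    N3), R/REM, ?/U for unscorable epochs.
    """
    path = Path(path)
    if not path.read_text().strip():
        raise ValidationError(f"{path}: empty hypnogram file")
    try:
        df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise ValidationError(f"{path}: empty hypnogram file") from exc
    if df.empty:
        raise ValidationError(f"{path}: hypnogram has no epochs")
    stage_col = None
    for cand in df.columns:
        if cand.strip().lower() == "stage":
            stage_col = cand
    if stage_col is None:
        raise FormatError(f"{path}: no 'stage' column in header {list(df.columns)}")
    stages = []
    for row, token in enumerate(df[stage_col]):
        key = str(token).strip().upper()
        if key not in STAGE_TOKEN_MAP:
            raise FormatError(f"{path}: unknown stage token {token!r} at row {row}")
        stages.append(STAGE_TOKEN_MAP[key])
    return Hypnogram(stages=tuple(stages))


# ---------------------------------------------------------------------------
# delimited tables
# ---------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path, manifest: str | None = None) -> Path:
    """Write a delimited table; floats keep 12 significant digits.

    ``manifest`` (e.g. ``"catalog=bai-v1;n_features=510"``) is stored as a
    leading ``#`` comment line.
    """
    path = Path(path)
    with open(path, "w") as fh:
        if manifest:
            fh.write(f"#{manifest}\n")
        df.to_csv(fh, index=False, float_format="%.12g")
    return path


def read_table(path, expect_manifest: dict | None = None) -> pd.DataFrame:
    """Read a table written by :func:`write_table`.

    ``expect_manifest`` maps keys (``catalog``, ``n_features``) to required
    values; a mismatch raises :class:`VersionError`.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        if not first:
            raise FormatError(f"{path}: empty table")
        manifest: dict[str, str] = {}
        if first.startswith("#"):
            for item in first[1:].strip().split(";"):
                if "=" in item:
                    k, v = item.split("=", 1)
                    manifest[k.strip()] = v.strip()
            rest_pos = fh.tell()
            header = fh.readline()
            fh.seek(rest_pos)
        else:
            header = first
            fh.seek(0)
        if not header.strip() or not any(c.isalpha() for c in header):
            raise FormatError(f"{path}: missing header line")
        df = pd.read_csv(fh)
    if expect_manifest:
        for key, want in expect_manifest.items():
            got = manifest.get(key)
            if got != str(want):
                raise VersionError(f"{path}: manifest {key}={got!r}, expected {want!r}")
    df.attrs["manifest"] = manifest
    return df


# ---------------------------------------------------------------------------
# model files
# ---------------------------------------------------------------------------

def save_model(model, path) -> Path:
    """Serialize a trained model (brain-age or artifact LDA) to JSON text."""
    path = Path(path)
    payload = model.to_dict()
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
    return path


def load_model(path):
    """Load a model saved by :func:`save_model`; dispatches on its kind."""
    path = Path(path)
    with open(path) as fh:
        payload = json.load(fh)
    kind = payload.get("kind")
    if kind == "brainage":
        from .brainage import BrainAgeModel

        return BrainAgeModel.from_dict(payload)
    if kind == "artifact_lda":
        from .artifact import ArtifactModel

        return ArtifactModel.from_dict(payload)
    raise VersionError(f"{path}: unknown model kind {kind!r}")
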