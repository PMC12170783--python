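"""Synthetic multi-night sleep-EEG cohorts with the statistical structure
the brain-age analysis assumes.

Each night is built from a first-order Markov hypnogram over the five AASM
stages and per-epoch colored Gaussian noise shaped by stage-specific band
templates (δ, θ, α, σ log-power levels in dB). Age acts through configured
per-year coefficients on the template parameters relative to a reference
age of 40: an older effective age means, among other declines, lower N3
delta power and fewer N2 spindles/K-complexes — the microstructural aging
signal the brain-age model is meant to read. A subject's ground-truth
``brain_age_offset`` shifts the age used in generation (effective age =
CA + offset), which makes parameter recovery well-defined.

N2 epochs additionally receive sleep-spindle bursts (11–15 Hz, 0.5–1.5 s)
and K-complex-like biphasic transients, the events behind the N2 amplitude/
band-power kurtosis features. A smooth device gain curve imprints the
wearable's spectral coloration (mild attenuation below 2 Hz and above
15 Hz) that the harmonization kernel must remove. Artifacts are injected
separately with ground-truth labels.

What this generator does **not** emulate: ultradian NREM–REM cycling,
within-night homeostatic slow-wave decline, real electrode-contact
nonstationarity, or correlated channel noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import (
    EPOCH_SECONDS,
    PSG_CHANNELS,
    PSG_FS,
    STAGES,
    WEARABLE_CHANNELS,
    WEARABLE_FS,
    EEGRecording,
    Hypnogram,
    ValidationError,
    substream,
)

REFERENCE_AGE = 40.0

#: stage band templates at the reference age, dB re 1 µV²/Hz
STAGE_TEMPLATES_DB = {
    #        delta theta alpha sigma
    "W":   {"delta": 8.0, "theta": 6.0, "alpha": 10.0, "sigma": 2.0},
    "N1":  {"delta": 10.0, "theta": 9.0, "alpha": 6.0, "sigma": 3.0},
    "N2":  {"delta": 13.0, "theta": 8.0, "alpha": 5.0, "sigma": 6.0},
    "N3":  {"delta": 18.0, "theta": 9.0, "alpha": 4.0, "sigma": 4.0},
    "REM": {"delta": 9.0, "theta": 8.0, "alpha": 5.0, "sigma": 2.0},
}

#: template change in dB per year of effective age beyond 40
AGING_DB_PER_YEAR = {
    ("N3", "delta"): -0.15,
    ("N3", "theta"): -0.05,
    ("N2", "delta"): -0.08,
    ("N2", "theta"): -0.04,
    ("N2", "sigma"): -0.08,
    ("N1", "delta"): -0.05,
    ("REM", "theta"): -0.04,
    ("W", "alpha"): -0.05,
}

_BAND_CENTERS = {"delta": 2.5, "theta": 6.0, "alpha": 10.0, "sigma": 13.0}

#: default stage transition matrix (rows/cols in STAGES order); mixes fast
#: enough that short desk-scale nights populate all five stages
DEFAULT_TRANSITION = np.array([
    # W     N1    N2    N3    REM
    [0.50, 0.35, 0.10, 0.02, 0.03],
    [0.10, 0.30, 0.50, 0.05, 0.05],
    [0.03, 0.05, 0.60, 0.22, 0.10],
    [0.02, 0.02, 0.25, 0.65, 0.06],
    [0.05, 0.10, 0.20, 0.05, 0.60],
])


@dataclass
class GroupSpec:
    """One simulated cohort group with (possibly confounded) demographics."""

    label: str
    n_subjects: int
    age_mean: float
    age_sd: float
    brain_age_offset: float = 0.0
    device: str = "wearable"
    sex_probs: dict = field(default_factory=lambda: {"F": 0.5, "M": 0.5})
    education_probs: dict = field(
        default_factory=lambda: {"high_school": 0.3, "college": 0.4, "graduate": 0.3}
    )
    race_probs: dict = field(
        default_factory=lambda: {"white": 0.6, "asian": 0.2, "black": 0.1, "other": 0.1}
    )
    nights_probs: dict = field(default_factory=lambda: {1: 0.26, 2: 0.23, 3: 0.45, 4: 0.06})


@dataclass
class SimulationConfig:
    """Study-level simulation parameters; defaults are the study conditions."""

    groups: list[GroupSpec] = field(default_factory=lambda: default_groups())
    transition: np.ndarray = field(default_factory=lambda: DEFAULT_TRANSITION.copy())
    templates_db: dict = field(default_factory=lambda: {s: dict(v) for s, v in STAGE_TEMPLATES_DB.items()})
    aging_db_per_year: dict = field(default_factory=lambda: dict(AGING_DB_PER_YEAR))
    spindle_rate_at_ref: float = 3.0       # events per N2 epoch at age 40
    spindle_rate_per_year: float = -0.030
    kcomplex_rate_at_ref: float = 1.5
    kcomplex_rate_per_year: float = -0.015
    spindle_amp_uv: float = 20.0
    kcomplex_amp_uv: float = 90.0
    subject_sd_db: float = 1.0   # stable per-subject template deviation
    night_sd_db: float = 0.3     # night-to-night deviation
    epoch_sd_db: float = 0.8     # epoch-to-epoch band-level jitter
    floor_db: float = -2.0       # broadband floor above 16 Hz
    artifact_rate: float = 0.0
    duration_mean_hr: float = 6.0
    duration_sd_hr: float = 1.2
    age_range: tuple = (18.0, 80.0)
    seed: int = 0

    def __post_init__(self) -> None:
        P = np.asarray(self.transition, dtype=float)
        if P.shape != (5, 5) or np.any(P < 0) or np.any(np.abs(P.sum(axis=1) - 1) > 1e-12):
            raise ValidationError("transition matrix must be 5×5 row-stochastic")
        self.transition = P


def default_groups() -> list[GroupSpec]:
    """The confounded two-group contrast: a large, older reference cohort
    and a small, younger cohort whose brains run 6 years young."""
    return [
        GroupSpec(label="reference", n_subjects=200, age_mean=52.0, age_sd=12.0,
                  brain_age_offset=0.0, sex_probs={"F": 0.5, "M": 0.5}),
        GroupSpec(label="meditator", n_subjects=34, age_mean=36.0, age_sd=7.0,
                  brain_age_offset=-6.0, sex_probs={"F": 0.36, "M": 0.64},
                  education_probs={"high_school": 0.05, "college": 0.45, "graduate": 0.5},
                  race_probs={"asian": 0.85, "white": 0.09, "black": 0.03, "other": 0.03}),
    ]


def healthy_training_group(n_subjects: int = 200) -> GroupSpec:
    """Brain-healthy training cohort spanning the 18–80 model age range."""
    return GroupSpec(label="healthy", n_subjects=n_subjects, age_mean=49.0,
                     age_sd=18.0, brain_age_offset=0.0, nights_probs={1: 1.0})


# ---------------------------------------------------------------------------
# hypnograms
# ---------------------------------------------------------------------------

def simulate_hypnogram(duration_hr: float, config: SimulationConfig, seed) -> Hypnogram:
    """First-order Markov stage sequence at 30-s steps, starting in W."""
    if not 0 < duration_hr <= 14:
        raise ValidationError("duration_hr must lie in (0, 14]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(np.floor(duration_hr * 3600 / EPOCH_SECONDS))
    P = config.transition
    cum = np.cumsum(P, axis=1)
    state = 0  # W
    u = rng.random(n)
    out = []
    for i in range(n):
        state = int(np.searchsorted(cum[state], u[i], side="right"))
        state = min(state, 4)
        out.append(STAGES[state])
    return Hypnogram(stages=tuple(out))


def stationary_distribution(P: np.ndarray) -> np.ndarray:
    """Stationary stage distribution of a transition matrix."""
    vals, vecs = np.linalg.eig(P.T)
    v = np.real(vecs[:, np.argmin(np.abs(vals - 1.0))])
    return v / v.sum()


# ---------------------------------------------------------------------------
# nights
# ---------------------------------------------------------------------------

def stage_template_db(stage: str, effective_age: float, config: SimulationConfig) -> dict:
    """Noiseless band levels (dB) for a stage at an effective age."""
    base = config.templates_db[stage]
    return {
        band: base[band] + config.aging_db_per_year.get((stage, band), 0.0) * (effective_age - REFERENCE_AGE)
        for band in base
    }


def event_rates(effective_age: float, config: SimulationConfig) -> tuple[float, float]:
    """(spindles, K-complexes) per N2 epoch at an effective age."""
    def decline(base: float, per_year: float, floor: float) -> float:
        if base <= 0.0:
            return 0.0
        return max(floor, base + per_year * (effective_age - REFERENCE_AGE))

    sp = decline(config.spindle_rate_at_ref, config.spindle_rate_per_year, 0.1)
    kc = decline(config.kcomplex_rate_at_ref, config.kcomplex_rate_per_year, 0.05)
    return sp, kc


def device_gain(freqs: np.ndarray, device: str) -> np.ndarray:
    """Smooth amplitude gain curve a device imprints on the scalp signal."""
    if device == "psg":
        return np.ones_like(freqs)
    f = np.maximum(freqs, 1e-6)
    low = np.sqrt(f ** 2 / (f ** 2 + 0.35 ** 2))     # mild attenuation < 2 Hz
    high = 1.0 / np.sqrt(1.0 + (f / 18.0) ** 4)      # mild roll-off > 15 Hz
    return low * high


def _interp_log_psd(levels_db: np.ndarray, freqs: np.ndarray, floor_db: float) -> np.ndarray:
    """Band levels (…, 4) → smooth log-PSD (…, n_freqs) via control points."""
    ctrl_f = np.array([0.3, 2.5, 6.0, 10.0, 13.0, 16.5, 25.0])
    lead = levels_db.shape[:-1]
    flat = levels_db.reshape(-1, 4)
    out = np.empty((flat.shape[0], freqs.size))
    for i, lv in enumerate(flat):
        ctrl_v = np.array([lv[0] + 1.0, lv[0], lv[1], lv[2], lv[3], floor_db, floor_db - 4.0])
        out[i] = np.interp(freqs, ctrl_f, ctrl_v)
    return out.reshape(*lead, freqs.size)


def _hann(n: int) -> np.ndarray:
    return 0.5 - 0.5 * np.cos(2 * np.pi * np.arange(n) / max(n - 1, 1))


from functools import lru_cache


@lru_cache(maxsize=8)
def _kcomplex_shape(fs: float, device: str) -> np.ndarray:
    """Unit-amplitude biphasic K-complex template, device-gain filtered."""
    tt = np.arange(int(1.2 * fs)) / fs
    shape = -np.exp(-((tt - 0.35) / 0.12) ** 2) + 0.8 * np.exp(-((tt - 0.65) / 0.18) ** 2)
    if device == "psg":
        return shape
    # pad to soften wrap-around of the circular gain filter
    m = len(shape)
    padded = np.concatenate([shape, np.zeros(m)])
    g = device_gain(np.fft.rfftfreq(len(padded), 1.0 / fs), device)
    return np.fft.irfft(np.fft.rfft(padded) * g, n=len(padded))[:m]


def simulate_night(
    subject_row, hypnogram: Hypnogram, device: str, config: SimulationConfig, seed
) -> EEGRecording:
    """One night of synthetic EEG for a subject, driven by its hypnogram.

    ``subject_row`` needs fields ``subject_id``, ``age``,
    ``true_brain_age_offset`` and optionally ``night_index``.
    """
    row = dict(subject_row) if not isinstance(subject_row, dict) else subject_row
    age = float(row["age"])
    offset = float(row.get("true_brain_age_offset", 0.0))
    night_index = int(row.get("night_index", 1))
    lo, hi = config.age_range
    if not lo <= age <= hi:
        raise ValidationError(f"chronological age {age} outside [{lo}, {hi}]")
    if device not in ("wearable", "psg"):
        raise ValidationError(f"unknown device {device!r}")
    eff_age = age + offset

    fs = WEARABLE_FS if device == "wearable" else PSG_FS
    channels = WEARABLE_CHANNELS if device == "wearable" else PSG_CHANNELS[:2]
    n_ch = len(channels)
    n = int(EPOCH_SECONDS * fs)
    E = len(hypnogram)
    if E == 0:
        raise ValidationError("hypnogram is empty")

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    # per-subject template deviation is stable across that subject's nights
    subj_rng = substream(config.seed, "subject-trait", str(row["subject_id"]))
    subj_jit = {
        s: subj_rng.normal(0.0, config.subject_sd_db, size=4) for s in STAGES
    }
    night_jit = {s: rng.normal(0.0, config.night_sd_db, size=4) for s in STAGES}

    bands = ("delta", "theta", "alpha", "sigma")
    levels = np.empty((E, 4))
    stage_idx = {s: i for i, s in enumerate(STAGES)}
    for e, stage in enumerate(hypnogram.stages):
        st = stage if stage in STAGES else "W"
        tmpl = stage_template_db(st, eff_age, config)
        levels[e] = [tmpl[b] for b in bands]
        levels[e] += subj_jit[st] + night_jit[st]
    levels = levels[:, None, :] + rng.normal(0.0, config.epoch_sd_db, size=(E, n_ch, 4))

    from scipy import fft as sfft

    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    gain = device_gain(freqs, device)
    log_psd = _interp_log_psd(levels, freqs, config.floor_db)  # (E, C, nf)
    # device coloration folded into the noise spectrum; events are
    # gain-filtered individually below
    S = 10.0 ** (log_psd / 10.0) * gain ** 2

    amp = np.sqrt(S * fs * n / 4.0).astype(np.float32)
    X = amp * (
        rng.standard_normal(S.shape, dtype=np.float32)
        + 1j * rng.standard_normal(S.shape, dtype=np.float32)
    )
    X[..., 0] = np.sqrt(2.0) * X[..., 0].real
    if n % 2 == 0:
        X[..., -1] = np.sqrt(2.0) * X[..., -1].real
    x = sfft.irfft(X, n=n, axis=-1).astype(float)  # (E, C, n) µV

    # N2 transient events: spindles and K-complex-like biphasic waves
    sp_rate, kc_rate = event_rates(eff_age, config)
    kc_shape = _kcomplex_shape(fs, device)
    for e, stage in enumerate(hypnogram.stages):
        if stage != "N2":
            continue
        for _ in range(rng.poisson(sp_rate)):
            dur = rng.uniform(0.5, 1.5)
            f0 = rng.uniform(11.0, 15.0)
            start = rng.uniform(0.0, EPOCH_SECONDS - dur)
            i0, i1 = int(start * fs), int((start + dur) * fs)
            tt = np.arange(i1 - i0) / fs
            seg = np.sin(2 * np.pi * f0 * tt) * _hann(i1 - i0)
            g0 = float(device_gain(np.array([f0]), device)[0])
            a = max(0.0, rng.normal(config.spindle_amp_uv, 4.0)) * g0
            for c in range(n_ch):
                x[e, c, i0:i1] += a * rng.uniform(0.8, 1.2) * seg
        for _ in range(rng.poisson(kc_rate)):
            start = rng.uniform(0.0, EPOCH_SECONDS - 1.2)
            i0 = int(start * fs)
            a = max(0.0, rng.normal(config.kcomplex_amp_uv, 15.0))
            for c in range(n_ch):
                x[e, c, i0:i0 + len(kc_shape)] += a * rng.uniform(0.8, 1.2) * kc_shape

    start_min = int(rng.uniform(21 * 60, 25 * 60)) % (24 * 60)
    rec = EEGRecording(
        subject_id=str(row["subject_id"]),
        night_index=night_index,
        device=device,
        channels=channels,
        fs=fs,
        signal=x.transpose(1, 0, 2).reshape(n_ch, E * n),
        start_clock=f"{start_min // 60:02d}:{start_min % 60:02d}",
    )
    return rec


# ---------------------------------------------------------------------------
# artifacts
# ---------------------------------------------------------------------------

ARTIFACT_TYPES = ("burst", "flatline", "noise")


def inject_artifacts(rec: EEGRecording, artifact_rate: float, seed) -> tuple[EEGRecording, list[str]]:
    """Contaminate a fraction of epochs; returns ground-truth labels.

    ``burst`` exceeds the 500 µV definite-amplitude rule, ``flatline``
    plants a ≥2-s segment with std < 1 µV, ``noise`` adds sub-threshold
    myogenic-like broadband noise that only the classifier step can catch.
    """
    if not 0.0 <= artifact_rate <= 1.0:
        raise ValidationError("artifact_rate must lie in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(EPOCH_SECONDS * rec.fs)
    E = rec.n_epochs
    labels = ["clean"] * E
    if artifact_rate == 0.0 or E == 0:
        return rec, labels
    sig = rec.signal.copy()
    hit = rng.random(E) < artifact_rate
    t = np.arange(n) / rec.fs
    for e in np.flatnonzero(hit):
        kind = ARTIFACT_TYPES[rng.integers(3)]
        labels[e] = kind
        sl = slice(e * n, (e + 1) * n)
        if kind == "burst":
            start = rng.uniform(0, EPOCH_SECONDS - 1.0)
            i0 = e * n + int(start * rec.fs)
            m = int(1.0 * rec.fs)
            burst = rng.uniform(600, 900) * np.sin(2 * np.pi * 3.0 * t[:m]) * _hann(m)
            ch = rng.integers(sig.shape[0])
            sig[ch, i0:i0 + m] += burst
            # guarantee the amplitude rule fires despite phase cancellation
            peak = i0 + m // 2
            sig[ch, peak] = np.sign(sig[ch, peak] or 1.0) * max(abs(sig[ch, peak]), 620.0)
        elif kind == "flatline":
            dur = rng.uniform(2.5, 4.0)
            start = rng.uniform(0, EPOCH_SECONDS - dur)
            i0 = e * n + int(start * rec.fs)
            m = int(dur * rec.fs)
            ch = rng.integers(sig.shape[0])
            sig[ch, i0:i0 + m] = rng.normal(0.0, 0.1, size=m)
        else:
            noise = rng.standard_normal((sig.shape[0], n))
            spec = np.fft.rfft(noise, axis=-1)
            fr = np.fft.rfftfreq(n, 1.0 / rec.fs)
            spec[:, fr < 14.0] = 0.0
            hf = np.fft.irfft(spec, n=n, axis=-1)
            hf *= 18.0 / hf.std(axis=-1, keepdims=True)
            sig[:, sl] += hf
    return rec.copy_with(signal=sig), labels


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

def _draw_categorical(rng, probs: dict, size: int) -> np.ndarray:
    keys = list(probs)
    p = np.array([probs[k] for k in keys], dtype=float)
    p = p / p.sum()
    return rng.choice(keys, size=size, p=p)


def simulate_cohort_table(config: SimulationConfig) -> pd.DataFrame:
    """Draw the cohort demographics table (ground-truth offsets included)."""
    rows = []
    for group in config.groups:
        if group.n_subjects < 2:
            raise ValidationError("need at least 2 subjects per group for matched designs")
        rng = substream(config.seed, "cohort", group.label)
        lo, hi = config.age_range
        ages = np.clip(rng.normal(group.age_mean, group.age_sd, size=group.n_subjects), lo, hi)
        sexes = _draw_categorical(rng, group.sex_probs, group.n_subjects)
        edus = _draw_categorical(rng, group.education_probs, group.n_subjects)
        races = _draw_categorical(rng, group.race_probs, group.n_subjects)
        nights = _draw_categorical(rng, group.nights_probs, group.n_subjects)
        for i in range(group.n_subjects):
            rows.append({
                "subject_id": f"{group.label}-{i + 1:04d}",
                "group": group.label,
                "age": round(float(ages[i]), 2),
                "sex": sexes[i],
                "education": edus[i],
                "race": races[i],
                "n_nights": int(nights[i]),
                "device": group.device,
                "true_brain_age_offset": group.brain_age_offset,
            })
    return pd.DataFrame(rows)


def subject_night(row, night_index: int, config: SimulationConfig, duration_hr: float | None = None):
    """Simulate one subject-night (hypnogram + recording + artifact labels).

    Deterministic given (config.seed, subject_id, night_index).
    """
    row = dict(row)
    rng = substream(config.seed, "night", str(row["subject_id"]), night_index)
    if duration_hr is None:
        duration_hr = float(np.clip(rng.normal(config.duration_mean_hr, config.duration_sd_hr), 0.5, 14.0))
    hyp = simulate_hypnogram(duration_hr, config, rng)
    row["night_index"] = night_index
    rec = simulate_night(row, hyp, row.get("device", "wearable"), config, rng)
    labels = ["clean"] * len(hyp)
    if config.artifact_rate > 0:
        rec, labels = inject_artifacts(rec, config.artifact_rate, rng)
    return rec, hyp, labels


def iter_cohort_nights(cohort: pd.DataFrame, config: SimulationConfig, duration_hr: float | None = None):
    """Lazily yield (row, night_index, recording, hypnogram, artifact_labels)."""
    for _, row in cohort.iterrows():
        for night in range(1, int(row["n_nights"]) + 1):
            rec, hyp, labels = subject_night(row, night, config, duration_hr)
            yield row, night, rec, hyp, labels


def simulate_cohort(config: SimulationConfig, duration_hr: float | None = None):
    """Materialize a full cohort: table plus per-night recordings/hypnograms.

    Suitable for small cohorts; for large ones iterate
    :func:`iter_cohort_nights` to keep memory bounded.
    """
    table = simulate_cohort_table(config)
    recordings: dict[tuple, EEGRecording] = {}
    hypnograms: dict[tuple, Hypnogram] = {}
    for row, night, rec, hyp, _ in iter_cohort_nights(table, config, duration_hr):
        recordings[(row["subject_id"], night)] = rec
        hypnograms[(row["subject_id"], night)] = hyp
    return table, recordings, hypnograms
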