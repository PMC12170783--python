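"""The per-epoch EEG feature catalog and stage-wise aggregation.

Catalog ``bai-v1`` extracts 51 features per channel from each clean 30-s
epoch (102 for the standard two-channel montage):

frequency domain
    * for each band δ (1–4 Hz), θ (4–8), α (8–12), σ (11–15): mean, std,
      skewness and excess kurtosis of the band-power series computed over
      2-s sub-windows advanced in 1-s steps (16 features). The kurtosis of
      these series is sensitive to transient high-power bursts such as
      K-complexes and spindles;
    * relative band power (band / total 1–20 Hz) for the four bands (4);
    * pairwise mean-power log-ratios δ/θ, δ/α, θ/α, σ/α, δ/σ, θ/σ (6);
    * normalized spectral entropy, 95% spectral edge frequency, total log
      power 1–20 Hz, peak frequency (4);

time domain
    * mean, std, skewness, excess kurtosis (4);
    * min, max, peak-to-peak, RMS (4);
    * line length, zero-crossing rate, Hjorth activity/mobility/complexity (5);
    * sample entropy (m=2, r=0.2·std), permutation entropy (order 3),
      25th/50th/75th percentile of |amplitude| (5);
    * excess kurtosis of the band-filtered signal for δ, θ, α (3).

Per-recording aggregation averages each feature across clean epochs within
each of the five sleep stages, giving the 510-value stage feature vector
(stage-major order W, N1, N2, N3, REM). Stages with no clean epochs are
flagged missing and filled from the brain-age model's stored training means
at prediction time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import EPOCH_SECONDS, STAGES, UNKNOWN_STAGE, ValidationError
from .spectral import multitaper_psd_array

CATALOG = "bai-v1"
BANDS = {"delta": (1.0, 4.0), "theta": (4.0, 8.0), "alpha": (8.0, 12.0), "sigma": (11.0, 15.0)}
TOTAL_BAND = (1.0, 20.0)
SUBWINDOW_SECONDS = 2.0
SUBWINDOW_STEP_SECONDS = 1.0
SAMPEN_TARGET_SAMPLES = 250

_BAND_NAMES = tuple(BANDS)
_RATIO_PAIRS = (
    ("delta", "theta"), ("delta", "alpha"), ("theta", "alpha"),
    ("sigma", "alpha"), ("delta", "sigma"), ("theta", "sigma"),
)

_PER_CHANNEL_NAMES = (
    [f"{b}_bp_{s}" for b in _BAND_NAMES for s in ("mean", "std", "skew", "kurt")]
    + [f"{b}_relpower" for b in _BAND_NAMES]
    + [f"logratio_{a}_{b}" for a, b in _RATIO_PAIRS]
    + ["spectral_entropy", "sef95", "log_total_power", "peak_freq"]
    + ["sig_mean", "sig_std", "sig_skew", "sig_kurt"]
    + ["sig_min", "sig_max", "sig_ptp", "sig_rms"]
    + ["line_length", "zero_crossing_rate", "hjorth_activity", "hjorth_mobility", "hjorth_complexity"]
    + ["sample_entropy", "perm_entropy", "abs_p25", "abs_p50", "abs_p75"]
    + ["bandkurt_delta", "bandkurt_theta", "bandkurt_alpha"]
)
assert len(_PER_CHANNEL_NAMES) == 51


def feature_names(n_channels: int = 2) -> list[str]:
    """Catalog ``bai-v1`` feature names: 51 per channel."""
    return [f"ch{c + 1}_{n}" for c in range(n_channels) for n in _PER_CHANNEL_NAMES]


def stage_feature_names(n_channels: int = 2) -> list[str]:
    """Names for the stage-aggregated vector, stage-major (5 × 102 = 510)."""
    per_epoch = feature_names(n_channels)
    return [f"{stage}_{n}" for stage in STAGES for n in per_epoch]


#: spectral sub-computations run on a copy decimated to this rate; the
#: pipeline's 0.5–20 Hz bandpass makes the signal band-limited well below
#: its Nyquist frequency, so nothing in the analysis band is lost
SPECTRAL_FS = 50.0


def spectral_decimation(fs: float) -> int:
    """Integer decimation factor taking ``fs`` down to ~50 Hz."""
    return max(1, int(round(fs / SPECTRAL_FS)))


def _moments(x: np.ndarray, axis: int = -1) -> tuple[np.ndarray, ...]:
    mu = x.mean(axis=axis, keepdims=True)
    xc = x - mu
    xc2 = xc * xc
    var = xc2.mean(axis=axis)
    std = np.sqrt(var)
    safe = np.maximum(std, np.asarray(1e-12, dtype=std.dtype))
    with np.errstate(divide="ignore", invalid="ignore"):
        skew = np.where(std > 0, (xc2 * xc).mean(axis=axis) / safe ** 3, 0.0)
        kurt = np.where(std > 0, (xc2 * xc2).mean(axis=axis) / safe ** 4 - 3.0, 0.0)
    return mu.squeeze(axis), std, skew, kurt


def _sample_entropy(u: np.ndarray, r_frac: float = 0.2) -> float:
    """SampEn(m=2, r=0.2·std) with Chebyshev distance; 0 for degenerate input."""
    std = u.std()
    if std <= 0 or len(u) < 10:
        return 0.0
    r = r_frac * std
    L = len(u)
    D = np.abs(u[:, None] - u[None, :])
    A2 = np.maximum(D[: L - 1, : L - 1], D[1:, 1:])
    A3 = np.maximum(A2[: L - 2, : L - 2], D[2:, 2:])
    A2 = A2[: L - 2, : L - 2]
    m = L - 2
    off = ~np.eye(m, dtype=bool)
    B = int((A2[off] < r).sum())
    A = int((A3[off] < r).sum())
    if A == 0 or B == 0:
        return 0.0
    return float(-np.log(A / B))


def _perm_entropy(x: np.ndarray) -> np.ndarray:
    """Normalized permutation entropy, order 3, delay 1; x shape (..., n)."""
    r0, r1, r2 = x[..., :-2], x[..., 1:-1], x[..., 2:]
    code = (r0 < r1).astype(int) + 2 * (r0 < r2) + 4 * (r1 < r2)
    n_pat = code.shape[-1]
    H = np.zeros(code.shape[:-1])
    for c in range(8):
        p = (code == c).sum(axis=-1) / n_pat
        with np.errstate(divide="ignore", invalid="ignore"):
            H -= np.where(p > 0, p * np.log(p), 0.0)
    return H / np.log(6.0)


def _fft_bandpass_spec(spec: np.ndarray, freqs: np.ndarray, n: int, lo: float, hi: float) -> np.ndarray:
    from scipy import fft as sfft

    sel = (freqs >= lo) & (freqs < hi)
    masked = np.where(sel, spec, 0.0)
    return sfft.irfft(masked, n=n, axis=-1)


def epoch_features_array(
    epochs: np.ndarray, fs: float, psd: np.ndarray | None = None, psd_freqs: np.ndarray | None = None
) -> np.ndarray:
    """Catalog ``bai-v1`` for a batch of epochs.

    Parameters
    ----------
    epochs : (E, C, N) array of µV signals, N = 30·fs
    psd, psd_freqs : optional precomputed multitaper PSDs (E, C, n_freqs)
        on the 1/30-Hz epoch grid covering at least 0.5–20 Hz

    Returns
    -------
    (E, C·51) feature matrix ordered channel-major.

    Notes
    -----
    Spectral sub-computations (PSDs, sub-window band powers, band-filtered
    kurtosis, permutation entropy) run on a copy decimated to ~50 Hz; the
    pipeline's 0.5–20 Hz bandpass makes this lossless for the analysis
    band. Amplitude statistics use the full-rate signal.
    """
    from scipy import fft as sfft

    x = np.asarray(epochs, dtype=float)
    E, C, N = x.shape
    if N != int(round(EPOCH_SECONDS * fs)):
        raise ValidationError("epochs must be 30 s long")
    x32 = x.astype(np.float32)
    dec = spectral_decimation(fs)
    xs = x32[..., ::dec]  # band-limited signal on the spectral grid
    fs_s = fs / dec
    if psd is None:
        psd_freqs, psd = multitaper_psd_array(xs, fs_s)
    df = psd_freqs[1] - psd_freqs[0]

    blocks: list[np.ndarray] = []

    # --- band-power sub-window series ---------------------------------
    w = int(round(SUBWINDOW_SECONDS * fs_s))
    step = int(round(SUBWINDOW_STEP_SECONDS * fs_s))
    ns = xs.shape[-1]
    starts = np.arange(0, ns - w + 1, step)
    frames = np.stack([xs[..., s:s + w] for s in starts], axis=2)  # (E,C,S,w)
    fspec = np.abs(sfft.rfft(frames, axis=-1)) ** 2 * (2.0 / (fs_s * w))
    ffreqs = np.fft.rfftfreq(w, 1.0 / fs_s)
    fdf = ffreqs[1] - ffreqs[0]
    for lo, hi in BANDS.values():
        series = fspec[..., (ffreqs >= lo) & (ffreqs < hi)].sum(axis=-1) * fdf  # (E,C,S)
        blocks.extend(_moments(series, axis=-1))

    # --- PSD-derived band powers --------------------------------------
    tlo, thi = TOTAL_BAND
    tot_sel = (psd_freqs >= tlo) & (psd_freqs < thi)
    total = psd[..., tot_sel].sum(axis=-1) * df  # (E,C)
    eps = 1e-12
    bp = {
        name: psd[..., (psd_freqs >= lo) & (psd_freqs < hi)].sum(axis=-1) * df
        for name, (lo, hi) in BANDS.items()
    }
    for name in _BAND_NAMES:
        blocks.append(bp[name] / np.maximum(total, eps))
    for a, b in _RATIO_PAIRS:
        blocks.append(np.log10(np.maximum(bp[a], eps) / np.maximum(bp[b], eps)))

    p = psd[..., tot_sel]
    psum = np.maximum(p.sum(axis=-1, keepdims=True), eps)
    pn = p / psum
    with np.errstate(divide="ignore", invalid="ignore"):
        ent = -np.where(pn > 0, pn * np.log(pn), 0.0).sum(axis=-1) / np.log(p.shape[-1])
    blocks.append(np.where(total > 0, ent, 0.0))
    cum = np.cumsum(p, axis=-1) / psum
    sef_idx = (cum < 0.95).sum(axis=-1)
    f_in = psd_freqs[tot_sel]
    blocks.append(f_in[np.minimum(sef_idx, len(f_in) - 1)])
    blocks.append(np.log10(np.maximum(total, eps)))
    blocks.append(f_in[p.argmax(axis=-1)])

    # --- time-domain statistics ---------------------------------------
    mu, std, skew, kurt = _moments(x32, axis=-1)
    blocks.extend([mu, std, skew, kurt])
    blocks.extend([x32.min(axis=-1), x32.max(axis=-1), np.ptp(x32, axis=-1),
                   np.sqrt((x32 * x32).mean(axis=-1))])
    dx = np.diff(x32, axis=-1)
    blocks.append(np.abs(dx).mean(axis=-1))
    xc = x32 - mu[..., None]
    blocks.append((np.diff(np.signbit(xc), axis=-1) != 0).mean(axis=-1))
    act = std ** 2
    vdx = dx.var(axis=-1)
    mob = np.sqrt(np.where(act > 0, vdx / np.maximum(act, eps), 0.0))
    ddx = np.diff(dx, axis=-1)
    mob2 = np.sqrt(np.where(vdx > 0, ddx.var(axis=-1) / np.maximum(vdx, eps), 0.0))
    comp = np.where(mob > 0, mob2 / np.maximum(mob, eps), 0.0)
    blocks.extend([act, mob, comp])

    dec_se = max(1, int(np.ceil(N / SAMPEN_TARGET_SAMPLES)))
    sampen = np.array(
        [[_sample_entropy(x[e, c, ::dec_se]) for c in range(C)] for e in range(E)]
    )
    blocks.append(sampen)
    blocks.append(_perm_entropy(xs))
    q = np.percentile(np.abs(x32), [25, 50, 75], axis=-1)
    blocks.extend([q[0], q[1], q[2]])

    xspec = sfft.rfft(xs, axis=-1)
    xs_freqs = np.fft.rfftfreq(ns, 1.0 / fs_s)
    for bname in ("delta", "theta", "alpha"):
        lo, hi = BANDS[bname]
        xb = _fft_bandpass_spec(xspec, xs_freqs, ns, lo, hi)
        blocks.append(_moments(xb, axis=-1)[3])

    feats = np.stack([np.asarray(b, dtype=float) for b in blocks], axis=-1)  # (E, C, 51)
    assert feats.shape[-1] == len(_PER_CHANNEL_NAMES)
    return feats.reshape(E, C * len(_PER_CHANNEL_NAMES))


@dataclass
class FeatureVector:
    """102 per-epoch features with provenance."""

    values: np.ndarray
    names: list[str]
    stage: str = UNKNOWN_STAGE
    provenance: dict = field(default_factory=dict)
    degenerate: bool = False


def epoch_features(epoch, psd=None) -> FeatureVector:
    """Catalog ``bai-v1`` features of one :class:`~sleepbai.core.Epoch`."""
    sig = np.atleast_2d(epoch.signal)
    if psd is not None:
        vals = epoch_features_array(sig[None], epoch.fs, psd=psd.power[None], psd_freqs=psd.freqs)[0]
    else:
        vals = epoch_features_array(sig[None], epoch.fs)[0]
    degenerate = bool(np.any(sig.std(axis=-1) == 0))
    return FeatureVector(
        values=vals,
        names=feature_names(sig.shape[0]),
        stage=epoch.stage,
        provenance={"subject_id": epoch.subject_id, "night_index": epoch.night_index,
                    "epoch_index": epoch.epoch_index},
        degenerate=degenerate,
    )


@dataclass
class StageFeatureVector:
    """Per-recording 510-value vector: 102 features × 5 stages, stage-major."""

    values: np.ndarray  # (510,) with NaN in missing-stage blocks
    names: list[str]
    stage_counts: dict[str, int]
    missing_stages: tuple[str, ...]
    catalog: str = CATALOG

    @property
    def n_features(self) -> int:
        return len(self.values)


def stage_aggregate(
    features: np.ndarray, stages, mask=None, n_channels: int = 2
) -> StageFeatureVector:
    """Average per-epoch features within each sleep stage over clean epochs.

    ``features`` is (E, 102); ``stages`` the per-epoch labels; ``mask`` an
    optional :class:`~sleepbai.artifact.ArtifactMask`. UNKNOWN-stage epochs
    are excluded. Missing-stage blocks are NaN and flagged; they are imputed
    from the model's training means at prediction time.
    """
    X = np.asarray(features, dtype=float)
    stages = list(stages)[: X.shape[0]]
    keep = np.ones(X.shape[0], dtype=bool)
    if mask is not None:
        keep = np.zeros(X.shape[0], dtype=bool)
        keep[mask.clean_indices] = True
    n_per = X.shape[1]
    vals = np.full(5 * n_per, np.nan)
    counts: dict[str, int] = {}
    missing = []
    any_clean = False
    for si, stage in enumerate(STAGES):
        sel = keep & np.array([s == stage for s in stages])
        counts[stage] = int(sel.sum())
        if counts[stage] == 0:
            missing.append(stage)
            continue
        any_clean = True
        vals[si * n_per:(si + 1) * n_per] = X[sel].mean(axis=0)
    if not any_clean:
        raise ValidationError("recording has no clean scored epochs; unusable")
    return StageFeatureVector(
        values=vals,
        names=stage_feature_names(n_channels),
        stage_counts=counts,
        missing_stages=tuple(missing),
    )
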