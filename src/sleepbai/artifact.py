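"""Two-step epoch-level artifact rejection.

Step 1 flags "definite" artifacts with deterministic rules: any channel with
a maximum absolute amplitude above 500 µV, or any channel containing a
contiguous segment of at least 2 s whose sample standard deviation falls
below 1 µV (scanned with sliding 2-s windows at 0.5-s steps, so embedded
flat segments are caught, not only whole-epoch flats).

Step 2 applies a trained two-class linear discriminant (LDA) to the
remaining epochs, targeting lower-amplitude contamination such as myogenic
broadband noise. Clinical PSG recordings skip the classifier — only the
definite rules are applied to the cleaner laboratory signals. Definite
flags are never overridden by the classifier.

The classifier's inputs are the small per-channel feature set catalogued as
``artifact-v1`` below.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import ValidationError, VersionError

AMPLITUDE_LIMIT_UV = 500.0
FLATLINE_STD_UV = 1.0
FLATLINE_SECONDS = 2.0
FLATLINE_STEP_SECONDS = 0.5

ARTIFACT_CATALOG = "artifact-v1"
_CHANNEL_FEATURES = (
    "log_power_total",   # log of 0.5–20 Hz power
    "log_power_high",    # log of 15–20 Hz power (myogenic band)
    "line_length",       # mean |first difference|
    "max_abs",
    "std",
    "excess_kurtosis",
    "zero_crossing_rate",
)

CLEAN = "clean"
DEFINITE = "definite_artifact"
CLASSIFIED = "classified_artifact"


def _sliding_std_min(x: np.ndarray, fs: float) -> np.ndarray:
    """Minimum sliding 2-s window std per (..., channel); 0.5-s step."""
    w = int(round(FLATLINE_SECONDS * fs))
    step = max(1, int(round(FLATLINE_STEP_SECONDS * fs)))
    n = x.shape[-1]
    if n < w:
        return np.full(x.shape[:-1], np.inf)
    starts = np.arange(0, n - w + 1, step)
    c1 = np.cumsum(x, axis=-1)
    c2 = np.cumsum(x * x, axis=-1)
    z = np.zeros(x.shape[:-1] + (1,))
    c1 = np.concatenate([z, c1], axis=-1)
    c2 = np.concatenate([z, c2], axis=-1)
    s1 = c1[..., starts + w] - c1[..., starts]
    s2 = c2[..., starts + w] - c2[..., starts]
    var = np.maximum(s2 / w - (s1 / w) ** 2, 0.0)
    return np.sqrt(var).min(axis=-1)


def flag_definite_array(epochs: np.ndarray, fs: float) -> tuple[np.ndarray, list[str | None]]:
    """Definite-rule flags for a batch of epochs of shape (E, C, N).

    Returns a boolean artifact mask per epoch and the firing rule
    (``"amplitude"``, ``"low_amplitude"`` or None) per epoch.
    """
    epochs = np.asarray(epochs, dtype=float)
    amp = np.abs(epochs).max(axis=-1).max(axis=-1) > AMPLITUDE_LIMIT_UV
    flat = (_sliding_std_min(epochs, fs) < FLATLINE_STD_UV).any(axis=-1)
    reasons: list[str | None] = [
        "amplitude" if a else ("low_amplitude" if f else None)
        for a, f in zip(amp, flat)
    ]
    return amp | flat, reasons


def flag_definite(epoch_signal: np.ndarray, fs: float) -> tuple[str, str | None]:
    """Definite-rule flag for one epoch of shape (C, N)."""
    mask, reasons = flag_definite_array(np.asarray(epoch_signal)[None], fs)
    return (DEFINITE if mask[0] else CLEAN), reasons[0]


def epoch_artifact_features_array(epochs: np.ndarray, fs: float) -> np.ndarray:
    """``artifact-v1`` features for a batch of epochs (E, C, N) → (E, C·7)."""
    x = np.asarray(epochs, dtype=float)
    n = x.shape[-1]
    spec = np.abs(np.fft.rfft(x, axis=-1)) ** 2 * (2.0 / (fs * n))
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    df = freqs[1] - freqs[0]
    total = spec[..., (freqs >= 0.5) & (freqs < 20.0)].sum(axis=-1) * df
    high = spec[..., (freqs >= 15.0) & (freqs < 20.0)].sum(axis=-1) * df
    eps = 1e-12
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    std = xc.std(axis=-1)
    m4 = (xc ** 4).mean(axis=-1)
    kurt = np.where(std > 0, m4 / np.maximum(std, eps) ** 4 - 3.0, 0.0)
    feats = np.stack(
        [
            np.log(total + eps),
            np.log(high + eps),
            np.abs(np.diff(x, axis=-1)).mean(axis=-1),
            np.abs(x).max(axis=-1),
            std,
            kurt,
            (np.diff(np.signbit(xc), axis=-1) != 0).mean(axis=-1),
        ],
        axis=-1,
    )  # (E, C, 7)
    return feats.reshape(x.shape[0], -1)


def epoch_artifact_features(epoch_signal: np.ndarray, fs: float) -> np.ndarray:
    """``artifact-v1`` feature vector for one epoch of shape (C, N)."""
    return epoch_artifact_features_array(np.asarray(epoch_signal)[None], fs)[0]


def artifact_feature_names(n_channels: int) -> list[str]:
    return [f"ch{c + 1}_{name}" for c in range(n_channels) for name in _CHANNEL_FEATURES]


@dataclass
class ArtifactModel:
    """Closed-form two-class LDA with pooled, ridge-regularized covariance."""

    feature_names: list[str]
    mean_clean: np.ndarray
    mean_artifact: np.ndarray
    covariance: np.ndarray  # pooled within-class, regularized
    prior_logodds: float  # log(n_artifact / n_clean)
    catalog: str = ARTIFACT_CATALOG
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        d = len(self.feature_names)
        for arr, name in (
            (self.mean_clean, "mean_clean"),
            (self.mean_artifact, "mean_artifact"),
        ):
            if np.asarray(arr).shape != (d,):
                raise VersionError(f"{name} length does not match feature names")
        if np.asarray(self.covariance).shape != (d, d):
            raise VersionError("covariance shape does not match feature names")

    @property
    def weights(self) -> np.ndarray:
        return np.linalg.solve(self.covariance, self.mean_artifact - self.mean_clean)

    @property
    def bias(self) -> float:
        w = self.weights
        return float(-0.5 * w @ (self.mean_artifact + self.mean_clean) + self.prior_logodds)

    def decision(self, features: np.ndarray) -> np.ndarray:
        """Discriminant w·x + b; positive ⇒ artifact posterior > clean."""
        return np.atleast_2d(features) @ self.weights + self.bias

    def predict(self, features: np.ndarray) -> np.ndarray:
        return self.decision(features) > 0

    def to_dict(self) -> dict:
        return {
            "kind": "artifact_lda",
            "catalog": self.catalog,
            "feature_names": list(self.feature_names),
            "mean_clean": self.mean_clean.tolist(),
            "mean_artifact": self.mean_artifact.tolist(),
            "covariance": self.covariance.tolist(),
            "prior_logodds": self.prior_logodds,
            "metadata": self.metadata,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ArtifactModel":
        return cls(
            feature_names=list(d["feature_names"]),
            mean_clean=np.asarray(d["mean_clean"], dtype=float),
            mean_artifact=np.asarray(d["mean_artifact"], dtype=float),
            covariance=np.asarray(d["covariance"], dtype=float),
            prior_logodds=float(d["prior_logodds"]),
            catalog=d.get("catalog", ARTIFACT_CATALOG),
            metadata=d.get("metadata", {}),
        )


def train_lda(features: np.ndarray, labels: np.ndarray, feature_names=None, seed: int | None = None) -> ArtifactModel:
    """Fit the two-class LDA (labels: 1 = artifact, 0 = clean).

    The pooled within-class covariance is regularized by
    ``1e-6 · trace(Σ)/d · I`` to keep the solve well-posed.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels).astype(int)
    if set(np.unique(y)) - {0, 1}:
        raise ValidationError("labels must be binary 0/1")
    if len(np.unique(y)) < 2:
        raise ValidationError("training data must contain both classes")
    n0, n1 = int((y == 0).sum()), int((y == 1).sum())
    if min(n0, n1) < 10:
        raise ValidationError("need at least 10 examples per class")
    d = X.shape[1]
    mu0 = X[y == 0].mean(axis=0)
    mu1 = X[y == 1].mean(axis=0)
    s0 = (X[y == 0] - mu0).T @ (X[y == 0] - mu0)
    s1 = (X[y == 1] - mu1).T @ (X[y == 1] - mu1)
    cov = (s0 + s1) / (n0 + n1 - 2)
    cov = cov + (1e-6 * np.trace(cov) / d) * np.eye(d)
    try:
        np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError("pooled covariance singular after regularization") from exc
    names = list(feature_names) if feature_names is not None else [f"f{i}" for i in range(d)]
    return ArtifactModel(
        feature_names=names,
        mean_clean=mu0,
        mean_artifact=mu1,
        covariance=cov,
        prior_logodds=float(np.log(n1 / n0)),
        metadata={"n_clean": n0, "n_artifact": n1, "seed": seed},
    )


@dataclass
class ArtifactMask:
    """Per-epoch artifact flags for one recording."""

    flags: list[str]  # CLEAN | DEFINITE | CLASSIFIED
    reasons: list[str | None] = field(default_factory=list)

    @property
    def artifact_fraction(self) -> float:
        if not self.flags:
            return 0.0
        return sum(f != CLEAN for f in self.flags) / len(self.flags)

    @property
    def clean_indices(self) -> np.ndarray:
        return np.flatnonzero([f == CLEAN for f in self.flags])


def classify_epochs(
    model: ArtifactModel | None,
    epochs: np.ndarray,
    fs: float,
    device: str = "wearable",
) -> ArtifactMask:
    """Full two-step mask for a batch of epochs of shape (E, C, N).

    Definite rules run first and are final. The LDA runs only on the
    remaining epochs and only for wearable recordings; PSG recordings use
    the definite rules alone.
    """
    epochs = np.asarray(epochs, dtype=float)
    definite, reasons = flag_definite_array(epochs, fs)
    flags = [DEFINITE if d else CLEAN for d in definite]
    if device == "wearable" and model is not None and not definite.all():
        expected = artifact_feature_names(epochs.shape[1])
        if list(model.feature_names) != expected:
            raise VersionError(
                "artifact model feature names do not match extractor "
                f"({len(model.feature_names)} vs {len(expected)} features)"
            )
        remaining = np.flatnonzero(~definite)
        feats = epoch_artifact_features_array(epochs[remaining], fs)
        hits = model.predict(feats)
        for idx, hit in zip(remaining, hits):
            if hit:
                flags[idx] = CLASSIFIED
    return ArtifactMask(flags=flags, reasons=reasons)
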