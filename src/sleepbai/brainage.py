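"""The linear sleep-EEG brain-age model and the brain age index (BAI).

Brain age (BA) is an affine function of the 510 stage-aggregated features:
features are standardized with training-set means and standard deviations
and combined as a weighted sum, ``BA = intercept + Σ w_i z_i``. Weights are
fit by ridge-penalized least squares of chronological age (CA) on the
features of a brain-healthy training cohort (ages 18–80), with the penalty
chosen by 5-fold cross-validated RMSE over a log grid. Ridge keeps the fit
stable with 510 strongly correlated features at modest n; no post-hoc
brain-age bias correction is applied.

The brain age index is the deviation from normative aging,
``BAI = BA − CA`` (years); a participant's point estimate is the average
BAI over their recorded nights, which damps night-to-night variability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import STAGES, ValidationError, VersionError
from .features import CATALOG, StageFeatureVector, stage_feature_names

PENALTY_GRID = np.logspace(-2, 3, 11)
TRAIN_AGE_RANGE = (18.0, 80.0)


@dataclass
class BrainAgeModel:
    """Affine brain-age predictor with its preprocessing metadata."""

    weights: np.ndarray          # (n_features,) on standardized features
    intercept: float             # years
    feature_means: np.ndarray    # training standardization means (raw space)
    feature_stds: np.ndarray     # training standardization stds (raw space)
    training_stage_means: np.ndarray  # raw-space means used to fill missing stages
    feature_names: list[str]
    channel_set: tuple[str, ...]
    catalog: str = CATALOG
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        d = len(self.feature_names)
        for name in ("weights", "feature_means", "feature_stds", "training_stage_means"):
            if np.asarray(getattr(self, name)).shape != (d,):
                raise VersionError(f"model field {name} does not match feature count {d}")

    def _vector(self, vec) -> np.ndarray:
        if isinstance(vec, StageFeatureVector):
            if vec.catalog != self.catalog:
                raise VersionError(
                    f"feature catalog {vec.catalog!r} does not match model {self.catalog!r}"
                )
            if len(vec.values) != len(self.feature_names):
                raise VersionError("stage feature vector length does not match model")
            x = np.asarray(vec.values, dtype=float)
        else:
            x = np.asarray(vec, dtype=float)
            if x.shape != (len(self.feature_names),):
                raise VersionError("feature vector length does not match model")
        # missing-stage imputation from training means
        x = np.where(np.isnan(x), self.training_stage_means, x)
        return x

    def predict(self, vec) -> float:
        """Brain age in years for one stage feature vector (no clipping)."""
        x = self._vector(vec)
        z = (x - self.feature_means) / self.feature_stds
        return float(self.intercept + z @ self.weights)

    def predict_many(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        X = np.where(np.isnan(X), self.training_stage_means, X)
        Z = (X - self.feature_means) / self.feature_stds
        return self.intercept + Z @ self.weights

    def to_dict(self) -> dict:
        return {
            "kind": "brainage",
            "catalog": self.catalog,
            "feature_names": list(self.feature_names),
            "channel_set": list(self.channel_set),
            "weights": self.weights.tolist(),
            "intercept": self.intercept,
            "feature_means": self.feature_means.tolist(),
            "feature_stds": self.feature_stds.tolist(),
            "training_stage_means": self.training_stage_means.tolist(),
            "metadata": self.metadata,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BrainAgeModel":
        return cls(
            weights=np.asarray(d["weights"], dtype=float),
            intercept=float(d["intercept"]),
            feature_means=np.asarray(d["feature_means"], dtype=float),
            feature_stds=np.asarray(d["feature_stds"], dtype=float),
            training_stage_means=np.asarray(d["training_stage_means"], dtype=float),
            feature_names=list(d["feature_names"]),
            channel_set=tuple(d["channel_set"]),
            catalog=d.get("catalog", CATALOG),
            metadata=d.get("metadata", {}),
        )


def train_brain_age(
    features: np.ndarray,
    ages,
    penalty_grid=PENALTY_GRID,
    seed: int = 0,
    channel_set: tuple[str, ...] = ("F7-O1", "F8-O2"),
    feature_names: list[str] | None = None,
    min_n: int = 50,
) -> BrainAgeModel:
    """Fit the ridge brain-age model on a brain-healthy cohort.

    ``features`` is (n, 510) and may contain NaN for missing-stage blocks;
    those are filled with training column means before fitting. Features
    with zero variance are dropped (weight 0) with a warning.
    """
    from sklearn.linear_model import Ridge
    from sklearn.model_selection import KFold

    X = np.asarray(features, dtype=float)
    y = np.asarray(ages, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValidationError("features and ages must align")
    if X.shape[0] < min_n:
        raise ValidationError(f"need at least {min_n} training recordings, got {X.shape[0]}")
    if y.min() < TRAIN_AGE_RANGE[0] - 1e-9 or y.max() > TRAIN_AGE_RANGE[1] + 1e-9:
        raise ValidationError("training ages must lie within [18, 80]")

    col_means = np.nanmean(X, axis=0)
    col_means = np.where(np.isnan(col_means), 0.0, col_means)
    X = np.where(np.isnan(X), col_means, X)

    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    degenerate = sd <= 1e-12 * np.maximum(1.0, np.abs(mu))
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} zero-variance features dropped (weight 0)",
            stacklevel=2,
        )
    sd_safe = np.where(degenerate, 1.0, sd)
    Z = (X - mu) / sd_safe
    Z[:, degenerate] = 0.0

    best_alpha, best_rmse = None, np.inf
    if np.std(y) == 0:
        best_alpha = float(penalty_grid[len(penalty_grid) // 2])
    else:
        kf = KFold(n_splits=5, shuffle=True, random_state=seed)
        splits = list(kf.split(Z))
        for alpha in penalty_grid:
            sq = 0.0
            for tr, te in splits:
                # penalty scaled per sample so the fit is invariant to
                # duplicating the training set
                model = Ridge(alpha=alpha * len(tr)).fit(Z[tr], y[tr])
                resid = y[te] - model.predict(Z[te])
                sq += float(resid @ resid)
            rmse = np.sqrt(sq / len(y))
            if rmse < best_rmse:
                best_alpha, best_rmse = float(alpha), rmse

    final = Ridge(alpha=best_alpha * len(y)).fit(Z, y)
    w = final.coef_.copy()
    w[degenerate] = 0.0
    names = feature_names if feature_names is not None else stage_feature_names()
    return BrainAgeModel(
        weights=w,
        intercept=float(final.intercept_),
        feature_means=mu,
        feature_stds=sd_safe,
        training_stage_means=col_means,
        feature_names=list(names),
        channel_set=tuple(channel_set),
        metadata={
            "n": int(X.shape[0]),
            "age_range": [float(y.min()), float(y.max())],
            "penalty": best_alpha,
            "cv_rmse": None if not np.isfinite(best_rmse) else float(best_rmse),
            "seed": seed,
        },
    )


def predict_brain_age(model: BrainAgeModel, vec) -> float:
    """Brain age (years) for one recording's stage feature vector."""
    return model.predict(vec)


def compute_bai(ba: float, ca: float) -> float:
    """Brain age index: BA − CA, in years."""
    if not (np.isfinite(ba) and np.isfinite(ca)):
        raise ValidationError("BA and CA must be finite")
    return float(ba - ca)


def average_nights(bais) -> float:
    """Point estimate of a participant's BAI: mean over eligible nights."""
    bais = list(bais)
    if not bais:
        raise ValidationError("need at least one eligible night")
    return float(np.mean(bais))


@dataclass
class BAIResult:
    """Per-subject brain-age summary across nights."""

    subject_id: str
    ca: float
    ba_per_night: list[float]
    bai_per_night: list[float]
    mean_bai: float
    n_nights: int

    @classmethod
    def from_nights(cls, subject_id: str, ca: float, ba_per_night) -> "BAIResult":
        ba = [float(b) for b in ba_per_night]
        bai = [compute_bai(b, ca) for b in ba]
        return cls(
            subject_id=subject_id,
            ca=float(ca),
            ba_per_night=ba,
            bai_per_night=bai,
            mean_bai=average_nights(bai),
            n_nights=len(bai),
        )
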