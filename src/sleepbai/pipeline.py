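"""End-to-end orchestration: recording → stage features → BAI → effects.

The canonical per-night processing order is: filter → artifact rejection →
(optional) cross-device harmonization → multitaper PSD → feature catalog →
stage aggregation. These helpers are shared by the command-line interface,
the test-suite and the acceptance script.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .artifact import ArtifactMask, ArtifactModel, classify_epochs
from .brainage import BAIResult, BrainAgeModel, train_brain_age
from .core import UNKNOWN_STAGE, EEGRecording, Hypnogram
from .features import (
    epoch_features_array,
    spectral_decimation,
    stage_aggregate,
    StageFeatureVector,
    stage_feature_names,
)
from .preprocess import InclusionDecision, epoch_array, filter_signal, screen_recording
from .spectral import HarmonizationKernel, apply_kernel_signal, multitaper_psd_array


@dataclass
class ProcessedNight:
    """Result of the per-night feature pipeline."""

    subject_id: str
    night_index: int
    decision: InclusionDecision
    mask: ArtifactMask
    vector: StageFeatureVector | None  # None when the night is excluded


def _harmonize_epochs(epochs: np.ndarray, stages, channels, kernel: HarmonizationKernel,
                      age: float, sex: str) -> np.ndarray:
    out = epochs.copy()
    stages = list(stages)
    by_stage: dict[str, list[int]] = {}
    for e in range(epochs.shape[0]):
        st = stages[e] if e < len(stages) and stages[e] != UNKNOWN_STAGE else "W"
        by_stage.setdefault(st, []).append(e)
    for st, idx in by_stage.items():
        for c, ch in enumerate(channels):
            entry = kernel.resolve(st, age, sex, ch)
            out[np.asarray(idx), c] = apply_kernel_signal(epochs[np.asarray(idx), c], entry)
    return out


def process_recording(
    rec: EEGRecording,
    hypnogram: Hypnogram,
    artifact_model: ArtifactModel | None = None,
    kernel: HarmonizationKernel | None = None,
    age: float | None = None,
    sex: str = "F",
    screen: bool = True,
) -> ProcessedNight:
    """Run one night through the full feature pipeline."""
    rec_f = filter_signal(rec)
    epochs = epoch_array(rec_f)
    stages = list(hypnogram.stages)
    while len(stages) < epochs.shape[0]:
        stages.append(UNKNOWN_STAGE)
    mask = classify_epochs(artifact_model, epochs, rec.fs, device=rec.device)
    decision = screen_recording(rec, mask.artifact_fraction)
    if screen and not decision.included:
        return ProcessedNight(rec.subject_id, rec.night_index, decision, mask, None)
    if kernel is not None:
        epochs = _harmonize_epochs(epochs, stages, rec.channels, kernel,
                                   age if age is not None else 40.0, sex)
    dec = spectral_decimation(rec.fs)
    freqs, psd = multitaper_psd_array(epochs[..., ::dec], rec.fs / dec)
    feats = epoch_features_array(epochs, rec.fs, psd=psd, psd_freqs=freqs)
    vector = stage_aggregate(feats, stages, mask, n_channels=epochs.shape[1])
    return ProcessedNight(rec.subject_id, rec.night_index, decision, mask, vector)


def cohort_stage_vectors(
    cohort: pd.DataFrame,
    config,
    duration_hr: float | None = None,
    artifact_model: ArtifactModel | None = None,
    kernel: HarmonizationKernel | None = None,
    screen: bool = False,
) -> pd.DataFrame:
    """Stage feature vectors for every simulated subject-night.

    Returns one row per included night: metadata columns followed by the
    510 stage features (NaN for missing-stage blocks).
    """
    from .simulate import iter_cohort_nights

    names = stage_feature_names()
    rows = []
    for row, night, rec, hyp, _ in iter_cohort_nights(cohort, config, duration_hr):
        processed = process_recording(
            rec, hyp, artifact_model=artifact_model, kernel=kernel,
            age=float(row["age"]), sex=str(row.get("sex", "F")), screen=screen,
        )
        if processed.vector is None:
            continue
        meta = {
            "subject_id": row["subject_id"],
            "night_index": night,
            "group": row["group"],
            "age": row["age"],
        }
        rows.append({**meta, **dict(zip(names, processed.vector.values))})
    return pd.DataFrame(rows)


def train_model_on_cohort(
    features_df: pd.DataFrame, seed: int = 0, channel_set=("F7-O1", "F8-O2")
) -> BrainAgeModel:
    """Fit the brain-age model on a per-night feature table (column ``age``)."""
    names = stage_feature_names()
    X = features_df[names].to_numpy(dtype=float)
    y = features_df["age"].to_numpy(dtype=float)
    return train_brain_age(X, y, seed=seed, channel_set=channel_set, feature_names=names)


def subject_bai_table(features_df: pd.DataFrame, model: BrainAgeModel) -> pd.DataFrame:
    """Per-subject mean BAI from a per-night feature table."""
    names = stage_feature_names()
    out = []
    for sid, sub in features_df.groupby("subject_id", sort=True):
        ca = float(sub["age"].iloc[0])
        ba = model.predict_many(sub[names].to_numpy(dtype=float))
        res = BAIResult.from_nights(sid, ca, list(ba))
        out.append({
            "subject_id": sid,
            "group": sub["group"].iloc[0],
            "age": ca,
            "mean_bai": res.mean_bai,
            "n_nights": res.n_nights,
        })
    return pd.DataFrame(out)


def pooled_stratum_psds(
    nights,
    subjects: pd.DataFrame,
    min_epochs: int = 30,
    filter_first: bool = True,
):
    """Per-stratum mean PSDs over many nights, for kernel derivation.

    ``nights`` yields (recording, hypnogram) pairs; ``subjects`` supplies
    age/sex per subject_id. PSDs are computed on the common 1/30-Hz grid
    (50 Hz decimated copy), so wearable (250 Hz) and PSG (200 Hz) cohorts
    land on identical frequencies.
    """
    from .features import spectral_decimation
    from .spectral import ANALYSIS_BAND, stratum_mean_psd

    subjects = subjects.set_index("subject_id") if "subject_id" in subjects.columns else subjects
    psd_rows, meta_rows = [], []
    freqs_out = None
    for rec, hyp in nights:
        rec_f = filter_signal(rec) if filter_first else rec
        epochs = epoch_array(rec_f)
        dec = spectral_decimation(rec.fs)
        freqs, psd = multitaper_psd_array(epochs[..., ::dec], rec.fs / dec)
        keep = (freqs >= ANALYSIS_BAND[0]) & (freqs <= ANALYSIS_BAND[1])
        freqs_out = freqs[keep]
        info = subjects.loc[rec.subject_id]
        stages = list(hyp.stages)
        for e in range(epochs.shape[0]):
            st = stages[e] if e < len(stages) else UNKNOWN_STAGE
            if st == UNKNOWN_STAGE:
                continue
            for c, ch in enumerate(rec.channels):
                psd_rows.append(psd[e, c][keep])
                meta_rows.append({"stage": st, "age": float(info["age"]),
                                  "sex": str(info["sex"]), "channel": ch})
    return stratum_mean_psd(
        np.asarray(psd_rows), freqs_out, pd.DataFrame(meta_rows), min_epochs=min_epochs
    )


def matched_group_effect(
    cohort: pd.DataFrame,
    bai: pd.DataFrame,
    group_label: str,
    reference_label: str,
    confounders=("age", "sex", "education", "race"),
):
    """Propensity full matching + weighted effect of group vs reference on BAI.

    Returns (EffectEstimate, MatchResult, balance_before, balance_after).
    """
    from .stats import adjusted_effect, balance_table, estimate_propensity, full_match

    merged = cohort.merge(bai[["subject_id", "mean_bai"]], on="subject_id")
    sub = merged[merged["group"].isin([group_label, reference_label])].reset_index(drop=True)
    scores = estimate_propensity(sub, treated_label=group_label, confounders=confounders)
    sub = sub.loc[scores.index]
    treated = (sub["group"] == group_label).to_numpy()
    match = full_match(scores.to_numpy(), treated, reference_group=reference_label)
    bal_before = balance_table(sub, treated, weights=None, covariates=confounders)
    bal_after = balance_table(sub, treated, weights=match.weights, covariates=confounders)
    est = adjusted_effect(sub["mean_bai"].to_numpy(), treated, match,
                          reference_group=reference_label)
    return est, match, bal_before, bal_after
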