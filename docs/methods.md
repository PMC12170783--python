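# Methods

`sleepbai` implements a sleep-EEG brain-age analysis: overnight EEG and a
hypnogram go in, a brain age index (BAI) and covariate-adjusted group
contrasts come out. This note documents the models, the parameters that
matter, the synthetic-data generator, and the numerical choices.

## Signal conditioning and screening

Signals are carried in microvolts throughout. Conditioning is a zero-phase
60 Hz notch (Q = 30) followed by a zero-phase 0.5–20 Hz bandpass, then
segmentation into non-overlapping 30-s epochs (trailing partial epochs are
dropped; a hypnogram shorter by exactly one epoch is padded with UNKNOWN,
larger mismatches are errors).

The bandpass is a minimal-order elliptic design chosen by `scipy`'s
`ellipord` for a 0.5–20 Hz passband (0.4 dB ripple per pass) and 0.15/25 Hz
stopband edges (12 dB per pass). After the forward–backward application
this yields ≤ 1 dB deviation over 1–18 Hz and ≥ 24 dB attenuation at
25 Hz; a Butterworth of the order usually quoted for sleep pipelines cannot
meet both figures simultaneously once applied twice, which is why the
package uses the elliptic family. Zero-phase filtering preserves the
morphology of transients (K-complexes) that the kurtosis features measure.

Whole recordings are excluded when shorter than 3 h, longer than 10 h,
more than 50% artifact, or started at an unusual hour. "Unusual sleep
time" is operationalized as the recording *start* falling in
[04:00, 18:00); the rule needs an anchor and the start time is the
simplest defensible one.

## Artifact rejection

Two steps, applied per 30-s epoch:

1. **Definite rules** — any channel with max |x| > 500 µV, or any channel
   containing a ≥ 2-s segment with sample SD < 1 µV. The flatline rule is
   evaluated with sliding 2-s windows at 0.5-s steps so that flat segments
   embedded in otherwise normal epochs are caught.
2. **Linear discriminant** — a closed-form two-class LDA (class means,
   pooled within-class covariance ridge-regularized by 10⁻⁶·trace(Σ)/d,
   threshold at equal posterior odds) over the small per-channel feature
   set `artifact-v1` (log total and 15–20 Hz power, line length, max |x|,
   SD, excess kurtosis, zero-crossing rate). This catches sub-threshold
   broadband/myogenic contamination.

Definite flags are never overridden. PSG recordings use the definite rules
only; laboratory signals do not need the classifier step. The `artifact-v1`
feature set is this package's own design — minimal, standard artifact
discriminators — and is versioned so models refuse mismatched extractors.

## Spectral estimation

Per-epoch PSDs use the multitaper method with K = 18 DPSS tapers and
time–half-bandwidth NW = 10 on 30-s windows (K = 2·NW − 2), eigenvalue-
unweighted taper averaging, one-sided density scaling. Under the 2·NW/T
convention the smoothing bandwidth figure is 0.67 Hz. (Taper-count /
bandwidth conventions differ across the literature; the common K = 2·NW − 1
rule is inconsistent with quoting 18 tapers and 0.67 Hz together, so the
package pins the convention that makes both figures true and reports it via
`spectral.reported_bandwidth_hz`.)

Because the pipeline signal is band-limited to 0.5–20 Hz by the filter,
spectral quantities inside the pipeline are computed on a copy decimated
to 50 Hz. The 30-s window keeps the frequency grid at 1/30 Hz regardless
of sampling rate, so wearable (250 Hz) and PSG (200 Hz) recordings land on
identical analysis grids — which is also what makes cross-device PSD
ratios well defined. `spectral.multitaper_psd` itself accepts any rate.
Spectrograms are sequences of per-epoch spectra in dB, clipped to
0.5–20 Hz, with a display floor at −40 dB re 1 µV²/Hz.

## Cross-device harmonization

A wearable imprints a smooth spectral coloration relative to laboratory
PSG. Within each stratum — sleep stage × age decade (18–29 … 70–80) × sex
× channel, with frontal channel pairing F3-M2→F7-O1, F4-M1→F8-O2 — the
group-mean PSDs of the two devices define a target magnitude response

    |H(f)| = sqrt( PSD_ref(f) / PSD_dev(f) ),   f ∈ [0.5, 20] Hz,

realized as a 513-tap symmetric (zero-phase) FIR via `firwin2`. The square
root is deliberate: filtering scales PSD by |H|², so the root of the ratio
is the response that actually moves the device PSD onto the reference; the
raw ratio (available as `mode="literal_ratio"`) corrects power twice.
Out-of-band the target is extended by continuing the band-edge slope for
1 Hz and then holding flat — a hard kink at the edge would ring through
the finite design; with this extension the realized response stays within
2% of target across the band. Strata with fewer than 30 epochs are flagged
insufficient; lookup falls back to the nearest age decade, then to a
stage × channel kernel pooled over demographics. Pipeline order is
filter → artifact rejection → harmonization → features.

## Feature catalog and stage aggregation

Catalog `bai-v1` extracts 51 features per channel per epoch (102 for two
channels); the composition is documented in `sleepbai.features`. It covers
band-power statistics over 2-s/1-s sub-windows for δ, θ, α, σ (the
kurtosis of these series responds to spindle/K-complex bursts), relative
band powers and six log-ratios, spectral entropy/edge/peak/total power,
amplitude statistics, line length, zero crossings, Hjorth parameters,
sample and permutation entropy, amplitude percentiles, and band-filtered
amplitude kurtosis. The exact membership is this package's versioned
reconstruction of the standard sleep brain-age feature family: the count
is pinned at 102 and checked.

Numerical choices: sample entropy (m = 2, r = 0.2·SD, Chebyshev distance)
runs on a stride-decimated ~250-sample copy of the epoch — the O(n²)
template count is not tractable at 7500 samples per epoch at cohort scale,
and the decimated statistic preserves the scale-invariance and
degeneracy behaviour the pipeline relies on. Permutation entropy (order 3,
delay 1, normalized by log 6) uses the 50 Hz copy. Constant epochs impute
0 for entropy/skew/kurtosis and set a degenerate flag. Heavy array math
runs in float32 where the quantity is a statistical estimate whose
sampling error dominates rounding (tapered periodograms, moment sums).

Per recording, features are averaged over clean epochs within each stage
(W, N1, N2, N3, REM), giving the 510-value stage-major vector. Stages with
no clean epochs are NaN-flagged and imputed from the model's stored
training means at prediction time, keeping the linear model applicable to
nights without, e.g., N3.

## Brain-age model

Brain age is an affine function of the 510 features: standardize with
training means/SDs, apply ridge-regression weights, add the intercept.
The penalty is selected by 5-fold cross-validated RMSE over the log grid
10⁻²…10³ (11 points); ridge keeps the fit stable with 510 strongly
correlated features at moderate n. Training requires n ≥ 50 recordings
with ages inside 18–80. Zero-variance features are dropped (weight 0) with
a warning. No post-hoc brain-age bias correction is applied — the index is
the raw deviation BAI = BA − CA, and a participant's point estimate is the
mean BAI over their recorded nights (averaging damps night-to-night
variability). Models serialize to a JSON manifest (weights, scalers, stage
means, channel set, catalog version) and refuse mismatched catalogs.

## Group comparisons

Group effects on BAI are adjusted for confounding demographics (age, sex,
education, race) by propensity-score **full matching**: a logistic model
of group membership (fit on a standardized design; an L2-penalized refit
handles separation), then subclasses over the sorted scores chosen by an
exact dynamic program minimizing total within-subclass spread — measured
on the logit scale, where scores saturating near 0/1 are not spuriously
close — subject to ≥ 1 member of each group per subclass. The smaller group receives unit weights; the other group's
weights are proportional to its subclass's focal:other ratio and rescaled
to sum to that group's size. Balance is audited by standardized mean
differences (indicator-coded categoricals, pooled unweighted SD); |SMD| <
0.1 is the conventional balance criterion. The effect is the weighted
least-squares coefficient of the group indicator, with cluster-robust
covariance at the subclass level (HC1-type small-sample factor) and a t
reference with (n_subclasses − 1) degrees of freedom. The outcome model is
weights-only (no covariates); on 1-D sorted scores the DP is exact, so no
stochastic matching machinery is needed. Ethnicity, when present, is a
covariate rather than a matching confounder.

Plain tools: paired and Welch t-tests, Spearman correlation, the
Bonferroni threshold α/m (0.05/50 = 0.001 in the package's default
labeling, with 0.001 < p < 0.05 labeled "trend-level"), and an OLS trend
line with pointwise 95% confidence band.

## Synthetic cohorts

The generator produces everything the pipeline consumes. Hypnograms are
first-order Markov chains over the five stages at 30-s steps, starting in
W, with a default transition matrix that mixes quickly enough for short
nights to populate every stage (deliberately no ultradian NREM–REM
cycling — cosmetic for this pipeline). Night EEG is per-epoch colored
Gaussian noise shaped by stage band templates (dB levels for δ, θ, α, σ at
a reference age of 40, interpolated into a smooth log-PSD), with N2
spindle bursts (11–15 Hz, 0.5–1.5 s, ~20 µV) and biphasic K-complex
transients (~90 µV). Aging acts linearly in dB/year on configured
template entries (strongest: N3 δ at −0.15 dB/y; N2 σ at −0.08 dB/y) and
on N2 event rates (spindles −0.03/y from 3.0, K-complexes −0.015/y from
1.5); a subject's ground-truth brain-age offset simply shifts the age used
in generation, which is what makes recovery experiments well defined.
Between-subject template jitter (SD 1 dB, stable across a subject's
nights), night jitter (0.3 dB) and epoch jitter (0.8 dB) set the noise
floor; with them, per-subject BAI scatter is a few years, comparable to
published night-to-night BAI variability. The wearable device curve
attenuates mildly below ~2 Hz and above ~15 Hz; PSG is flat. Injected
artifacts come in three flavours with ground-truth labels: >500 µV bursts,
≥2-s flatlines, and sub-threshold broadband noise only the classifier can
catch. Default cohort structure mirrors a confounded observational
contrast: a large older reference group (n = 200, age ≈ N(52, 12²),
offset 0) versus a small younger exposed group (n = 34, age ≈ N(36, 7²),
offset −6 y), nights per subject drawn from {1: 0.26, 2: 0.23, 3: 0.45,
4: 0.06}, night length ≈ N(6.0, 1.2²) h.

What the generator does *not* emulate: ultradian cycling and homeostatic
within-night drift, real electrode-contact nonstationarity, correlated
channel noise, oscillatory phase structure beyond Gaussianity, or
device-specific artifact morphologies. Passing tests therefore demonstrate
that the pipeline recovers the structure the generator encodes — spectral
aging trends, device coloration, confounded group offsets — not that the
model matches any specific real cohort.

## Problem sizes in the test-suite experiments

End-to-end experiments run at desk scale, chosen so every stage of the
pipeline is exercised on a workstation: brain-age training and held-out
calibration use 200-subject cohorts with single 0.5-h nights (60 epochs;
the fast-mixing hypnogram chain populates all five stages); the
confounded effect-recovery experiment uses 20 replicates of 200 + 34
subjects with single 0.25-h nights; harmonization closure uses 10 + 10
reference and 8 held-out subjects at 0.5 h per night with subject-level
template jitter disabled (the closure property concerns device coloration,
which subject variability would only mask). Group sizes, offsets and all
acceptance thresholds are fixed by the study design, not by runtime.

## Known limitations

* The brain-age trainer is ridge-only; the linear "weighted sum" form is
  the contract, alternative learners are out of scope.
* Ridge shrinkage slightly compresses predictions toward the training
  mean age; with the default generator signal-to-noise the residual
  attenuation of injected offsets is well under the reported SEs, and no
  bias correction is applied.
* Harmonization assumes the two devices record the same underlying
  process up to a smooth linear coloration; nonlinear device effects are
  not modeled.
* The full-matching DP is exact for 1-D propensity scores but does not
  generalize to multivariate distance matching.
* EDF support covers plain EDF/EDF+ signal layouts with a single EEG
  sampling rate; annotations and event streams are ignored.
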