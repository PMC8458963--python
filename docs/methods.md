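# Methods

`neurofuse` implements a multimodal pipeline for monitoring dementia severity:
resting-state EEG and structural-MRI morphometry features are extracted per
subject, ranked against the Mini-Mental State Examination score (MMSE, the
continuous regression target, here in the minimal-to-mild range 21–26), and
fed to repeated cross-validated regression models whose error is tested
against a permuted-label null.  Because no public dataset pairs clinical EEG
with MRI morphometry for this population, the package ships a synthetic
cohort generator that reproduces the statistical structure the analysis
assumes; every stage is exercised end-to-end on generated data.

## EEG pre-processing

Recordings are 7-channel (F3, Fz, F4, Cz, P3, Pz, P4), 125 Hz, ~3 min,
eyes-open resting state.  The chain is:

1. **Band-pass 0.5–45 Hz, zero phase.**  Filters are windowed-sinc (Hamming)
   band-pass FIRs.  Zero phase is realized as a *single delay-compensated
   pass* of the symmetric (linear-phase type I) kernel with reflection
   padding — not forward–backward filtering.  This gives exactly zero phase
   at every frequency, preserves the designed (rather than squared) magnitude
   response, and runs as one FFT convolution over an entire
   epochs × channels × samples array.  Tap count follows a transition width
   of min(1 Hz, 0.25·lower band edge), capped at 325 taps so a 1000-sample
   (8 s) epoch always exceeds three filter lengths; the cap is what bounds
   the low-edge steepness of the delta filter (its nominal 0.125 Hz
   transition would need ~3300 taps).  Hamming stop-band attenuation is
   ~53 dB.
2. **Optional wavelet-ICA cleaning.**  FastICA (deflation) unmixes the
   channels; within each component, sym4 wavelet coefficients exceeding a
   universal threshold (σ from the MAD of the finest detail level,
   k·σ·√(2 ln N)) are treated as the artifact, reconstructed and subtracted.
   High-amplitude ocular/muscular transients are attenuated while clean
   activity changes by <10 % RMS.  FastICA's failure to converge on
   near-Gaussian clean data is reported as a warning, not an error.  The
   stage is **off by default** in the shipped analyses: the generator plants
   no artifacts, so cleaning would be a pure identity risk there.
3. **Virtual bipolars.**  Two inter-hemispheric difference channels, F3−F4
   and P3−P4, are appended (9 channels total).
4. **Epoching.**  8-s windows with 1-s shifts starting at sample 0; a 180-s
   recording yields 173 epochs.  No epoch rejection is applied.

## EEG features (286 per epoch, 1716 per subject)

All families are self-normalized, hence invariant to positive rescaling of
the raw signal (checked by a dedicated invariance suite).

* **Relative spectral power** (81): band power / full-band power for delta
  0.5–4, theta 4–8, alpha 8–12, low-alpha 8–10, high-alpha 10–12, beta
  12–30, delta-beta 0.5–30, theta-beta 4–30, gamma 30–45 Hz, per channel.
  Linear-phase FIR edges are −6 dB at the band boundary, so a tone exactly on
  the low/high-alpha split contributes quarter-power to each half; tests
  therefore probe tones inside a half-band.
* **Magnitude squared coherence** (25): Welch MSC (1-s Hamming segments,
  50 % overlap within the epoch) averaged over five bands for the pairs
  Fz–Pz, F3–F4, P3–P4, F3–P3, F4–P4.
* **Amplitude-modulation rate-of-change** (126): per carrier band, the
  zero-phase subband signal's Hilbert envelope is demeaned and its
  periodogram integrated over each permitted modulation band, normalized by
  the carrier's total (DC-free) modulation energy.  DC is removed because
  the feature targets the *rate of change* of subband energy, not its level.
  The 14 permitted (carrier, modulation) combinations are delta-mdelta,
  theta-mdelta, theta-mtheta, alpha-mdelta, alpha-mtheta, beta-mdelta,
  beta-mtheta, beta-malpha, beta-mbeta, gamma-mdelta, gamma-mtheta,
  gamma-malpha, gamma-mbeta, gamma-mgamma; modulation band edges mirror the
  EEG band edges.  Band integration uses half-open intervals [lo, hi) so a
  boundary FFT bin belongs to exactly one band — this keeps a carrier's
  fractions sub-additive (they sum to ≤ 1).
  Two physical constraints matter when reasoning about these features:
  a carrier of bandwidth B has intrinsic envelope fluctuations up to ~B Hz,
  so a narrow carrier (e.g. theta, B = 4 Hz) arrives *saturated* in mdelta
  and is insensitive to added slow modulation; and an imposed modulation at
  rate f puts sidebands at ±f around the carrier, so modulation is only
  preserved through the analysis filter when the sidebands stay in band.
* **Modulation-spectral patches** (54): a dense modulation spectrogram
  (256-ms Hamming STFT frames, 32-ms hop; per carrier bin, the demeaned
  frame-magnitude series is Fourier-transformed along time) is integrated
  over three rectangles R1–R3 of the (modulation × carrier) frequency plane,
  normalized by total DC-free modulation power, plus the ratios R1/R3,
  R2/R1, R2/R3 with the denominator floored at 1e-12.  The shipped
  rectangle coordinates are an explicit approximation (the discriminative
  regions reported in prior severity work are published only graphically);
  they are configuration, and the patch tests construct their own
  rectangles rather than depending on the defaults.

**Functionals.**  Each per-epoch feature trajectory is collapsed with mean,
standard deviation (n−1), coefficient of variation (std/mean, defined 0 when
|mean| < 1e-12), median, skewness and excess kurtosis (moment-based, no bias
correction, defined 0 at zero variance).  Epochs flagged invalid for a
feature are excluded; fewer than 3 valid epochs marks the subject-feature
missing.  6 × 286 = 1716 per-subject features.

## MRI features (285 per subject)

A versioned manifest fixes 62 subcortical volumes (ASEG segmentation rows
plus whole-brain summary volumes such as CortexVol, CerebralWhiteMatterVol,
MaskVol and eTIV), 148 cortical measures (Desikan-Killiany thickness and
area per hemisphere, hemisphere summaries, four lobar thickness summaries)
and 75 white-matter volumes (wmparc regions, unsegmented white matter,
corpus-callosum parts).  The exact structure lists behind the 62/148/75
cardinalities are a documented approximation of a typical morphometry
export; the pipeline's contracts depend on the counts and the naming
grammar, not on specific structures, and the manifest is replaceable
configuration.  Two interchangeable encodings are parsed — FreeSurfer-style
stats files (`#` headers with `Measure` summaries and `ColHeaders`,
whitespace bodies) and a flat two-column TSV — and must agree exactly.
No head-size (eTIV) correction is applied.

## Feature selection and grouping

Rankers score features against MMSE on a dedicated *selection* subset of
subjects (~25 %, MMSE-stratified; see below):

* Pearson and Spearman: score = |correlation|, constants scored 0, ties
  broken by name.
* **mRMR** (difference scheme, greedy): relevance is the univariate
  regression F-statistic expressed on the correlation scale
  (|r| = √(F/(F+n−2)), a monotone transform of F, so the first pick is
  exactly the top-F feature); redundancy is the mean |Pearson| with the
  already-selected set; each step maximizes relevance − redundancy.  Both
  terms must live on the same [0, 1] scale: a raw F-statistic (unbounded,
  easily in the hundreds) minus a correlation (≤ 1) would never let
  redundancy demote a near-duplicate of a selected feature, defeating the
  algorithm's purpose.  A brute-force greedy oracle (plain loops, scipy
  statistics) verifies the vectorized implementation on small instances.

Feature groups mirror the study design: Group 1 = top-24 EEG, Group 2 =
top-24 MRI, Group 3 = top-24 of the fused matrix, Group 4 = top-12 EEG +
top-12 MRI.  Selection is repeated over five independent partitions;
features selected in ≥ 2 runs form the "consistent" sets used for the
restricted models.  In the fused ranking the strongly MMSE-coupled EEG
features dominate and cross-modality redundancy demotes MRI features — the
same asymmetry the original study observed — which is why planted-signal
recovery is assessed on the per-modality rankings that feed Groups 1, 2
and 4.

## Evaluation

* **Partitioning**: per-MMSE-stratum largest-remainder allocation of 25 % to
  the selection side (total = round(0.25·n); a singleton stratum always
  stays on the train/test side), deterministic per seed, five runs.
  Feature-selection subjects never enter any CV fold.
* **Scaling**: max-abs per feature, fitted on the training fold by default
  (leakage-safe); `leakage_mode="pre"` scales the full matrix before
  splitting for fidelity with protocols that normalize first.  Zero-max
  columns pass through flagged; apply-side values may exceed ±1.
* **Repeated CV**: N × K-fold (defaults N=10, K=5 in the shipped analyses;
  the harness supports the 50×5 setting) on the ~75 % train/test side;
  per-fold RMSE plus Pearson/Spearman of predicted vs. observed MMSE
  (recorded missing when undefined).  Backends: linear/RBF SVR (C=1),
  random forest (100 trees, seeded), KNN (k=5, inverse-distance weights) —
  standard scikit-learn estimators behind a fit/predict contract; the
  harness, not the estimators, is the contribution under test.
* **Permutation null**: each replicate permutes the labels once and reruns
  the full repeated CV.  Two statistics are reported.  The classic
  convention — a two-tailed two-sample t-test pooling individual CV-trial
  RMSEs from both sides (`t_trials`, `p_trials`) — is kept for protocol
  fidelity, but it is strongly anticonservative: trials share subjects, so
  on a verifiably null dataset it can emit p-values near 1e-6 in either
  direction.  The significance verdict therefore uses the replicate-level
  test: the true-label mean RMSE is located within the distribution of
  per-permutation mean RMSEs (one-sample t with prediction-interval scaling,
  n_perm − 1 degrees of freedom), for which the permutation replicate is the
  genuinely exchangeable unit.  "Significant" requires replicate-level
  p < 0.025 *and* a lower true-label mean.  With n_perm = 5 the null-cohort
  p-value is approximately uniform, i.e. above 0.05 about 95 % of the time.

## Synthetic cohort generator

The generator *is* the study's data model, with defaults frozen at the
study's conditions: 89 subjects, MMSE sampled from weights
(0.14, 0.19, 0.22, 0.20, 0.15, 0.10) over 21–26 (mean ≈ 23.3, sd ≈ 1.5; the
true cohort histogram is unpublished, so the weights are a configurable
symmetric-ish approximation — the printed sd of 1.8 is barely attainable on
a 6-point support without bimodality), 3-min 7-channel 125 Hz EEG, and a
complete 285-feature MRI table per subject.

**EEG.**  Each channel is an independent sum over the five classical bands
of band-limited Gaussian noise multiplied by a strictly positive envelope
1 + m(t), with a coarse 1/f-like amplitude tilt across bands.  For each
planted (band, modulation band) effect, m(t) adds modulation-band-limited
unit-RMS noise scaled by depth = baseline + slope·(MMSE − 23.5).  Parameters
are validated against over-modulation (depth must stay positive across the
MMSE range and total worst-case depth per band stays below 0.9); residual
Gaussian excursions are clipped at an envelope floor of 0.05.  Default
planted effects: (beta, malpha, baseline 0.28, slope −0.045/point) and
(beta, mtheta, 0.28, +0.045) — wide-carrier pairs chosen because narrow
carriers are saturated by their intrinsic envelope (see above) and cannot
carry a recoverable drift.

**MRI.**  Eight planted features (hippocampal volumes, entorhinal thickness,
temporal/frontal areas, white-matter volumes — regions reported as
severity-sensitive) follow typical + slope·(MMSE − 23.5) + Gaussian noise,
with noise_sd = slope so the population feature–MMSE correlation is ≈ 0.85;
all other manifest features are typical values (category-appropriate scales,
fixed across cohorts) plus 5 % proportional noise.  Values are rounded to
the stats-file precision (0.1 mm³/mm², 0.001 mm) so both on-disk encodings
round-trip exactly.

**What the generator does not emulate**: volume conduction and inter-channel
correlation, true 1/f spectra, artifacts (unless injected by a test),
non-linear feature–MMSE relations, site effects, and realistic effect sizes —
planted correlations are deliberately strong so that recovery is a sharp
pass/fail signal at n = 89.  Passing tests therefore demonstrate that the
pipeline recovers the structure it assumes, not that it would reach any
particular accuracy on clinical data; real-cohort error levels are outside
what synthetic data can certify.

## Persistence

EEG is written as plain EDF (not EDF+): one 1-s record per data block,
16-bit samples, per-signal physical ranges re-parsed from their 8-character
header fields before digitization so a write/read round trip is exact to
within one quantization step; header dates are fixed constants, making
output bytes a pure function of the data.  The writer/reader pair is
implemented here (no installed library writes EDF); `mne`'s EDF reader
serves as an independent oracle in the tests.  MRI tables are written in
both supported encodings; the cohort table is a TSV of (subject_id, mmse).

## Determinism and problem sizes

One master seed determines everything: stage seeds are BLAKE2 hashes of
"master:stage-name" reduced mod 2³¹, cohort seeds and per-repeat CV seeds
derive from them, and the whole pipeline is reproducible bit-for-bit.  The
shipped analyses and checks use the full 89-subject cohort at full recording
length for feature extraction and selection, with N=10, K=5 repeated CV and
5 permutation replicates (the tests scale some cohorts to 16–40 subjects
and 12–60 s where only mechanics, not detection power, are at stake).

## Known limitations

* The trial-level t-test on correlated CV trials is nominal, not exact
  (above); the replicate-level verdict has only n_perm − 1 degrees of
  freedom at the default n_perm = 5.
* The fused (Group 3) mRMR ranking is EEG-dominated by construction when
  EEG effects are strong; MRI recovery is assessed per modality.
* Patch rectangles and the MRI manifest's structure lists are declared
  approximations, shipped as replaceable configuration.
* The narrow-carrier saturation of amplitude-modulation fractions is a
  property of the feature definition itself; severity effects planted there
  are not recoverable, and the defaults avoid those pairs.
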