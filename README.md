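# neurofuse

Multimodal EEG + structural-MRI feature pipeline for monitoring dementia
severity, with a synthetic cohort generator for end-to-end validation.

## The problem

In early Alzheimer's disease, clinicians track severity with the Mini-Mental
State Examination (MMSE, 0–30; 21–26 covers minimal-to-mild dementia).
Resting-state EEG and structural-MRI morphometry each carry severity
information of a different kind — EEG captures the slowing and reduced
dynamics of cortical activity, MRI the regional atrophy — and the question
this package operationalizes is whether *fusing* the two modalities predicts
MMSE better than either alone.  It is intended for researchers building or
stress-testing such prediction pipelines: every stage is a tested library
function, and a generator produces full synthetic cohorts (EEG recordings,
MRI feature tables, MMSE labels) with planted, recoverable severity effects,
so the machinery can be validated end-to-end without any clinical data.

## The method

Per subject, from 7-channel (F3, Fz, F4, Cz, P3, Pz, P4) 125 Hz, 3-min
resting EEG plus two virtual inter-hemispheric bipolars (F3−F4, P3−P4),
features are extracted over 8-s epochs with 1-s shifts:

| family | definition | count/epoch |
|---|---|---|
| relative spectral power | band power / broadband power, 9 bands | 81 |
| magnitude squared coherence | Welch MSC averaged in 5 bands, 5 electrode pairs | 25 |
| amplitude-modulation rate-of-change | Hilbert-envelope spectral energy of carrier band *b* in modulation band *m*, normalized: E(b,m)/ΣE(b,·), 14 permitted (b,m) pairs | 126 |
| modulation-spectral patches | energy in rectangles R1–R3 of the (modulation × carrier) frequency plane + ratios R1/R3, R2/R1, R2/R3 | 54 |

The 286 per-epoch features are collapsed with six functionals (mean, σ,
cv, median, skewness, kurtosis) → 1716 EEG features per subject; MRI
contributes 285 morphometry features (62 subcortical volumes, 148 cortical
thickness/area, 75 white-matter volumes) parsed from FreeSurfer-style stats
tables or flat TSV.  Features are ranked against MMSE on a dedicated
selection subset (25 % of subjects, MMSE-stratified, five repartitions) with
Pearson, Spearman, or greedy mRMR (relevance − redundancy, both on the
correlation scale); the top-24 EEG (Group 1), top-24 MRI (Group 2), top-24
fused (Group 3) and top-12+top-12 (Group 4) sets feed N×K repeated
cross-validated regression (SVR linear/RBF, random forest, KNN), scored by
held-out RMSE and predicted-vs-observed correlation, with significance
assessed against permuted-label refits.  See `docs/methods.md` for the
model details and numerical conventions.

## Worked example

```python
import pandas as pd
from neurofuse import CohortSpec, generate_cohort, rank_mrmr
from neurofuse.pipeline import eeg_feature_matrix, mri_feature_matrix

spec = CohortSpec(n_subjects=30, duration=60.0, seed=7)   # scaled-down cohort
cohort = generate_cohort(spec)
eeg = eeg_feature_matrix(cohort)          # 30 x 1716
mri = mri_feature_matrix(cohort)          # 30 x 285
y = pd.Series({r.subject_id: r.mmse for r in cohort})
ranking = rank_mrmr(pd.concat([eeg, mri], axis=1), y[eeg.index], k=5)
for name, score in zip(ranking.ordered_names, ranking.scores):
    print(f"{score:6.3f}  {name}")
```

prints

```
 0.927  Left-Hippocampus
 0.228  median-pow-delta-beta-P4
 0.458  mean-am-beta-malpha-P3
 0.322  mean-am-beta-malpha-Pz
 0.276  Right-Hippocampus
```

The first pick is the planted hippocampal atrophy effect (score = |r| with
MMSE ≈ 0.93 on this seed); later picks surface the planted beta-band
alpha-rate modulation drift and the second hippocampus while mRMR's
redundancy term demotes near-copies of features already selected.  Scores
after the first are relevance *minus* mean correlation with the selected
set, hence smaller and not monotone.

The full analysis lives in `analysis/` as numbered scripts
(`01_simulate_cohort.py` … `05_significance.py`); each prints what it found
and writes its tables under `results/`.  For example `05_significance.py`
reports, for the 89-subject benchmark cohort:

```
planted: true RMSE 0.287 vs null 1.555, t=-9.76, p=0.000618 -> significant
null-cohort: true RMSE 1.673 vs null 1.597, t=3.08, p=0.0369 -> not significant
  set  n_features  rmse_mean  rmse_sd
  eeg          31      0.233    0.054
  mri          18      0.549    0.123
fused          30      0.233    0.051
fused consistent-feature model beats at least one unimodal model: True
```

i.e. on the planted cohort the Group-4 random forest beats the permuted-label
null decisively (p is the replicate-level permutation test; see
`docs/methods.md`); on a cohort with all planted slopes zeroed the same test
is correctly non-significant; and the fused consistent-feature model does at
least as well as the best unimodal one.  RMSE values here are far below
clinical reality because the generator's planted effects are deliberately
strong — the synthetic benchmark certifies mechanics, not clinical accuracy.

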