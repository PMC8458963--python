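"""Shared configuration for the numbered analysis scripts.

The benchmark configuration is frozen here: an 89-subject synthetic cohort
(3-min, 7-channel, 125 Hz EEG; 285-feature MRI tables; MMSE 21-26) with the
default planted severity effects, mRMR selection over five stratified
selection/train-test partitions, and 10x5 repeated cross-validation.  All
scripts derive their randomness from MASTER_SEED, cache the expensive feature
matrices under scratch/, and write their tables under results/.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

from neurofuse import CohortSpec, RunConfig

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"

MASTER_SEED = 1

CONFIG = RunConfig(
    models=("svm-linear", "svm-rbf", "random-forest", "knn"),
    N=10, K=5, n_perm=5, n_runs=5,
).with_master_seed(MASTER_SEED)

#: Same cohort conditions with every planted slope zeroed: the null study.
NULL_SPEC = dataclasses.replace(
    CONFIG.spec,
    eeg_effects=tuple(dataclasses.replace(e, slope=0.0)
                      for e in CONFIG.spec.eeg_effects),
    mri_effects=tuple(dataclasses.replace(e, slope=0.0)
                      for e in CONFIG.spec.mri_effects),
)

PIPELINE_DIR = SCRATCH / "pipeline"


def ensure_dirs() -> None:
    RESULTS.mkdir(exist_ok=True)
    SCRATCH.mkdir(exist_ok=True)


def benchmark_data(config: RunConfig = CONFIG):
    """(eeg, mri, fused, y) for the benchmark cohort, disk-cached."""
    import pandas as pd

    from neurofuse import generate_cohort
    from neurofuse.pipeline import (_cached_matrix, eeg_feature_matrix,
                                    mri_feature_matrix)

    cohort = generate_cohort(config.spec)
    cache = PIPELINE_DIR / "cache"
    fkey = config.feature_hash()
    eeg = _cached_matrix(cache / "eeg_features.tsv", fkey,
                         lambda: eeg_feature_matrix(cohort, config.band_scheme,
                                                    config.patch_scheme,
                                                    config.use_wica))
    mri = _cached_matrix(cache / "mri_features.tsv", fkey,
                         lambda: mri_feature_matrix(cohort))
    fused = pd.concat([eeg, mri], axis=1)
    y = pd.Series({r.subject_id: r.mmse for r in cohort})[fused.index]
    return eeg, mri, fused, y


def partition_plans(y, config: RunConfig = CONFIG):
    """The frozen per-run selection/train-test partitions."""
    from neurofuse import stratified_partition
    from neurofuse.pipeline import stage_seed

    ids = list(y.index)
    return [stratified_partition(ids, y[ids], frac=config.frac,
                                 seed=stage_seed(config.master_seed,
                                                 f"partition-{r}"),
                                 run_id=r)
            for r in range(config.n_runs)]
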