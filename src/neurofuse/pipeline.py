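"""End-to-end orchestration: cohort -> features -> selection -> evaluation.

``run_all`` executes the whole analysis deterministically from one master
seed.  Stage seeds are derived by hashing ``"<master_seed>:<stage name>"``
(BLAKE2, reduced mod 2^31), so stages are mutually independent yet fully
reproducible.  The two expensive stages (EEG and MRI feature matrices) can be
cached to disk; caches are keyed by a hash of the configuration and are
invalidated automatically when it changes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import CohortSpec, SubjectRecord, generate_cohort, recovered_markers
from .eeg_features import aggregate_functionals, epoch_features
from .evaluate import (consistent_feature_model, permutation_null, repeated_cv,
                       stratified_partition)
from .mri import MriFeatureRow, assemble_mri_matrix, load_manifest
from .preprocess import add_virtual_bipolars, bandpass_zero_phase, make_epochs, wica_clean
from .schemes import BandScheme, PatchScheme
from .selection import (FeatureGroup, RankingResult, build_groups, consistent_set,
                        rank_correlation, rank_mrmr, stability_report)

log = logging.getLogger(__name__)

RANKERS = ("pearson", "spearman", "mrmr")


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed."""
    digest = hashlib.blake2s(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2 ** 31)


@dataclass(frozen=True)
class RunConfig:
    spec: CohortSpec = field(default_factory=CohortSpec)
    ranker: str = "mrmr"
    models: tuple[str, ...] = ("random-forest",)
    N: int = 10
    K: int = 5
    n_perm: int = 5
    frac: float = 0.25
    n_runs: int = 5
    top_k: int = 24
    half_k: int = 12
    master_seed: int = 0
    leakage_mode: str = "fold"
    use_wica: bool = False
    band_scheme: BandScheme = field(default_factory=BandScheme)
    patch_scheme: PatchScheme = field(default_factory=PatchScheme)

    def __post_init__(self) -> None:
        if self.ranker not in RANKERS:
            raise ValueError(f"unknown ranker {self.ranker!r}; choose from {RANKERS}")

    def config_hash(self) -> str:
        return hashlib.blake2s(repr(self).encode()).hexdigest()[:16]

    def feature_hash(self) -> str:
        """Hash of the fields the feature matrices depend on (cache key)."""
        key = repr((self.spec, self.band_scheme, self.patch_scheme, self.use_wica))
        return hashlib.blake2s(key.encode()).hexdigest()[:16]

    def with_master_seed(self, master_seed: int) -> "RunConfig":
        """Re-seed the whole run: the cohort seed is derived from the master."""
        spec = dataclasses.replace(self.spec, seed=stage_seed(master_seed, "cohort"))
        return dataclasses.replace(self, spec=spec, master_seed=master_seed)


def subject_eeg_features(rec, band_scheme: BandScheme | None = None,
                         patch_scheme: PatchScheme | None = None,
                         use_wica: bool = False) -> pd.Series:
    """Per-subject EEG feature vector (1716 values under default schemes).

    Chain: 0.5-45 Hz zero-phase band-pass, optional wavelet-ICA cleaning,
    virtual bipolars, 8-s/1-s epochs, per-epoch features, six functionals.
    """
    filtered = bandpass_zero_phase(rec, 0.5, 45.0)
    if use_wica:
        filtered = wica_clean(filtered)
    expanded = add_virtual_bipolars(filtered)
    epochs = make_epochs(expanded)
    values, valid = epoch_features(epochs, band_scheme, patch_scheme)
    return aggregate_functionals(values, valid)


def eeg_feature_matrix(cohort: list[SubjectRecord],
                       band_scheme: BandScheme | None = None,
                       patch_scheme: PatchScheme | None = None,
                       use_wica: bool = False) -> pd.DataFrame:
    rows = {rec.subject_id: subject_eeg_features(rec.eeg, band_scheme,
                                                 patch_scheme, use_wica)
            for rec in cohort}
    return pd.DataFrame(rows).T


def mri_feature_matrix(cohort: list[SubjectRecord]) -> pd.DataFrame:
    rows = [MriFeatureRow(rec.subject_id, rec.mri) for rec in cohort]
    return assemble_mri_matrix(rows)


def _rank(ranker: str, X: pd.DataFrame, y, k: int, run_id: int) -> RankingResult:
    if ranker == "mrmr":
        return rank_mrmr(X, y, k=k, run_id=run_id)
    return rank_correlation(X, y, method=ranker, run_id=run_id)


def _cached_matrix(path: Path, key: str, compute) -> pd.DataFrame:
    """Load a TSV-cached matrix if its config hash matches, else recompute."""
    key_file = path.with_suffix(".hash")
    if path.exists() and key_file.exists() and key_file.read_text().strip() == key:
        log.info("stage cache hit: %s", path)
        return pd.read_csv(path, sep="\t", index_col=0)
    matrix = compute()
    path.parent.mkdir(parents=True, exist_ok=True)
    matrix.to_csv(path, sep="\t")
    key_file.write_text(key)
    return matrix


def run_all(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Run the full analysis; returns a JSON-serializable results bundle.

    The bundle contains per-run partitions and rankings, the four feature
    groups, pooled repeated-CV summaries per (group, model), stability
    reports and consistent-feature model summaries, and the permutation-null
    significance test for the multimodal Group 4.
    """
    manifest = load_manifest()
    key = config.config_hash()
    cohort = generate_cohort(config.spec, manifest)
    ids = [r.subject_id for r in cohort]
    mmse = pd.Series({r.subject_id: r.mmse for r in cohort})

    def compute_eeg():
        log.info("extracting EEG features for %d subjects", len(cohort))
        return eeg_feature_matrix(cohort, config.band_scheme, config.patch_scheme,
                                  config.use_wica)

    if out_dir is not None:
        cache = Path(out_dir) / "cache"
        fkey = config.feature_hash()
        eeg_X = _cached_matrix(cache / "eeg_features.tsv", fkey, compute_eeg)
        mri_X = _cached_matrix(cache / "mri_features.tsv", fkey,
                               lambda: mri_feature_matrix(cohort))
    else:
        eeg_X = compute_eeg()
        mri_X = mri_feature_matrix(cohort)
    fused_X = pd.concat([eeg_X, mri_X], axis=1)
    y = mmse.loc[eeg_X.index]

    runs = []
    rankings: dict[str, list[RankingResult]] = {"eeg": [], "mri": [], "fused": []}
    groups_per_run: list[dict[int, FeatureGroup]] = []
    for r in range(config.n_runs):
        plan = stratified_partition(ids, mmse[ids], frac=config.frac,
                                    seed=stage_seed(config.master_seed,
                                                    f"partition-{r}"),
                                    run_id=r)
        sel = list(plan.selection_ids)
        per_mod = {}
        for mod, X in (("eeg", eeg_X), ("mri", mri_X), ("fused", fused_X)):
            rk = _rank(config.ranker, X.loc[sel], y[sel],
                       k=config.top_k, run_id=r)
            rankings[mod].append(rk)
            per_mod[mod] = rk
        groups = build_groups(per_mod["eeg"], per_mod["mri"], per_mod["fused"],
                              top_k=config.top_k, half_k=config.half_k)
        groups_per_run.append(groups)
        runs.append({"plan": plan, "groups": groups})

    # pooled repeated CV per (group, model) across the per-run partitions
    cv_summaries: dict[str, dict] = {}
    for gid in (1, 2, 3, 4):
        for model in config.models:
            pooled = []
            for r, run in enumerate(runs):
                members = list(groups_per_run[r][gid].members)
                tt = list(run["plan"].traintest_ids)
                res = repeated_cv(fused_X.loc[tt, members], y[tt], model,
                                  N=config.N, K=config.K,
                                  seed=stage_seed(config.master_seed,
                                                  f"cv-{gid}-{model}-{r}"),
                                  group_id=gid,
                                  leakage_mode=config.leakage_mode)
                pooled.append(res)
            rmse = np.concatenate([p.rmse for p in pooled])
            pear = np.concatenate([p.pearson for p in pooled])
            spear = np.concatenate([p.spearman for p in pooled])
            cv_summaries[f"group{gid}-{model}"] = {
                "rmse_mean": float(rmse.mean()),
                "rmse_sd": float(rmse.std(ddof=1)),
                "pearson_mean": float(np.nanmean(pear)),
                "spearman_mean": float(np.nanmean(spear)),
                "n_trials": int(rmse.size),
            }

    stability = {}
    consistent: dict[str, tuple[str, ...]] = {}
    for mod in ("eeg", "mri", "fused"):
        report = stability_report(rankings[mod], top_k=config.top_k)
        stability[mod] = report
        consistent[mod] = consistent_set(report)

    consistent_summaries = {}
    for mod in ("eeg", "mri", "fused"):
        if not consistent[mod]:
            consistent_summaries[mod] = None
            continue
        pooled = []
        for r, run in enumerate(runs):
            tt = list(run["plan"].traintest_ids)
            res = consistent_feature_model(
                fused_X.loc[tt], y[tt], consistent[mod],
                model_spec="random-forest", N=config.N, K=config.K,
                seed=stage_seed(config.master_seed, f"consistent-{mod}-{r}"),
                leakage_mode=config.leakage_mode)
            pooled.append(res)
        rmse = np.concatenate([p.rmse for p in pooled])
        pear = np.concatenate([p.pearson for p in pooled])
        spear = np.concatenate([p.spearman for p in pooled])
        consistent_summaries[mod] = {
            "features": list(consistent[mod]),
            "rmse_mean": float(rmse.mean()),
            "rmse_sd": float(rmse.std(ddof=1)),
            "pearson_mean": float(np.nanmean(pear)),
            "spearman_mean": float(np.nanmean(spear)),
        }

    tt0 = list(runs[0]["plan"].traintest_ids)
    g4 = list(groups_per_run[0][4].members)
    perm = permutation_null(fused_X.loc[tt0, g4], y[tt0], "random-forest",
                            N=config.N, K=config.K, n_perm=config.n_perm,
                            seed=stage_seed(config.master_seed, "permutation"),
                            group_id=4, leakage_mode=config.leakage_mode)

    recovery = {
        mod: [sorted(set(recovered_markers(rk.top(config.top_k), config.spec)))
              for rk in rankings[mod]]
        for mod in ("eeg", "mri", "fused")
    }

    bundle = {
        "config_hash": key,
        "n_subjects": len(ids),
        "ranker": config.ranker,
        "cv": cv_summaries,
        "stability": {mod: stability[mod].to_dict(orient="list")
                      for mod in stability},
        "consistent_models": consistent_summaries,
        "permutation_group4": perm.summary,
        "planted_recovery": recovery,
        "runs": [{
            "selection_ids": list(run["plan"].selection_ids),
            "traintest_ids": list(run["plan"].traintest_ids),
            "groups": {gid: list(g.members)
                       for gid, g in groups_per_run[r].items()},
        } for r, run in enumerate(runs)],
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with (out / "results_bundle.json").open("w") as fh:
            json.dump(bundle, fh, indent=2)
    return bundle
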