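"""Partitioning, scaling, repeated cross-validated regression and the
permutation null.

The evaluation design mirrors the study protocol: ~25% of subjects are set
aside (MMSE-stratified) exclusively for feature selection; the remaining ~75%
are evaluated with N-times-repeated K-fold cross-validation (RMSE plus
Pearson/Spearman of predicted vs. observed MMSE per held-out fold), and
significance is assessed by comparing the true-label RMSE distribution with
that of models trained on permuted labels (two-tailed two-sample t-test).

Max-abs feature scaling is fitted inside each training fold by default
(leakage-safe); ``leakage_mode="pre"`` reproduces the alternative of scaling
the full matrix before splitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold
from sklearn.neighbors import KNeighborsRegressor
from sklearn.svm import SVR

MODEL_SPECS = ("svm-linear", "svm-rbf", "random-forest", "knn")


@dataclass(frozen=True)
class PartitionPlan:
    selection_ids: tuple[str, ...]
    traintest_ids: tuple[str, ...]
    run_id: int
    seed: int

    def __post_init__(self) -> None:
        if set(self.selection_ids) & set(self.traintest_ids):
            raise ValueError("selection and train/test sides overlap")


@dataclass
class CVResult:
    model: str
    group_id: int | None
    rmse: np.ndarray       # N*K values
    pearson: np.ndarray    # N*K values, NaN where undefined
    spearman: np.ndarray

    @property
    def summary(self) -> dict[str, float]:
        return {
            "rmse_mean": float(np.mean(self.rmse)),
            "rmse_sd": float(np.std(self.rmse, ddof=1)),
            "pearson_mean": float(np.nanmean(self.pearson)),
            "pearson_sd": float(np.nanstd(self.pearson, ddof=1)),
            "spearman_mean": float(np.nanmean(self.spearman)),
            "spearman_sd": float(np.nanstd(self.spearman, ddof=1)),
            "n_trials": int(self.rmse.size),
        }


def stratified_partition(subject_ids, mmse, frac: float = 0.25, seed: int = 0,
                         run_id: int = 0) -> PartitionPlan:
    """MMSE-stratified split into selection (~frac) and train/test sides.

    Per-stratum allocation uses largest-remainder rounding of ``frac`` with a
    selection-side total of ``round(frac * n)``; a stratum with a single
    subject always lands on the train/test side.  Deterministic given seed.
    """
    if not (0.0 < frac < 1.0):
        raise ValueError("frac must be in (0, 1)")
    subject_ids = list(subject_ids)
    mmse = np.asarray(mmse)
    if len(subject_ids) != len(mmse):
        raise ValueError("subject_ids and mmse lengths differ")
    rng = np.random.default_rng(seed)
    strata = {}
    for sid, score in zip(subject_ids, mmse):
        strata.setdefault(int(score), []).append(sid)
    eligible = {s: ids for s, ids in strata.items() if len(ids) > 1}
    singles = [ids[0] for s, ids in strata.items() if len(ids) == 1]

    target = round(frac * len(subject_ids))
    quotas = {s: frac * len(ids) for s, ids in eligible.items()}
    alloc = {s: int(np.floor(q)) for s, q in quotas.items()}
    # cap at len-1 so every stratum keeps a train/test representative
    for s in alloc:
        alloc[s] = min(alloc[s], len(eligible[s]) - 1)
    remainder_order = sorted(eligible, key=lambda s: (-(quotas[s] - alloc[s]), s))
    i = 0
    while sum(alloc.values()) < target and i < 10 * len(remainder_order):
        s = remainder_order[i % len(remainder_order)]
        if alloc[s] < len(eligible[s]) - 1:
            alloc[s] += 1
        i += 1

    selection: list[str] = []
    for s in sorted(eligible):
        ids = sorted(eligible[s])
        rng.shuffle(ids)
        selection.extend(ids[: alloc[s]])
    sel = set(selection)
    traintest = [sid for sid in subject_ids if sid not in sel]
    return PartitionPlan(tuple(sorted(selection)), tuple(traintest), run_id, seed)


def maxabs_scale(train_X: np.ndarray, apply_X: np.ndarray | None = None
                 ) -> tuple[np.ndarray, np.ndarray | None, np.ndarray, np.ndarray]:
    """Scale columns by the training max absolute value.

    Returns (scaled train, scaled apply, scale vector, zero-scale flags).
    Train columns land in [-1, 1]; apply columns may exceed that (allowed).
    All-zero columns pass through unscaled and are flagged.
    """
    train_X = np.asarray(train_X, dtype=float)
    if not np.isfinite(train_X).all():
        raise ValueError("non-finite entries in training matrix")
    scale = np.max(np.abs(train_X), axis=0)
    flags = scale == 0
    safe = np.where(flags, 1.0, scale)
    out_apply = None
    if apply_X is not None:
        apply_X = np.asarray(apply_X, dtype=float)
        if not np.isfinite(apply_X).all():
            raise ValueError("non-finite entries in apply matrix")
        out_apply = apply_X / safe
    return train_X / safe, out_apply, scale, flags


def build_model(model_spec: str, seed: int = 0):
    """Instantiate a regression backend with the frozen default settings."""
    if model_spec == "svm-linear":
        return SVR(kernel="linear", C=1.0)
    if model_spec == "svm-rbf":
        return SVR(kernel="rbf", C=1.0, gamma="scale")
    if model_spec == "random-forest":
        return RandomForestRegressor(n_estimators=100, random_state=seed)
    if model_spec == "knn":
        return KNeighborsRegressor(n_neighbors=5, weights="distance")
    raise ValueError(f"unknown model spec {model_spec!r}; choose from {MODEL_SPECS}")


def _trial_metrics(y_true: np.ndarray, y_pred: np.ndarray
                   ) -> tuple[float, float, float]:
    rmse = float(np.sqrt(np.mean((y_true - y_pred) ** 2)))
    if len(y_true) < 2 or np.ptp(y_true) == 0 or np.ptp(y_pred) == 0:
        return rmse, np.nan, np.nan
    pear = float(stats.pearsonr(y_true, y_pred)[0])
    spear = float(stats.spearmanr(y_true, y_pred)[0])
    return rmse, pear, spear


def repeated_cv(X, y, model_spec: str, N: int = 50, K: int = 5, seed: int = 0,
                group_id: int | None = None,
                leakage_mode: str = "fold") -> CVResult:
    """N-times repeated K-fold cross-validation.

    Per held-out fold: RMSE and predicted-vs-observed Pearson/Spearman
    (recorded as missing when undefined, e.g. a constant prediction).
    Max-abs scaling is fitted on the training fold (``leakage_mode="fold"``,
    default) or on the full matrix before splitting (``"pre"``).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.shape[0] != y.size:
        raise ValueError("X and y disagree on subject count")
    if X.shape[0] < K:
        raise ValueError(f"{X.shape[0]} subjects cannot fill {K} folds")
    if leakage_mode not in ("fold", "pre"):
        raise ValueError(f"unknown leakage_mode {leakage_mode!r}")
    if leakage_mode == "pre":
        X, _, _, _ = maxabs_scale(X)

    root = np.random.SeedSequence(seed)
    rep_seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in root.spawn(N)]
    rmse, pear, spear = [], [], []
    for rep_seed in rep_seeds:
        kf = KFold(n_splits=K, shuffle=True, random_state=rep_seed)
        for fold_i, (tr, te) in enumerate(kf.split(X)):
            if leakage_mode == "fold":
                Xtr, Xte, _, _ = maxabs_scale(X[tr], X[te])
            else:
                Xtr, Xte = X[tr], X[te]
            model = build_model(model_spec, seed=rep_seed + fold_i)
            model.fit(Xtr, y[tr])
            r, p, s = _trial_metrics(y[te], model.predict(Xte))
            rmse.append(r)
            pear.append(p)
            spear.append(s)
    return CVResult(model_spec, group_id, np.array(rmse), np.array(pear),
                    np.array(spear))


@dataclass
class PermutationReport:
    """Comparison of true-label CV error with a permuted-label null.

    Two views of the same data are reported.  ``t_trials``/``p_trials`` is
    the two-sample t-test over individual CV-trial RMSE values (the classic
    reporting convention); because trials share subjects this test is
    strongly anticonservative and can produce tiny p-values on a truly null
    dataset.  ``t_statistic``/``p_value`` treat the permutation replicate as
    the exchangeable unit: the true-label mean RMSE is located within the
    distribution of per-replicate mean RMSEs (one-sample t with n_perm - 1
    degrees of freedom, prediction-interval scaling).  The ``significant``
    verdict uses the replicate-level p-value and requires the true mean to be
    *lower* than the null mean.
    """

    true_result: CVResult
    null_rmse: np.ndarray
    perm_means: np.ndarray
    t_statistic: float
    p_value: float
    t_trials: float
    p_trials: float
    n_perm: int

    @property
    def summary(self) -> dict[str, float]:
        return {
            "true_rmse_mean": float(np.mean(self.true_result.rmse)),
            "null_rmse_mean": float(np.mean(self.null_rmse)),
            "t": self.t_statistic,
            "p": self.p_value,
            "t_trials": self.t_trials,
            "p_trials": self.p_trials,
            "n_perm": self.n_perm,
            "significant": bool(self.p_value < 0.025
                                and np.mean(self.true_result.rmse)
                                < np.mean(self.null_rmse)),
        }


def permutation_null(X, y, model_spec: str, N: int = 10, K: int = 5,
                     n_perm: int = 5, seed: int = 0,
                     group_id: int | None = None,
                     leakage_mode: str = "fold") -> PermutationReport:
    """Compare true-label CV RMSE with a permuted-label null.

    Each permutation replicate permutes the labels once, then runs the full
    N x K repeated CV; the two RMSE samples are compared with a two-tailed
    two-sample t-test.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    y = np.asarray(y, dtype=float)
    root = np.random.SeedSequence(seed)
    cv_seed, perm_stream = root.spawn(2)
    true_result = repeated_cv(X, y, model_spec,
                              N=N, K=K,
                              seed=int(cv_seed.generate_state(1)[0] % 2 ** 31),
                              group_id=group_id, leakage_mode=leakage_mode)
    null_rmse = []
    for rep in perm_stream.spawn(n_perm):
        rng = np.random.default_rng(rep)
        y_perm = rng.permutation(y)
        res = repeated_cv(X, y_perm, model_spec, N=N, K=K,
                          seed=int(rep.generate_state(1)[0] % 2 ** 31),
                          group_id=group_id, leakage_mode=leakage_mode)
        null_rmse.append(res.rmse)
    perm_means = np.array([r.mean() for r in null_rmse])
    null_rmse = np.concatenate(null_rmse)
    t_trials, p_trials = stats.ttest_ind(true_result.rmse, null_rmse)
    true_mean = float(true_result.rmse.mean())
    if n_perm >= 2 and perm_means.std(ddof=1) > 0:
        # is the true-label mean a plausible draw from the replicate means?
        se = perm_means.std(ddof=1) * np.sqrt(1.0 + 1.0 / n_perm)
        t = (true_mean - perm_means.mean()) / se
        p = float(2.0 * stats.t.sf(abs(t), df=n_perm - 1))
    else:
        t, p = np.nan, np.nan
    return PermutationReport(true_result, null_rmse, perm_means, float(t), p,
                             float(t_trials), float(p_trials), n_perm)


def consistent_feature_model(X: pd.DataFrame, y, consistent: tuple[str, ...],
                             model_spec: str = "random-forest", N: int = 10,
                             K: int = 5, seed: int = 0,
                             leakage_mode: str = "fold") -> CVResult:
    """Repeated CV on the matrix restricted to the consistently-selected set."""
    if len(consistent) == 0:
        raise ValueError("consistent feature set is empty")
    missing = [c for c in consistent if c not in X.columns]
    if missing:
        raise KeyError(f"consistent features absent from matrix: {missing}")
    return repeated_cv(X.loc[:, list(consistent)], y, model_spec, N=N, K=K,
                       seed=seed, leakage_mode=leakage_mode)
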