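"""Feature ranking against MMSE and top-feature grouping.

Three rankers are provided: absolute Pearson correlation, absolute Spearman
correlation, and a greedy minimum-redundancy-maximum-relevance (mRMR) scheme
for a continuous target.  The mRMR variant is the difference ("MID") form:
relevance is the univariate regression F-statistic of a feature against MMSE,
redundancy the mean absolute Pearson correlation with the already-selected
set, and each step picks ``argmax(relevance - redundancy)``.  All orderings
are deterministic, with ties broken by canonical (lexicographic) feature
name.

Groups mirror the study design: Group 1 = top-24 EEG features, Group 2 =
top-24 MRI, Group 3 = top-24 of the fused (concatenated) matrix, Group 4 =
top-12 EEG + top-12 MRI.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RankingResult:
    ranker: str
    ordered_names: tuple[str, ...]
    scores: tuple[float, ...]  # aligned with ordered_names
    run_id: int = 0

    def top(self, k: int) -> tuple[str, ...]:
        if k > len(self.ordered_names):
            raise ValueError(f"requested top-{k} of {len(self.ordered_names)} features")
        return self.ordered_names[:k]


@dataclass(frozen=True)
class FeatureGroup:
    group_id: int
    members: tuple[str, ...]


def _clean_matrix(X: pd.DataFrame) -> pd.DataFrame:
    """Drop features containing missing values (logged), keep the rest."""
    bad = X.columns[X.isna().any(axis=0)]
    if len(bad):
        log.warning("excluding %d feature(s) with missing values from ranking: %s",
                    len(bad), list(bad[:5]))
        X = X.drop(columns=bad)
    if not np.isfinite(X.to_numpy()).all():
        raise ValueError("feature matrix contains non-finite values")
    return X


def _pearson_to_target(A: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Columnwise Pearson r against y; constant columns get r = 0."""
    Ac = A - A.mean(axis=0)
    yc = y - y.mean()
    denom = np.sqrt((Ac ** 2).sum(axis=0) * (yc ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Ac * yc[:, None]).sum(axis=0) / denom
    return np.where(denom > 0, r, 0.0)


def _order(names: np.ndarray, scores: np.ndarray) -> np.ndarray:
    """Descending by score, ties broken by ascending name."""
    return np.lexsort((names, -scores))


def rank_correlation(X: pd.DataFrame, y, method: str = "pearson",
                     run_id: int = 0) -> RankingResult:
    """Rank features by absolute Pearson or Spearman correlation with MMSE."""
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation method {method!r}")
    X = _clean_matrix(X)
    y = np.asarray(y, dtype=float)
    if len(y) < 3:
        raise ValueError("need at least 3 subjects to rank")
    if np.ptp(y) == 0:
        raise ValueError("target is constant; correlations undefined")
    A = X.to_numpy(dtype=float)
    if method == "spearman":
        A = stats.rankdata(A, axis=0)
        y = stats.rankdata(y)
    score = np.abs(_pearson_to_target(A, y))
    names = X.columns.to_numpy(dtype=object)
    idx = _order(names, score)
    return RankingResult(method, tuple(names[idx]), tuple(score[idx]), run_id)


def relevance_f_statistic(X: pd.DataFrame, y) -> pd.Series:
    """Univariate linear-regression F-statistic per feature (constant -> 0)."""
    y = np.asarray(y, dtype=float)
    r = _pearson_to_target(X.to_numpy(dtype=float), y)
    n = len(y)
    with np.errstate(divide="ignore"):
        f = r ** 2 / np.maximum(1.0 - r ** 2, 1e-300) * (n - 2)
    return pd.Series(f, index=X.columns)


def rank_mrmr(X: pd.DataFrame, y, k: int, run_id: int = 0) -> RankingResult:
    """Greedy mRMR (difference scheme) ranking of the top ``k`` features.

    Relevance is the univariate regression F-statistic expressed on the
    correlation scale (``|r| = sqrt(F / (F + n - 2))``, a monotone transform,
    so the first pick is exactly the top-F feature); redundancy is the mean
    absolute Pearson correlation with the already-selected set.  Putting both
    terms on the same [0, 1] scale is what lets redundancy actually demote a
    near-duplicate of an already-selected feature -- with raw F values the
    subtraction would be vacuous.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    X = _clean_matrix(X)
    if k > X.shape[1]:
        raise ValueError(f"k={k} exceeds {X.shape[1]} usable features")
    y = np.asarray(y, dtype=float)
    if np.ptp(y) == 0:
        raise ValueError("target is constant; relevance undefined")

    names = X.columns.to_numpy(dtype=object)
    A = X.to_numpy(dtype=float)
    sd = A.std(axis=0)
    Z = (A - A.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    Z[:, sd == 0] = 0.0
    n = A.shape[0]

    relevance = np.abs(_pearson_to_target(A, y))
    selected: list[int] = []
    redundancy_sum = np.zeros(A.shape[1])
    candidates = np.ones(A.shape[1], dtype=bool)
    scores: list[float] = []
    for step in range(k):
        if step == 0:
            crit = relevance.copy()
        else:
            crit = relevance - redundancy_sum / step
        crit = np.where(candidates, crit, -np.inf)
        idx = _order(names, crit)[0]
        selected.append(idx)
        scores.append(float(crit[idx]))
        candidates[idx] = False
        redundancy_sum += np.abs(Z.T @ Z[:, idx]) / n
    return RankingResult("mrmr", tuple(names[selected]), tuple(scores), run_id)


def build_groups(eeg_rank: RankingResult, mri_rank: RankingResult,
                 fused_rank: RankingResult, top_k: int = 24,
                 half_k: int = 12) -> dict[int, FeatureGroup]:
    """The four study feature groups from per-modality and fused rankings."""
    g4 = eeg_rank.top(half_k) + mri_rank.top(half_k)
    if len(set(g4)) != len(g4):
        raise ValueError("EEG and MRI rankings share feature names")
    return {
        1: FeatureGroup(1, eeg_rank.top(top_k)),
        2: FeatureGroup(2, mri_rank.top(top_k)),
        3: FeatureGroup(3, fused_rank.top(top_k)),
        4: FeatureGroup(4, g4),
    }


def stability_report(rankings: list[RankingResult], top_k: int = 24,
                     min_count: int = 2) -> pd.DataFrame:
    """Selection counts of top-``top_k`` membership across runs.

    Returns a table (feature, count, consistent) sorted by descending count
    then name; ``consistent`` marks ``count >= min_count``.
    """
    if len(rankings) < 2:
        raise ValueError("stability needs at least 2 runs")
    universe = set(rankings[0].ordered_names)
    for r in rankings[1:]:
        if r.ranker == rankings[0].ranker and r.ranker != "mrmr" \
                and set(r.ordered_names) != universe:
            raise ValueError("rankings cover different feature universes")
    counts: dict[str, int] = {}
    for r in rankings:
        for name in r.top(min(top_k, len(r.ordered_names))):
            counts[name] = counts.get(name, 0) + 1
    table = pd.DataFrame(
        sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])),
        columns=["feature", "count"])
    table["consistent"] = table["count"] >= min_count
    return table


def consistent_set(report: pd.DataFrame) -> tuple[str, ...]:
    return tuple(report.loc[report["consistent"], "feature"])
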