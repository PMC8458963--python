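"""Feature ranking: correlation rankers, greedy mRMR, groups and stability."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sstats

from neurofuse.selection import (FeatureGroup, RankingResult, build_groups,
                                 consistent_set, rank_correlation, rank_mrmr,
                                 stability_report)


def brute_force_mrmr(X: pd.DataFrame, y: np.ndarray, k: int) -> list[str]:
    """Independent greedy oracle: plain loops, scipy statistics.

    Relevance: the univariate F-statistic on the correlation scale, i.e.
    sqrt(F / (F + n - 2)) == |Pearson r|; redundancy: mean |Pearson| with the
    already-selected features; step criterion relevance - redundancy; ties by
    feature name.
    """
    n = len(y)
    relevance = {}
    for c in X.columns:
        x = X[c].to_numpy()
        if np.ptp(x) == 0:
            relevance[c] = 0.0
        else:
            r = sstats.pearsonr(x, y)[0]
            f = r ** 2 / (1 - r ** 2) * (n - 2)
            relevance[c] = np.sqrt(f / (f + n - 2))
    chosen: list[str] = []
    while len(chosen) < k:
        best_name, best_score = None, None
        for c in sorted(X.columns):
            if c in chosen:
                continue
            if chosen:
                red = np.mean([abs(sstats.pearsonr(X[c], X[s])[0])
                               if np.ptp(X[c].to_numpy()) > 0
                               and np.ptp(X[s].to_numpy()) > 0 else 0.0
                               for s in chosen])
            else:
                red = 0.0
            score = relevance[c] - red
            if best_score is None or score > best_score:
                best_name, best_score = c, score
        chosen.append(best_name)
    return chosen


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


class TestCorrelationRanking:
    def test_signed_copies_of_target_outrank_noise(self, rng):
        y = rng.normal(size=30)
        X = pd.DataFrame({"plus": y, "minus": -y, "noise": rng.normal(size=30)})
        for method in ("pearson", "spearman"):
            rk = rank_correlation(X, y, method)
            assert set(rk.ordered_names[:2]) == {"minus", "plus"}
            assert rk.ordered_names[-1] == "noise"
            assert rk.scores[0] == pytest.approx(1.0)

    def test_symmetric_quadratic_blind_spot(self, rng):
        """y^2 with y symmetric about 0: both rankers score ~0 despite a
        perfect V-shaped relation -- the documented blind spot of
        correlation-based selection."""
        y = np.concatenate([-np.linspace(0.1, 2, 15), np.linspace(0.1, 2, 15)])
        X = pd.DataFrame({"vshape": y ** 2, "linear": y + rng.normal(0, 0.5, 30)})
        for method in ("pearson", "spearman"):
            rk = rank_correlation(X, y, method)
            scores = dict(zip(rk.ordered_names, rk.scores))
            assert scores["vshape"] < 0.1
            assert rk.ordered_names[0] == "linear"

    def test_constant_feature_scored_zero_and_last(self, rng):
        y = rng.normal(size=20)
        X = pd.DataFrame({"flat": np.ones(20), "ok": y + rng.normal(0, 1, 20)})
        rk = rank_correlation(X, y, "pearson")
        assert rk.ordered_names[-1] == "flat"
        assert rk.scores[-1] == 0.0

    def test_constant_target_rejected(self, rng):
        X = pd.DataFrame({"a": rng.normal(size=10)})
        with pytest.raises(ValueError, match="constant"):
            rank_correlation(X, np.ones(10), "pearson")


class TestMrmr:
    def test_duplicate_feature_demoted_by_redundancy(self, rng):
        y = rng.normal(size=40)
        f1 = y + rng.normal(0, 0.1, 40)
        g = rng.normal(size=40)
        y2 = y + 0.8 * g  # make g informative too
        X = pd.DataFrame({"f1": f1, "f2": f1.copy(), "f3": g})
        rk = rank_mrmr(X, y2, k=3)
        assert rk.ordered_names[0] in ("f1", "f2")
        assert rk.ordered_names[1] == "f3"

    def test_first_pick_is_max_relevance(self, rng):
        y = rng.normal(size=25)
        X = pd.DataFrame({f"f{i}": y * w + rng.normal(0, 1, 25)
                          for i, w in enumerate([0.2, 2.0, 0.5])})
        rk1 = rank_mrmr(X, y, k=1)
        pearson_top = rank_correlation(X, y, "pearson").ordered_names[0]
        assert rk1.ordered_names == (pearson_top,)

    def test_independent_features_follow_relevance_order(self, rng):
        weights = [1.5, 1.0, 0.6, 0.3, 0.1]
        Z = rng.normal(size=(200, 5))
        y = Z @ np.array(weights) + rng.normal(0, 0.5, 200)
        X = pd.DataFrame(Z, columns=[f"f{i}" for i in range(5)])
        rk = rank_mrmr(X, y, k=5)
        assert list(rk.ordered_names) == [f"f{i}" for i in range(5)]

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_brute_force_oracle(self, seed):
        """Vectorized greedy equals the loop-and-scipy oracle on small cases."""
        rng = np.random.default_rng(seed)
        n, p, k = 25, 12, 4
        base = rng.normal(size=(n, 3))
        X = pd.DataFrame(
            np.column_stack([base[:, rng.integers(3)] + rng.normal(0, 0.8, n)
                             for _ in range(p)]),
            columns=[f"f{i:02d}" for i in range(p)])
        y = base @ np.array([1.0, -0.7, 0.3]) + rng.normal(0, 0.5, n)
        rk = rank_mrmr(X, y, k=k)
        assert list(rk.ordered_names) == brute_force_mrmr(X, y, k)

    def test_subject_permutation_invariance(self, rng):
        n = 30
        X = pd.DataFrame(rng.normal(size=(n, 8)),
                         columns=[f"f{i}" for i in range(8)])
        y = X["f0"].to_numpy() + rng.normal(0, 0.5, n)
        perm = rng.permutation(n)
        rk1 = rank_mrmr(X, y, k=5)
        rk2 = rank_mrmr(X.iloc[perm].reset_index(drop=True), y[perm], k=5)
        assert rk1.ordered_names == rk2.ordered_names

    def test_invalid_k_rejected(self, rng):
        X = pd.DataFrame({"a": rng.normal(size=10)})
        with pytest.raises(ValueError):
            rank_mrmr(X, rng.normal(size=10), k=0)
        with pytest.raises(ValueError):
            rank_mrmr(X, rng.normal(size=10), k=2)


def _ranking(names, run_id=0, ranker="pearson"):
    return RankingResult(ranker, tuple(names),
                         tuple(np.linspace(1, 0, len(names))), run_id)


class TestGroupsAndStability:
    def test_group_sizes(self):
        eeg = _ranking([f"e{i}" for i in range(30)])
        mri = _ranking([f"m{i}" for i in range(30)])
        fused = _ranking([f"e{i}" for i in range(15)] + [f"m{i}" for i in range(15)])
        groups = build_groups(eeg, mri, fused)
        assert all(len(groups[g].members) == 24 for g in (1, 2, 3, 4))
        assert len(set(groups[4].members)) == 24

    def test_all_eeg_fused_top_is_allowed(self):
        eeg = _ranking([f"e{i}" for i in range(30)])
        mri = _ranking([f"m{i}" for i in range(30)])
        fused = _ranking([f"e{i}" for i in range(30)])
        groups = build_groups(eeg, mri, fused)
        assert all(m.startswith("e") for m in groups[3].members)

    def test_insufficient_ranking_depth_rejected(self):
        with pytest.raises(ValueError):
            build_groups(_ranking(["a", "b"]), _ranking([f"m{i}" for i in range(30)]),
                         _ranking([f"x{i}" for i in range(30)]))

    def test_identical_runs_give_full_counts(self):
        names = [f"f{i}" for i in range(30)]
        report = stability_report([_ranking(names, r) for r in range(5)])
        assert (report["count"] == 5).sum() == 24
        assert len(consistent_set(report)) == 24

    def test_disjoint_runs_give_empty_consistent_set(self):
        a = _ranking([f"a{i}" for i in range(24)], 0, ranker="mrmr")
        b = _ranking([f"b{i}" for i in range(24)], 1, ranker="mrmr")
        report = stability_report([a, b])
        assert len(consistent_set(report)) == 0

    def test_single_run_rejected(self):
        with pytest.raises(ValueError, match="2 runs"):
            stability_report([_ranking(["a"])])
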