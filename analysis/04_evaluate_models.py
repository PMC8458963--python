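"""Repeated cross-validated regression of MMSE on the four feature groups.

Groups: 1 = top-24 EEG, 2 = top-24 MRI, 3 = top-24 fused, 4 = top-12 EEG +
top-12 MRI (all from mRMR on the selection subjects).  Each (group, model)
cell pools 10x5 repeated-CV trials over the five partitions' train/test
subjects (features scaled by train-fold max-abs), reporting RMSE and
predicted-vs-observed correlations.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))

import numpy as np
import pandas as pd
from common import CONFIG, RESULTS, benchmark_data, ensure_dirs, partition_plans

from neurofuse.evaluate import repeated_cv
from neurofuse.pipeline import stage_seed
from neurofuse.selection import build_groups, rank_mrmr


def main() -> None:
    ensure_dirs()
    eeg, mri, fused, y = benchmark_data()
    plans = partition_plans(y)

    groups_per_run = []
    for plan in plans:
        sel = list(plan.selection_ids)
        groups_per_run.append(build_groups(
            rank_mrmr(eeg.loc[sel], y[sel], k=CONFIG.top_k, run_id=plan.run_id),
            rank_mrmr(mri.loc[sel], y[sel], k=CONFIG.top_k, run_id=plan.run_id),
            rank_mrmr(fused.loc[sel], y[sel], k=CONFIG.top_k, run_id=plan.run_id),
            top_k=CONFIG.top_k, half_k=CONFIG.half_k))

    rows = []
    for gid in (1, 2, 3, 4):
        for model in CONFIG.models:
            rmse, pear, spear = [], [], []
            for plan, groups in zip(plans, groups_per_run):
                tt = list(plan.traintest_ids)
                res = repeated_cv(
                    fused.loc[tt, list(groups[gid].members)], y[tt], model,
                    N=CONFIG.N, K=CONFIG.K,
                    seed=stage_seed(CONFIG.master_seed,
                                    f"cv-{gid}-{model}-{plan.run_id}"),
                    group_id=gid, leakage_mode=CONFIG.leakage_mode)
                rmse.append(res.rmse)
                pear.append(res.pearson)
                spear.append(res.spearman)
            rmse = np.concatenate(rmse)
            rows.append({
                "group": gid, "model": model,
                "rmse_mean": rmse.mean(), "rmse_sd": rmse.std(ddof=1),
                "pearson_mean": np.nanmean(np.concatenate(pear)),
                "spearman_mean": np.nanmean(np.concatenate(spear)),
                "n_trials": rmse.size,
            })
    table = pd.DataFrame(rows)
    table.to_csv(RESULTS / "cv_summary.tsv", sep="\t", index=False,
                 float_format="%.4f")
    with pd.option_context("display.width", 120):
        print(table.round(3).to_string(index=False))
    best = table.loc[table["rmse_mean"].idxmin()]
    print(f"\nbest cell: group {int(best['group'])} / {best['model']} "
          f"(RMSE {best['rmse_mean']:.3f} +/- {best['rmse_sd']:.3f})")
    print(f"table -> {RESULTS / 'cv_summary.tsv'}")


if __name__ == "__main__":
    main()
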