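#!/usr/bin/env python
"""Covariate-adjusted CCA with permutation validation.

Exposure block residualized for IMD, brain block for PMA at scan, GA at
birth and sex; 1000 permutations of the block correspondence per window.
Whole-pregnancy first, then the three seasonally adjusted trimester windows
(where the planted whole-pregnancy signal is expected to be diluted).
"""

import pandas as pd

from airbrain import run_full_cca
from airbrain.pipeline import _write

SEED = 2026
summary = pd.read_csv("results/cohort_summary.csv", dtype={"subject_id": str})

for window in ("whole_pregnancy", "t1", "t2", "t3"):
    analysis = run_full_cca(summary, window=window, B=1000, seed=SEED)
    _write(analysis.null.to_frame(), "results", f"cca_modes_{window}.csv")
    for k, (lx, ly) in analysis.loadings.items():
        _write(lx, "results", f"cca_loadings_{window}_mode{k}_exposure.csv")
        _write(ly, "results", f"cca_loadings_{window}_mode{k}_brain.csv")
    scores = pd.DataFrame({"subject_id": analysis.blocks.subject_ids})
    for k in range(analysis.result.K):
        scores[f"U{k + 1}"] = analysis.result.scores_x[:, k]
        scores[f"V{k + 1}"] = analysis.result.scores_y[:, k]
    _write(scores, "results", f"cca_scores_{window}.csv")

    print(f"\n[{window}] n={analysis.n}")
    for k in range(analysis.result.K):
        status = "PASS" if analysis.null.passed[k] else "fail"
        print(
            f"  mode {k + 1}: r={analysis.result.canonical_corr[k]:.3f} "
            f"spearman={analysis.null.observed[k]:.3f} "
            f"null_p95={analysis.null.p95[k]:.3f} "
            f"p={analysis.null.p_empirical[k]:.4f} [{status}]"
        )
    for k, (lx, ly) in analysis.loadings.items():
        top = ly.reindex(ly.spearman_r.abs().sort_values(ascending=False).index)
        print(f"  mode {k} exposure loadings: "
              + ", ".join(f"{r.variable}={r.spearman_r:+.2f}"
                          for r in lx.itertuples()))
        print(f"  mode {k} top brain loadings: "
              + ", ".join(f"{r.variable}={r.spearman_r:+.2f}"
                          for r in top.head(3).itertuples()))

print("\nwrote results/cca_modes_*.csv, loadings and scores tables")
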