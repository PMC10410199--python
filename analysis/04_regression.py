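#!/usr/bin/env python
"""Single-pollutant regressions of relative volumes on exposure.

24 OLS models (8 regions x 3 pollutants), each adjusted for PMA at scan,
GA at birth, sex and IMD quintile; Benjamini-Hochberg FDR across the
whole-pregnancy family. The planted signal is a diffuse multivariate mode,
so single-pollutant slopes are expected to be weak — the multivariate CCA
(05) is the tool that detects it.
"""

import pandas as pd

from airbrain import run_regression_table
from airbrain.pipeline import _write

summary = pd.read_csv("results/cohort_summary.csv", dtype={"subject_id": str})
table = run_regression_table(summary, window="whole_pregnancy")
_write(table, "results", "regression_whole_pregnancy.csv")

print("single-pollutant models, whole pregnancy (24 tests, joint FDR):")
print(f"  min raw p: {table.p.min():.4f}  min FDR p: {table.p_fdr.min():.4f}")
sig = table[table.p_fdr < 0.05]
if len(sig):
    print(sig.to_string(index=False))
else:
    print("  no association survives FDR correction")
print("wrote results/regression_whole_pregnancy.csv")
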