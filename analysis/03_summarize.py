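#!/usr/bin/env python
"""Build the per-subject analysis table.

ICV-relative regional volumes; whole-pregnancy and per-trimester exposure
means; trimester means seasonally adjusted against the cohort's own
week-of-year climatology. Also writes median/range descriptive tables.
"""

from airbrain import read_cohort, summarize_cohort
from airbrain.pipeline import _write, descriptive_tables, normality_checks

filtered = read_cohort("results/cohort_filtered")
summary = summarize_cohort(filtered)
_write(summary, "results", "cohort_summary.csv")
tables = descriptive_tables(summary)
for name, table in tables.items():
    _write(table, "results", f"{name}.csv")
_write(normality_checks(summary), "results", "normality.csv")

print(f"analysis table: {len(summary)} subjects x {summary.shape[1]} columns")
print("\ndemographics:")
for _, row in tables["descriptives"].iterrows():
    print(f"  {row.statistic}: {row.value}")
print("\nwhole-pregnancy exposure (median, range, ug/m3):")
expo = tables["exposure_summary"]
for _, row in expo[expo.window == "whole_pregnancy"].iterrows():
    print(f"  {row.pollutant}: {row.median_range}")
print("\nwrote results/cohort_summary.csv and descriptive tables")
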