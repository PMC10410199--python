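#!/usr/bin/env python
"""Apply the exclusion cascade to the raw cohort.

Sequential rules: maternal smoking, gestational age at birth <= 36 or >= 44
weeks, major focal lesion, dropped twin, residence outside the exposure
model domain. Writes the filtered cohort and the audit trail.
"""

from airbrain import apply_exclusions, read_cohort, write_cohort
from airbrain.pipeline import _write

cohort = read_cohort("results/cohort_raw")
filtered, audit = apply_exclusions(cohort)
write_cohort(filtered, "results/cohort_filtered")
_write(audit.to_frame(), "results", "exclusion_audit.csv")

print(f"enrolled: {audit.initial_n}")
for rule, count in audit.excluded.items():
    print(f"  excluded ({rule}): {count}")
print(f"final analysis sample: {audit.final_n}")
print("wrote results/cohort_filtered/ and results/exclusion_audit.csv")
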