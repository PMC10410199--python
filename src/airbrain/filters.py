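"""Sequential exclusion cascade with an auditable count trail.

Rules are applied in a fixed order — maternal smoking, gestational age at
birth out of range, major focal lesion, dropped member of a multiple
pregnancy, residence outside the exposure-model domain — and each rule's
count is the number of subjects it removes among those still remaining, so
a subject meeting several criteria is counted once, under the first.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import FLAG_COLUMNS, Cohort

#: Gestational-age bounds (weeks): excluded if ga_birth <= 36 or >= 44.
GA_LOW, GA_HIGH = 36.0, 44.0

RULES = ("smoking", "ga_out_of_range", "lesion", "twin_drop", "outside_domain")


@dataclass
class ExclusionAudit:
    """Counts of the sequential exclusion cascade."""

    initial_n: int
    excluded: dict[str, int]
    final_n: int

    def to_frame(self) -> pd.DataFrame:
        rows = [("initial", self.initial_n)]
        rows += [(f"excluded_{rule}", self.excluded[rule]) for rule in RULES]
        rows.append(("final", self.final_n))
        return pd.DataFrame(rows, columns=["stage", "n"])


def _rule_mask(subjects: pd.DataFrame, rule: str) -> np.ndarray:
    if rule == "ga_out_of_range":
        ga = subjects["ga_birth"].to_numpy(dtype=float)
        return (ga <= GA_LOW) | (ga >= GA_HIGH)
    return subjects[f"flag_{rule}"].to_numpy(dtype=bool)


def apply_exclusions(cohort: Cohort) -> tuple[Cohort, ExclusionAudit]:
    """Apply the cascade; return the filtered cohort and its audit trail."""
    subjects = cohort.subjects
    missing = [c for c in FLAG_COLUMNS if c not in subjects.columns]
    if missing:
        raise ValueError(f"missing flag column(s): {', '.join(missing)}")
    for col in FLAG_COLUMNS:
        if not subjects[col].isin([True, False]).all():
            raise ValueError(f"flag column {col!r} contains non-boolean values")

    remaining = np.ones(len(subjects), dtype=bool)
    excluded: dict[str, int] = {}
    for rule in RULES:
        hits = _rule_mask(subjects, rule) & remaining
        excluded[rule] = int(hits.sum())
        remaining &= ~hits

    audit = ExclusionAudit(
        initial_n=len(subjects),
        excluded=excluded,
        final_n=int(remaining.sum()),
    )
    filtered = cohort.subset(subjects.loc[remaining, "subject_id"])
    return filtered, audit
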