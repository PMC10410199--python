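"""Cohort container and delimited-text persistence.

A cohort is three aligned tables: per-subject demographics and exclusion
flags, per-subject absolute brain volumes (mm3), and a long-format table of
weekly pollutant concentrations (ug/m3) indexed from conception week 0.
Floats are written with 17 significant digits so a write/read round trip is
lossless.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import POLLUTANTS, REGIONS

FLAG_COLUMNS = (
    "flag_smoking",
    "flag_ga_out_of_range",
    "flag_lesion",
    "flag_twin_drop",
    "flag_outside_domain",
)

SUBJECT_COLUMNS = (
    "subject_id",
    "ga_birth",
    "pma_scan",
    "sex",
    "imd_quintile",
    "birth_date",
) + FLAG_COLUMNS

VOLUME_COLUMNS = ("subject_id", "icv", "tbv") + REGIONS

EXPOSURE_COLUMNS = ("subject_id", "week_index", "pollutant", "concentration")

_FLOAT_FMT = "%.17g"


class CohortParseError(ValueError):
    """A cohort file is malformed; the message names the file/row/column."""


@dataclass
class Cohort:
    """Aligned per-subject tables: demographics+flags, volumes, exposures."""

    subjects: pd.DataFrame
    volumes: pd.DataFrame
    exposures: pd.DataFrame

    @property
    def n(self) -> int:
        return len(self.subjects)

    def subset(self, subject_ids) -> "Cohort":
        ids = pd.Index(subject_ids)
        return Cohort(
            subjects=self.subjects[self.subjects.subject_id.isin(ids)].reset_index(
                drop=True
            ),
            volumes=self.volumes[self.volumes.subject_id.isin(ids)].reset_index(
                drop=True
            ),
            exposures=self.exposures[
                self.exposures.subject_id.isin(ids)
            ].reset_index(drop=True),
        )


def _check_columns(df: pd.DataFrame, required, path: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise CohortParseError(
            f"{path}: missing required column(s) {', '.join(missing)}"
        )


def write_cohort(cohort: Cohort, path: str) -> None:
    """Write the three cohort CSVs under directory ``path``."""
    os.makedirs(path, exist_ok=True)
    cohort.subjects.to_csv(
        os.path.join(path, "subjects.csv"), index=False, float_format=_FLOAT_FMT
    )
    cohort.volumes.to_csv(
        os.path.join(path, "volumes.csv"), index=False, float_format=_FLOAT_FMT
    )
    cohort.exposures.to_csv(
        os.path.join(path, "exposures.csv"), index=False, float_format=_FLOAT_FMT
    )


def read_cohort(path: str) -> Cohort:
    """Read a cohort previously written by :func:`write_cohort`."""
    sub_path = os.path.join(path, "subjects.csv")
    vol_path = os.path.join(path, "volumes.csv")
    exp_path = os.path.join(path, "exposures.csv")

    subjects = pd.read_csv(sub_path, dtype={"subject_id": str})
    _check_columns(subjects, SUBJECT_COLUMNS, sub_path)
    for col in FLAG_COLUMNS:
        # a single malformed entry makes pandas read the whole column as
        # strings, so accept "True"/"False" spellings before validating
        mapped = subjects[col].map(
            {True: True, False: False, "True": True, "False": False}
        )
        bad = mapped.isna() & subjects[col].notna()
        if bad.any() or subjects[col].isna().any():
            bad = bad | subjects[col].isna()
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise CohortParseError(
                f"{sub_path}: row {row}, column {col!r}: not a boolean"
            )
        subjects[col] = mapped.astype(bool)
    bad_sex = ~subjects["sex"].isin(["male", "female"]) & subjects["sex"].notna()
    if len(subjects) and bad_sex.any():
        row = int(np.flatnonzero(bad_sex.to_numpy())[0])
        raise CohortParseError(
            f"{sub_path}: row {row}, column 'sex': expected 'male' or 'female'"
        )

    volumes = pd.read_csv(vol_path, dtype={"subject_id": str})
    _check_columns(volumes, VOLUME_COLUMNS, vol_path)

    exposures = pd.read_csv(
        exp_path, dtype={"subject_id": str, "pollutant": str}
    )
    _check_columns(exposures, EXPOSURE_COLUMNS, exp_path)
    if len(exposures):
        bad_poll = ~exposures["pollutant"].isin(POLLUTANTS)
        if bad_poll.any():
            row = int(np.flatnonzero(bad_poll.to_numpy())[0])
            raise CohortParseError(
                f"{exp_path}: row {row}, column 'pollutant': unknown label "
                f"{exposures['pollutant'].iloc[row]!r}"
            )
        exposures["week_index"] = exposures["week_index"].astype(int)

    return Cohort(subjects=subjects, volumes=volumes, exposures=exposures)
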