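"""Gestational exposure windowing and seasonal adjustment.

Weekly pollutant concentrations are indexed from conception (week 0) to
birth. The whole-pregnancy summary is the unweighted mean of the weekly
values; trimesters are cut at the end of gestational weeks 13 and 26, with
the third trimester running to birth. Trimester means are additionally
adjusted for seasonality — short windows sample the annual pollution cycle
unevenly — by subtracting the anomaly of a network-wide reference series
over the same calendar window relative to the 52 weeks centred on it. The
reference is kept as a cyclic 52-bin week-of-year climatology, so the
centred 52-week mean is the annual mean and the adjustment is defined for
any window.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import POLLUTANTS, REGIONS
from .io import Cohort
from .volumetrics import relative_volumes

#: First week index of the second and third trimesters (cut points at the
#: end of gestational weeks 13 and 26).
T2_START, T3_START = 14, 27

WINDOW_COLUMNS = ["whole_pregnancy", "t1", "t2", "t3"]


class CoverageError(ValueError):
    """An exposure or reference series does not cover the required window."""


def weeks_of_year(birth_date: dt.date, ga_birth: float, n_weeks: int) -> np.ndarray:
    """Cyclic week-of-year bin (0-51) for each gestation week.

    Week 0 starts at the estimated conception date, ``birth_date`` minus
    ``ga_birth`` weeks.
    """
    conception = birth_date - dt.timedelta(days=round(float(ga_birth) * 7))
    doy0 = conception.timetuple().tm_yday
    return ((doy0 + 7 * np.arange(n_weeks)) // 7) % 52


@dataclass
class ExposureSummary:
    """Windowed exposure means (ug/m3) for one subject and one pollutant."""

    whole_pregnancy: float
    t1: float
    t2: float
    t3: float

    def as_dict(self) -> dict[str, float]:
        return {
            "whole_pregnancy": self.whole_pregnancy,
            "t1": self.t1,
            "t2": self.t2,
            "t3": self.t3,
        }


def window_exposure(series: np.ndarray, ga_birth: float) -> ExposureSummary:
    """Whole-pregnancy and per-trimester means of one weekly series.

    ``series[w]`` is the concentration in gestation week ``w`` (week 0 =
    conception); the series must cover conception to birth, i.e. have at
    least ``ceil(ga_birth)`` entries.
    """
    series = np.asarray(series, dtype=float)
    n_weeks = int(np.ceil(ga_birth))
    if series.ndim != 1 or len(series) < n_weeks:
        raise CoverageError(
            f"series has {len(series)} weeks but gestation spans {n_weeks}"
        )
    series = series[:n_weeks]

    def _mean(chunk: np.ndarray) -> float:
        return float(chunk.mean()) if len(chunk) else float("nan")

    return ExposureSummary(
        whole_pregnancy=_mean(series),
        t1=_mean(series[:T2_START]),
        t2=_mean(series[T2_START:T3_START]),
        t3=_mean(series[T3_START:]),
    )


def seasonal_adjustment(
    raw_mean: float, reference: np.ndarray, window_bins: np.ndarray
) -> float:
    """Subtract the reference anomaly of the window from a raw window mean.

    ``reference`` is a cyclic 52-bin week-of-year climatology; the anomaly is
    the reference mean over ``window_bins`` minus the reference mean over the
    52 weeks centred on the window (the annual mean, for a cyclic series).
    """
    reference = np.asarray(reference, dtype=float)
    if reference.shape != (52,):
        raise ValueError("reference must be a 52-bin week-of-year series")
    window_bins = np.asarray(window_bins, dtype=int)
    if np.isnan(reference[window_bins]).any() or np.isnan(reference).any():
        raise CoverageError("reference series has a coverage gap")
    anomaly = reference[window_bins].mean() - reference.mean()
    return float(raw_mean - anomaly)


def build_reference_series(cohort: Cohort) -> pd.DataFrame:
    """Network-wide weekly-mean climatology, one 52-bin column per pollutant.

    Every subject-week observation is assigned to its week-of-year bin and
    averaged across the cohort.
    """
    subjects = cohort.subjects.set_index("subject_id")
    sums = np.zeros((52, len(POLLUTANTS)))
    counts = np.zeros((52, len(POLLUTANTS)))
    for (sid, pol), grp in cohort.exposures.groupby(
        ["subject_id", "pollutant"], sort=True
    ):
        row = subjects.loc[sid]
        grp = grp.sort_values("week_index")
        bins = weeks_of_year(
            dt.date.fromisoformat(str(row["birth_date"])),
            float(row["ga_birth"]),
            len(grp),
        )
        j = POLLUTANTS.index(pol)
        np.add.at(sums[:, j], bins, grp["concentration"].to_numpy())
        np.add.at(counts[:, j], bins, 1.0)
    with np.errstate(invalid="ignore"):
        clim = sums / counts
    return pd.DataFrame(clim, columns=list(POLLUTANTS))


def summarize_cohort(
    cohort: Cohort,
    denominator: str = "icv",
    reference: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-subject analysis table: covariates, relative volumes, exposures.

    Produces one row per subject with demographic covariates, ``rel_<region>``
    relative volumes, ``<pollutant>_<window>`` raw window means and
    ``<pollutant>_<trimester>_adj`` seasonally adjusted trimester means.
    ``reference`` defaults to the climatology of the cohort itself.
    """
    if reference is None:
        reference = build_reference_series(cohort)

    vols = relative_volumes(cohort.volumes, denominator=denominator)
    rel_cols = [f"rel_{r}" for r in REGIONS]
    base = cohort.subjects[
        ["subject_id", "ga_birth", "pma_scan", "sex", "imd_quintile", "birth_date"]
    ].merge(vols[["subject_id"] + rel_cols], on="subject_id", validate="1:1")

    series_map: dict[tuple[str, str], np.ndarray] = {
        key: grp.sort_values("week_index")["concentration"].to_numpy()
        for key, grp in cohort.exposures.groupby(
            ["subject_id", "pollutant"], sort=True
        )
    }

    rows = []
    for rec in base.itertuples(index=False):
        ga = float(rec.ga_birth)
        n_weeks = int(np.ceil(ga))
        bdate = dt.date.fromisoformat(str(rec.birth_date))
        bins = weeks_of_year(bdate, ga, n_weeks)
        out: dict[str, float] = {}
        for pol in POLLUTANTS:
            series = series_map.get((rec.subject_id, pol))
            if series is None:
                raise CoverageError(
                    f"subject {rec.subject_id}: no {pol} exposure series"
                )
            summ = window_exposure(series, ga)
            out[f"{pol}_whole_pregnancy"] = summ.whole_pregnancy
            out[f"{pol}_t1"] = summ.t1
            out[f"{pol}_t2"] = summ.t2
            out[f"{pol}_t3"] = summ.t3
            ref = reference[pol].to_numpy()
            for name, raw, sl in (
                ("t1", summ.t1, slice(0, T2_START)),
                ("t2", summ.t2, slice(T2_START, T3_START)),
                ("t3", summ.t3, slice(T3_START, n_weeks)),
            ):
                window_bins = bins[sl]
                out[f"{pol}_{name}_adj"] = (
                    seasonal_adjustment(raw, ref, window_bins)
                    if len(window_bins)
                    else float("nan")
                )
        rows.append(out)

    return pd.concat([base, pd.DataFrame(rows, index=base.index)], axis=1)
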