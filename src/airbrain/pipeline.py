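"""End-to-end pipeline: simulate -> filter -> summarize -> regress -> CCA.

Every stage writes plain CSV tables under the configured output directory;
the run log records the seed, package version and every setting in effect,
so each emitted number is reproducible from the persisted config alone.
"""

from __future__ import annotations

import json
import os

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__
from .cca import run_full_cca
from .config import POLLUTANTS, REGIONS, PipelineConfig
from .exposure import summarize_cohort
from .filters import apply_exclusions
from .io import Cohort, read_cohort, write_cohort
from .regression import run_regression_table
from .simulate import simulate_cohort

_FLOAT_FMT = "%.10g"


class PipelineStageError(RuntimeError):
    """A stage failed; outputs up to that stage were persisted."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def _median_range(x) -> str:
    x = np.asarray(x, dtype=float)
    return f"{np.median(x):.6g} ({np.min(x):.6g} - {np.max(x):.6g})"


def _write(df: pd.DataFrame, outdir: str, name: str) -> None:
    df.to_csv(os.path.join(outdir, name), index=False, float_format=_FLOAT_FMT)


def descriptive_tables(summary: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Median/range descriptive tables for demographics, exposure, volumes."""
    demo = pd.DataFrame(
        [
            ("n", str(len(summary))),
            ("pma_scan_weeks", _median_range(summary["pma_scan"])),
            ("ga_birth_weeks", _median_range(summary["ga_birth"])),
            ("n_male", str(int((summary["sex"] == "male").sum()))),
            ("n_female", str(int((summary["sex"] == "female").sum()))),
            ("imd_quintile", _median_range(summary["imd_quintile"])),
        ],
        columns=["statistic", "value"],
    )
    expo_rows = []
    for pol in POLLUTANTS:
        for window in ("t1", "t2", "t3", "whole_pregnancy"):
            col = (
                f"{pol}_whole_pregnancy"
                if window == "whole_pregnancy"
                else f"{pol}_{window}"
            )
            expo_rows.append((pol, window, _median_range(summary[col].dropna())))
    expo = pd.DataFrame(expo_rows, columns=["pollutant", "window", "median_range"])
    vol_rows = [
        (f"rel_{region}", _median_range(summary[f"rel_{region}"]))
        for region in REGIONS
    ]
    vols = pd.DataFrame(vol_rows, columns=["volume", "median_range"])
    return {"descriptives": demo, "exposure_summary": expo, "volume_summary": vols}


def normality_checks(summary: pd.DataFrame) -> pd.DataFrame:
    """Shapiro-Wilk statistics per analysis variable (logged, not branching)."""
    rows = []
    cols = [f"rel_{r}" for r in REGIONS] + [
        f"{p}_whole_pregnancy" for p in POLLUTANTS
    ]
    for col in cols:
        x = summary[col].dropna().to_numpy()
        res = stats.shapiro(x)
        rows.append((col, float(res.statistic), float(res.pvalue)))
    return pd.DataFrame(rows, columns=["variable", "shapiro_w", "p"])


def run_pipeline(
    config: PipelineConfig,
    cohort: Cohort | None = None,
) -> dict:
    """Run the full pipeline, writing a report bundle under config.outdir.

    Returns a dict with the in-memory artefacts (audit, summary, regression
    tables, CCA analyses) for programmatic use.
    """
    config.validate()
    outdir = config.outdir
    os.makedirs(outdir, exist_ok=True)
    artefacts: dict = {}
    stage = "setup"
    try:
        stage = "simulate"
        if cohort is None:
            cohort = simulate_cohort(config.simulation)
        write_cohort(cohort, os.path.join(outdir, "cohort_raw"))

        stage = "filter"
        filtered, audit = apply_exclusions(cohort)
        _write(audit.to_frame(), outdir, "exclusion_audit.csv")
        artefacts["audit"] = audit

        stage = "summarize"
        summary = summarize_cohort(
            filtered, denominator=config.analysis.volume_denominator
        )
        _write(summary, outdir, "cohort_summary.csv")
        artefacts["summary"] = summary
        if "descriptives" in config.tables:
            for name, table in descriptive_tables(summary).items():
                _write(table, outdir, f"{name}.csv")
            _write(normality_checks(summary), outdir, "normality.csv")

        stage = "regress"
        if "regression" in config.tables:
            regs = {}
            for window in config.analysis.windows:
                table = run_regression_table(
                    summary,
                    window=window,
                    imd_coding=config.analysis.imd_coding,
                )
                _write(table, outdir, f"regression_{window}.csv")
                regs[window] = table
            artefacts["regression"] = regs

        stage = "cca"
        if "cca" in config.tables:
            ccas = {}
            for window in config.analysis.windows:
                analysis = run_full_cca(
                    summary,
                    window=window,
                    B=config.analysis.n_permutations,
                    seed=config.analysis.seed,
                    subgroup_sex=config.analysis.subgroup_sex,
                )
                tag = window if analysis.subgroup_sex is None else (
                    f"{window}_{analysis.subgroup_sex}"
                )
                _write(analysis.null.to_frame(), outdir, f"cca_modes_{tag}.csv")
                for k, (lx, ly) in analysis.loadings.items():
                    _write(lx, outdir, f"cca_loadings_{tag}_mode{k}_exposure.csv")
                    _write(ly, outdir, f"cca_loadings_{tag}_mode{k}_brain.csv")
                scores = pd.DataFrame({"subject_id": analysis.blocks.subject_ids})
                for k in range(analysis.result.K):
                    scores[f"U{k + 1}"] = analysis.result.scores_x[:, k]
                    scores[f"V{k + 1}"] = analysis.result.scores_y[:, k]
                _write(scores, outdir, f"cca_scores_{tag}.csv")
                ccas[tag] = analysis
            artefacts["cca"] = ccas

        stage = "log"
        log = {
            "version": __version__,
            "seed": config.simulation.seed,
            "analysis_seed": config.analysis.seed,
            "settings": config.settings_in_effect(),
        }
        with open(os.path.join(outdir, "run_log.json"), "w") as fh:
            json.dump(log, fh, indent=2, sort_keys=True)
    except Exception as err:  # noqa: BLE001 - annotate the failing stage
        raise PipelineStageError(stage, err) from err
    return artefacts


__all__ = [
    "PipelineStageError",
    "descriptive_tables",
    "normality_checks",
    "run_pipeline",
    "read_cohort",
]
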