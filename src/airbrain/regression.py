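"""Single-pollutant linear regression of relative brain volumes.

One ordinary-least-squares model per (region, pollutant) pair: relative
volume on the windowed pollutant mean, adjusting for postmenstrual age at
scan, gestational age at birth, sex and deprivation quintile. The 24 tests
of a window form one family for Benjamini-Hochberg FDR adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .config import POLLUTANTS, REGIONS


@dataclass
class RegressionResult:
    region: str
    pollutant: str
    beta: float
    ci_low: float
    ci_high: float
    p: float
    p_fdr: float | None = None
    n: int = 0


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone-enforced)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _exposure_column(pollutant: str, window: str) -> str:
    if window == "whole_pregnancy":
        return f"{pollutant}_whole_pregnancy"
    return f"{pollutant}_{window}_adj"


#: Default adjustment set of the single-pollutant models.
DEFAULT_COVARIATES = ("pma_scan", "ga_birth", "sex", "imd_quintile")


def _design(
    summary: pd.DataFrame, exposure_col: str, imd_coding: str, covariates
) -> pd.DataFrame:
    X = pd.DataFrame(
        {"exposure": summary[exposure_col].to_numpy(dtype=float)}
    )
    for cov in covariates:
        if cov == "sex":
            X["sex_male"] = (summary["sex"] == "male").to_numpy(dtype=float)
        elif cov == "imd_quintile" and imd_coding == "categorical":
            q = summary["imd_quintile"].to_numpy(dtype=int)
            for level in (2, 3, 4, 5):  # quintile 1 is the reference
                X[f"imd_q{level}"] = (q == level).astype(float)
        else:
            X[cov] = summary[cov].to_numpy(dtype=float)
    return sm.add_constant(X, has_constant="add")


def fit_single_pollutant(
    summary: pd.DataFrame,
    region: str,
    pollutant: str,
    window: str = "whole_pregnancy",
    imd_coding: str = "numeric",
    covariates=DEFAULT_COVARIATES,
) -> RegressionResult:
    """OLS of one relative volume on one pollutant plus covariates.

    The confidence interval uses the t distribution with the residual
    degrees of freedom; the p-value is two-sided. ``covariates`` selects the
    adjustment set (empty for an unadjusted simple regression).
    """
    exposure_col = _exposure_column(pollutant, window)
    cols = [f"rel_{region}", exposure_col] + [
        c for c in ("pma_scan", "ga_birth", "sex", "imd_quintile")
        if c in covariates
    ]
    data = summary[cols].dropna()
    if len(data) < 10:
        raise ValueError(f"insufficient complete cases (n={len(data)} < 10)")
    y = data[f"rel_{region}"].to_numpy(dtype=float)
    X = _design(data, exposure_col, imd_coding, covariates)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    fit = sm.OLS(y, X).fit()
    ci = fit.conf_int(alpha=0.05)
    return RegressionResult(
        region=region,
        pollutant=pollutant,
        beta=float(fit.params["exposure"]),
        ci_low=float(ci.loc["exposure", 0]),
        ci_high=float(ci.loc["exposure", 1]),
        p=float(fit.pvalues["exposure"]),
        n=len(data),
    )


def run_regression_table(
    summary: pd.DataFrame,
    window: str = "whole_pregnancy",
    imd_coding: str = "numeric",
) -> pd.DataFrame:
    """All 24 (region, pollutant) models for one window, FDR-adjusted jointly."""
    results = [
        fit_single_pollutant(summary, region, pollutant, window, imd_coding)
        for region in REGIONS
        for pollutant in POLLUTANTS
    ]
    table = pd.DataFrame(
        {
            "region": [r.region for r in results],
            "pollutant": [r.pollutant for r in results],
            "beta": [r.beta for r in results],
            "ci_low": [r.ci_low for r in results],
            "ci_high": [r.ci_high for r in results],
            "p": [r.p for r in results],
        }
    )
    table["p_fdr"] = bh_fdr(table["p"])
    table.attrs["window"] = window
    table.attrs["imd_coding"] = imd_coding
    return table
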