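"""Covariate-adjusted canonical correlation analysis with permutation
validation.

The exposure block (three pollutants) is residualized for deprivation
quintile and the brain block (eight relative volumes) for postmenstrual age
at scan, gestational age at birth and sex; both are column-standardized.
CCA is solved classically: whiten each block's covariance by its Cholesky
factor and take the SVD of the whitened cross-covariance, giving
``min(p, q) = 3`` modes with non-increasing canonical correlations and
within-block uncorrelated variates.

Mode validation shuffles the subject correspondence between the blocks
(one relative row permutation per iteration), refits the CCA, and records
the Spearman correlation of each variate pair. A mode is significant when
its observed Spearman correlation exceeds the 95th percentile of its own
null distribution; empirical p-values carry the +1 correction and passing
modes are Benjamini-Hochberg adjusted. Loadings are Spearman correlations
of each adjusted variable with its own block's variate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .config import POLLUTANTS, REGIONS
from .regression import bh_fdr


class DegenerateColumnError(ValueError):
    """A residualized column has (numerically) zero variance."""


class SingularBlockError(ValueError):
    """A within-block covariance matrix is singular; regularized CCA is not
    provided."""


def _spearman(u: np.ndarray, v: np.ndarray) -> float:
    """Spearman correlation via average ranks then Pearson."""
    ru = stats.rankdata(u)
    rv = stats.rankdata(v)
    ru = ru - ru.mean()
    rv = rv - rv.mean()
    denom = np.sqrt((ru @ ru) * (rv @ rv))
    if denom == 0:
        return float("nan")
    return float((ru @ rv) / denom)


def residualize(
    values: np.ndarray, covariates: np.ndarray | None = None
) -> np.ndarray:
    """Column-wise OLS residuals (with intercept), then standardized.

    Residual columns are orthogonal to every covariate column; each output
    column has mean zero and unit sample variance (ddof=1).
    """
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    if covariates is None:
        design = np.ones((n, 1))
    else:
        covariates = np.asarray(covariates, dtype=float)
        if covariates.ndim == 1:
            covariates = covariates[:, None]
        design = np.column_stack([np.ones(n), covariates])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("covariate design matrix is rank deficient")
    coef, *_ = np.linalg.lstsq(design, values, rcond=None)
    resid = values - design @ coef
    sd = resid.std(axis=0, ddof=1)
    degenerate = np.flatnonzero(sd < 1e-12 * np.maximum(1.0, np.abs(values).max()))
    if degenerate.size:
        raise DegenerateColumnError(
            f"column(s) {degenerate.tolist()} have zero residual variance "
            "(perfectly explained by the covariates)"
        )
    return resid / sd


@dataclass
class AdjustedBlocks:
    """Residualized, standardized analysis blocks with aligned rows."""

    X: np.ndarray  # n x 3 pollutant residuals
    Y: np.ndarray  # n x 8 relative-volume residuals
    x_labels: tuple[str, ...] = POLLUTANTS
    y_labels: tuple[str, ...] = REGIONS
    subject_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.X.shape[0] != self.Y.shape[0]:
            raise ValueError("blocks must have the same number of rows")

    @property
    def n(self) -> int:
        return self.X.shape[0]


@dataclass
class CCAResult:
    weights_x: np.ndarray  # p x K
    weights_y: np.ndarray  # q x K
    canonical_corr: np.ndarray  # K, non-increasing, >= 0
    spearman_corr: np.ndarray  # K, Spearman correlation of variate pairs
    scores_x: np.ndarray  # n x K, unit sample variance
    scores_y: np.ndarray  # n x K
    x_labels: tuple[str, ...] = POLLUTANTS
    y_labels: tuple[str, ...] = REGIONS

    @property
    def K(self) -> int:
        return len(self.canonical_corr)


def fit_cca(blocks: AdjustedBlocks) -> CCAResult:
    """Classical CCA via SVD of the whitened cross-covariance.

    Deterministic; the sign of each mode is fixed by forcing the
    largest-magnitude exposure-side weight positive.
    """
    X, Y = blocks.X, blocks.Y
    n, p = X.shape
    q = Y.shape[1]
    if n <= p + q + 1:
        raise ValueError(f"need n > {p + q + 1} subjects, got {n}")
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    Sxx = (Xc.T @ Xc) / (n - 1)
    Syy = (Yc.T @ Yc) / (n - 1)
    Sxy = (Xc.T @ Yc) / (n - 1)
    try:
        Lx = np.linalg.cholesky(Sxx)
        Ly = np.linalg.cholesky(Syy)
    except np.linalg.LinAlgError as err:
        raise SingularBlockError(
            "within-block covariance is singular; drop collinear columns "
            "(regularized CCA is out of scope)"
        ) from err
    M = linalg.solve_triangular(Lx, Sxy, lower=True)
    M = linalg.solve_triangular(Ly, M.T, lower=True).T
    U, s, Vt = np.linalg.svd(M, full_matrices=False)
    K = min(p, q)
    a = linalg.solve_triangular(Lx.T, U[:, :K], lower=False)
    b = linalg.solve_triangular(Ly.T, Vt[:K].T, lower=False)
    corr = np.clip(s[:K], 0.0, 1.0)

    # sign convention: largest-magnitude exposure weight positive per mode
    for k in range(K):
        j = int(np.argmax(np.abs(a[:, k])))
        if a[j, k] < 0:
            a[:, k] *= -1.0
            b[:, k] *= -1.0

    scores_x = Xc @ a
    scores_y = Yc @ b
    # unit sample variance (a'Sxx a = 1 already; renormalize for safety)
    scores_x /= scores_x.std(axis=0, ddof=1)
    scores_y /= scores_y.std(axis=0, ddof=1)

    spearman = np.array(
        [_spearman(scores_x[:, k], scores_y[:, k]) for k in range(K)]
    )
    return CCAResult(
        weights_x=a,
        weights_y=b,
        canonical_corr=corr,
        spearman_corr=spearman,
        scores_x=scores_x,
        scores_y=scores_y,
        x_labels=blocks.x_labels,
        y_labels=blocks.y_labels,
    )


@dataclass
class PermutationNull:
    """Per-mode permutation null and significance decisions."""

    B: int
    observed: np.ndarray  # K, observed Spearman statistic per mode
    observed_pearson: np.ndarray  # K, canonical correlations (diagnostic)
    null: np.ndarray  # B x K null Spearman statistics
    p95: np.ndarray  # K, 95th percentile of each mode's null
    passed: np.ndarray  # K bool, observed > p95
    p_empirical: np.ndarray  # K, (1 + #{null >= obs}) / (B + 1)
    p_fdr: np.ndarray  # K, BH over passing modes (NaN elsewhere)
    rng_seed: int | None = None
    statistic: str = "per_mode"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "mode": np.arange(1, len(self.observed) + 1),
                "canonical_corr": self.observed_pearson,
                "spearman_corr": self.observed,
                "null_mean": self.null.mean(axis=0),
                "null_p5": np.percentile(self.null, 5, axis=0),
                "null_p95": self.p95,
                "empirical_p": self.p_empirical,
                "p_fdr": self.p_fdr,
                "pass": self.passed,
            }
        )


def permutation_test(
    blocks: AdjustedBlocks,
    B: int = 1000,
    seed: int | None = None,
    statistic: str = "per_mode",
) -> PermutationNull:
    """Permutation null for mode significance.

    Shuffling the rows of one block relative to the other breaks any true
    subject-level association while preserving each block's internal
    structure; permuting both blocks independently would yield the same null,
    so a single relative shuffle per iteration is drawn. ``statistic``
    selects per-mode comparison (default) or a max-over-modes null for
    family-wise control.
    """
    if B < 100:
        raise ValueError("B must be at least 100")
    if statistic not in ("per_mode", "max"):
        raise ValueError("statistic must be 'per_mode' or 'max'")
    rng = np.random.default_rng(seed)
    observed_fit = fit_cca(blocks)
    K = observed_fit.K
    null = np.empty((B, K))
    for b in range(B):
        perm = rng.permutation(blocks.n)
        fit = fit_cca(
            AdjustedBlocks(
                X=blocks.X[perm],
                Y=blocks.Y,
                x_labels=blocks.x_labels,
                y_labels=blocks.y_labels,
            )
        )
        null[b] = fit.spearman_corr
    if statistic == "max":
        null = np.tile(null.max(axis=1)[:, None], (1, K))
    observed = observed_fit.spearman_corr
    p95 = np.percentile(null, 95, axis=0)
    passed = observed > p95
    p_emp = (1.0 + (null >= observed[None, :]).sum(axis=0)) / (B + 1.0)
    p_fdr = np.full(K, np.nan)
    if passed.any():
        p_fdr[passed] = bh_fdr(p_emp[passed])
    return PermutationNull(
        B=B,
        observed=observed,
        observed_pearson=observed_fit.canonical_corr,
        null=null,
        p95=p95,
        passed=passed,
        p_empirical=p_emp,
        p_fdr=p_fdr,
        rng_seed=seed,
        statistic=statistic,
    )


def mode_loadings(
    block: np.ndarray, scores: np.ndarray, labels=None
) -> pd.DataFrame:
    """Spearman loading table of one block against one canonical variate.

    For each (adjusted) variable: Spearman correlation with the variate,
    its square, a two-sided p-value from the large-sample t approximation,
    and BH-FDR within the block's variable family.
    """
    block = np.asarray(block, dtype=float)
    scores = np.asarray(scores, dtype=float)
    if labels is None:
        labels = [f"var{j}" for j in range(block.shape[1])]
    rows = []
    for j, label in enumerate(labels):
        col = block[:, j]
        if np.ptp(col) == 0 or np.ptp(scores) == 0:
            raise DegenerateColumnError(
                f"variable {label!r} is constant; Spearman correlation undefined"
            )
        res = stats.spearmanr(col, scores)
        r = float(res.statistic)
        rows.append((label, r, r * r, float(res.pvalue)))
    table = pd.DataFrame(
        rows, columns=["variable", "spearman_r", "r_squared", "p"]
    )
    table["p_fdr"] = bh_fdr(table["p"])
    return table


@dataclass
class CCAAnalysis:
    """Full adjusted-CCA output for one window (and optional subgroup)."""

    window: str
    n: int
    blocks: AdjustedBlocks
    result: CCAResult
    null: PermutationNull
    #: per passing mode (1-based): (exposure loadings, brain loadings)
    loadings: dict[int, tuple[pd.DataFrame, pd.DataFrame]] = field(
        default_factory=dict
    )
    subgroup_sex: str | None = None


def build_adjusted_blocks(
    summary: pd.DataFrame, window: str = "whole_pregnancy"
) -> AdjustedBlocks:
    """Residualize and standardize the exposure and brain blocks.

    Pollutant window means (seasonally adjusted for trimester windows) are
    adjusted for deprivation quintile; relative volumes are adjusted for
    postmenstrual age at scan, gestational age at birth and sex.
    """
    if window == "whole_pregnancy":
        x_cols = [f"{p}_whole_pregnancy" for p in POLLUTANTS]
    else:
        x_cols = [f"{p}_{window}_adj" for p in POLLUTANTS]
    y_cols = [f"rel_{r}" for r in REGIONS]
    data = summary.dropna(subset=x_cols + y_cols)
    X_raw = data[x_cols].to_numpy(dtype=float)
    Y_raw = data[y_cols].to_numpy(dtype=float)
    imd = data["imd_quintile"].to_numpy(dtype=float)
    brain_cov = np.column_stack(
        [
            data["pma_scan"].to_numpy(dtype=float),
            data["ga_birth"].to_numpy(dtype=float),
            (data["sex"] == "male").to_numpy(dtype=float),
        ]
    )
    # constant covariates (e.g. sex within a sex-stratified subgroup) carry
    # no information and would duplicate the intercept
    brain_cov = brain_cov[:, np.ptp(brain_cov, axis=0) > 0]
    if np.ptp(imd) == 0:
        imd = None
    return AdjustedBlocks(
        X=residualize(X_raw, imd),
        Y=residualize(Y_raw, brain_cov),
        subject_ids=data["subject_id"].to_numpy(),
    )


def run_full_cca(
    summary: pd.DataFrame,
    window: str = "whole_pregnancy",
    B: int = 1000,
    seed: int | None = None,
    subgroup_sex: str | None = None,
    statistic: str = "per_mode",
) -> CCAAnalysis:
    """Residualize, fit, validate against the permutation null, and compute
    loading tables for every passing mode."""
    if window not in ("whole_pregnancy", "t1", "t2", "t3"):
        raise ValueError(f"unknown window {window!r}")
    if subgroup_sex is not None:
        summary = summary[summary["sex"] == subgroup_sex]
    if len(summary) < 30:
        raise ValueError(
            f"subgroup too small for CCA (n={len(summary)} < 30)"
        )
    blocks = build_adjusted_blocks(summary, window)
    null = permutation_test(blocks, B=B, seed=seed, statistic=statistic)
    result = fit_cca(blocks)
    loadings = {
        k + 1: (
            mode_loadings(blocks.X, result.scores_x[:, k], blocks.x_labels),
            mode_loadings(blocks.Y, result.scores_y[:, k], blocks.y_labels),
        )
        for k in range(result.K)
        if null.passed[k]
    }
    return CCAAnalysis(
        window=window,
        n=blocks.n,
        blocks=blocks,
        result=result,
        null=null,
        loadings=loadings,
        subgroup_sex=subgroup_sex,
    )
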