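"""Synthetic neonatal cohort generator.

Generates cohorts with the statistical structure the downstream analysis
assumes: three strongly inter-correlated pollutants with log-normal
marginals, nine absolute brain volumes plus ICV with covariate dependence on
postmenstrual age at scan, gestational age at birth and sex, deprivation
quintiles correlated with exposure, an exclusion cascade with configurable
counts, and an optional planted latent exposure-to-brain canonical mode of
exactly known strength.

Planted-mode construction
-------------------------
Let ``u`` and ``v`` be standard-normal latents sharing a common factor so
that ``corr(u, v) = rho``. In a whitened variable space the exposure block is
``X~ = u w_x~' + E (I - w_x~ w_x~')`` (noise projected off the signal
direction), so ``cov(X~) = I`` and all cross-covariance between the blocks is
the rank-1 matrix ``rho * w_x~ w_y~'``. Colouring by the target correlation
matrix square root then gives the configured marginal correlations while —
because canonical correlations are invariant to invertible column maps — the
population first canonical correlation remains exactly ``rho`` and the
population canonical weight vector is exactly the planted one.
"""

from __future__ import annotations

import datetime as dt

import numpy as np
import pandas as pd
from scipy import stats

from .config import (
    DEFAULT_ICV_MARGINAL,
    DEFAULT_REGION_MARGINALS,
    POLLUTANTS,
    REGIONS,
    SimulationConfig,
)
from .exposure import weeks_of_year
from .io import Cohort

# Demographic calibration: term GA distribution, scan-delay distribution,
# sex balance and deprivation-quintile frequencies of the emulated cohort.
_GA_TERM_MEAN, _GA_TERM_SD = 40.1, 1.3
_GA_TERM_LO, _GA_TERM_HI = 36.15, 43.55
_SCAN_DELAY_LOG_MEDIAN, _SCAN_DELAY_LOG_SD = np.log(1.15), 0.5
_P_MALE = 0.441
_IMD_QUINTILE_PROBS = np.array([0.10, 0.15, 0.20, 0.25, 0.30])
_TBV_ICV_RATIO, _TBV_RATIO_SD = 0.824, 0.02
_SEASONAL_PEAK_WEEK = 2.0  # winter-high: annual peak in mid-January

_COHORT_START = dt.date(2015, 6, 1)
_COHORT_SPAN_DAYS = 1827  # births spread over five years


def _sym_sqrt(C: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh(C)
    return (vecs * np.sqrt(np.clip(vals, 0.0, None))) @ vecs.T


def _latent_pair(rng: np.random.Generator, n: int, rho: float):
    """Standard-normal latents with corr(u, v) = rho via a shared factor."""
    g = rng.standard_normal(n)
    e_u = rng.standard_normal(n)
    e_v = rng.standard_normal(n)
    u = np.sqrt(rho) * g + np.sqrt(1.0 - rho) * e_u
    v = np.sqrt(rho) * g + np.sqrt(1.0 - rho) * e_v
    return u, v


def _planted_block(
    rng: np.random.Generator,
    latent: np.ndarray,
    weights: np.ndarray,
    colour_half: np.ndarray | None,
) -> np.ndarray:
    """Unit-variance block carrying ``latent`` along ``weights`` (whitened)."""
    n, p = latent.shape[0], weights.shape[0]
    if colour_half is not None:
        w = colour_half @ weights
    else:
        w = weights.copy()
    w = w / np.linalg.norm(w)
    noise = rng.standard_normal((n, p))
    noise -= np.outer(noise @ w, w)  # project noise off the signal direction
    block = latent[:, None] * w[None, :] + noise
    if colour_half is not None:
        block = block @ colour_half
    return block


def simulate_cohort(config: SimulationConfig) -> Cohort:
    """Generate one synthetic cohort; reproducible under a fixed seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects

    # --- exclusion flags: disjoint subject sets per rule, in cascade order
    order = rng.permutation(n)
    flags = {f"flag_{rule}": np.zeros(n, dtype=bool) for rule in (
        "smoking", "ga_out_of_range", "lesion", "twin_drop", "outside_domain")}
    pos = 0
    for rule, count in zip(
        ("smoking", "ga_out_of_range", "lesion", "twin_drop", "outside_domain"),
        config.exclusion_counts,
    ):
        flags[f"flag_{rule}"][order[pos : pos + count]] = True
        pos += count

    # --- demographics
    ga = stats.truncnorm.rvs(
        (_GA_TERM_LO - _GA_TERM_MEAN) / _GA_TERM_SD,
        (_GA_TERM_HI - _GA_TERM_MEAN) / _GA_TERM_SD,
        loc=_GA_TERM_MEAN,
        scale=_GA_TERM_SD,
        size=n,
        random_state=rng,
    )
    preterm = flags["flag_ga_out_of_range"]
    ga[preterm] = rng.uniform(26.0, 36.0, preterm.sum())
    scan_delay = np.exp(
        rng.normal(_SCAN_DELAY_LOG_MEDIAN, _SCAN_DELAY_LOG_SD, n)
    )
    pma = ga + scan_delay
    male = rng.random(n) < _P_MALE
    birth_offset = rng.integers(0, _COHORT_SPAN_DAYS, n)
    birth_date = np.array(
        [_COHORT_START + dt.timedelta(days=int(d)) for d in birth_offset]
    )

    # --- deprivation: latent score cut into quintiles, shared with exposure
    q_latent = rng.standard_normal(n)
    cuts = stats.norm.ppf(np.cumsum(_IMD_QUINTILE_PROBS)[:-1])
    imd_quintile = 1 + np.searchsorted(cuts, q_latent)

    # --- planted canonical channel
    u, v = _latent_pair(rng, n, config.planted_rho)
    Cx_half = _sym_sqrt(config.pollutant_corr)
    x_core = _planted_block(rng, u, config.planted_weights_x, Cx_half)
    y_core = _planted_block(rng, v, config.planted_weights_y, None)

    # mix in the deprivation confounder on the exposure side
    gamma = config.imd_exposure_corr
    z_x = np.sqrt(1.0 - gamma**2) * x_core + gamma * q_latent[:, None]

    # --- whole-pregnancy exposure targets (log-normal marginals)
    targets = np.empty((n, 3))
    for j, pol in enumerate(POLLUTANTS):
        median, lo, hi = config.pollutant_marginals[pol]
        sigma = np.log(hi / lo) / 6.0
        targets[:, j] = median * np.exp(sigma * z_x[:, j])

    # --- volumes
    pma_c = pma - 41.29
    ga_c = ga - 40.14
    male_f = male.astype(float)
    a_icv, b_icv, c_icv = config.covariate_effects["icv"]
    icv = DEFAULT_ICV_MARGINAL[0] * np.exp(
        a_icv * pma_c
        + b_icv * ga_c
        + c_icv * male_f
        + config.icv_noise_scale * rng.standard_normal(n)
    )
    tbv_ratio = np.clip(
        _TBV_ICV_RATIO * np.exp(_TBV_RATIO_SD * rng.standard_normal(n)),
        0.5,
        0.97,
    )
    tbv = icv * tbv_ratio

    frac = np.empty((n, len(REGIONS)))
    for r, region in enumerate(REGIONS):
        med = DEFAULT_REGION_MARGINALS[region][0]
        a, b, c = config.covariate_effects[region]
        s = config.noise_scales[region]
        frac[:, r] = med * np.exp(
            a * pma_c + b * ga_c + c * male_f + s * y_core[:, r]
        )
    for (region, pollutant), slope in config.planted_slopes.items():
        r = REGIONS.index(region)
        j = POLLUTANTS.index(pollutant)
        med_p = config.pollutant_marginals[pollutant][0]
        frac[:, r] = frac[:, r] + slope * (targets[:, j] - med_p)
    frac = np.clip(frac, 1e-6, None)
    region_vols = frac * icv[:, None]

    # --- weekly exposure series: target + window-centred seasonal anomaly
    #     + window-centred weekly noise (whole-pregnancy mean == target)
    amp = np.array([config.seasonal_amplitude[p] for p in POLLUTANTS])
    wk_sd = np.array([config.weekly_noise_sd[p] for p in POLLUTANTS])
    subj_ids = np.array([f"S{idx:04d}" for idx in range(n)])

    lengths = np.ceil(ga).astype(int)
    rows_id, rows_week, rows_pol, rows_conc = [], [], [], []
    for i in range(n):
        L = lengths[i]
        woy = weeks_of_year(birth_date[i], float(ga[i]), L)
        seasonal = np.cos(2.0 * np.pi * (woy - _SEASONAL_PEAK_WEEK) / 52.0)
        noise = rng.standard_normal((L, 3)) * wk_sd[None, :]
        series = (
            targets[i][None, :]
            + amp[None, :] * (seasonal - seasonal.mean())[:, None]
            + (noise - noise.mean(axis=0)[None, :])
        )
        series = np.maximum(series, 0.1)
        for j, pol in enumerate(POLLUTANTS):
            rows_id.append(np.repeat(subj_ids[i], L))
            rows_week.append(np.arange(L))
            rows_pol.append(np.repeat(pol, L))
            rows_conc.append(series[:, j])

    exposures = pd.DataFrame(
        {
            "subject_id": np.concatenate(rows_id),
            "week_index": np.concatenate(rows_week),
            "pollutant": np.concatenate(rows_pol),
            "concentration": np.concatenate(rows_conc),
        }
    )

    subjects = pd.DataFrame(
        {
            "subject_id": subj_ids,
            "ga_birth": ga,
            "pma_scan": pma,
            "sex": np.where(male, "male", "female"),
            "imd_quintile": imd_quintile,
            "birth_date": [d.isoformat() for d in birth_date],
            **flags,
        }
    )
    volumes = pd.DataFrame(
        {"subject_id": subj_ids, "icv": icv, "tbv": tbv}
        | {region: region_vols[:, r] for r, region in enumerate(REGIONS)}
    )
    return Cohort(subjects=subjects, volumes=volumes, exposures=exposures)
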