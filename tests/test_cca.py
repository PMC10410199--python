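"""Adjusted CCA: residualization, solver, permutation null, loadings."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from airbrain import (
    AdjustedBlocks,
    SimulationConfig,
    apply_exclusions,
    build_adjusted_blocks,
    fit_cca,
    mode_loadings,
    permutation_test,
    residualize,
    run_full_cca,
    simulate_cohort,
    summarize_cohort,
)
from airbrain.cca import DegenerateColumnError, SingularBlockError

from helpers import grid_cca_first_corr, optim_cca_first_corr, rank_then_pearson


def random_blocks(rng, n=200, p=3, q=8, rho=0.0):
    shared = rng.standard_normal(n)
    X = rng.standard_normal((n, p)) + rho * shared[:, None]
    Y = rng.standard_normal((n, q)) + rho * shared[:, None]
    return AdjustedBlocks(
        X=residualize(X),
        Y=residualize(Y),
        x_labels=tuple(f"x{j}" for j in range(p)),
        y_labels=tuple(f"y{j}" for j in range(q)),
    )


# ------------------------------------------------------------ residualize


def test_intercept_only_residualization_is_standardization(rng):
    x = rng.lognormal(1.0, 0.5, (40, 2))
    out = residualize(x)
    expected = (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)
    assert np.allclose(out, expected)


def test_residuals_are_orthogonal_to_covariates(rng):
    x = rng.standard_normal((100, 3))
    cov = rng.standard_normal((100, 2))
    out = residualize(x, cov)
    assert np.abs(out.mean(axis=0)).max() < 1e-10
    assert np.allclose(out.std(axis=0, ddof=1), 1.0)
    for j in range(2):
        corr = np.corrcoef(out.T, cov[:, j])[-1, :-1]
        assert np.abs(corr).max() < 1e-10


def test_perfectly_confounded_column_is_degenerate():
    c = np.arange(6.0)
    with pytest.raises(DegenerateColumnError, match="zero residual variance"):
        residualize(c[:, None], c)


def test_six_row_residuals_match_hand_normal_equations():
    # y = 2c + e with a hand-solvable single-covariate design:
    # b1 = S_cy / S_cc, b0 = ybar - b1*cbar, residuals = y - b0 - b1*c
    c = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
    e = np.array([0.3, -0.1, 0.2, -0.4, 0.1, -0.1])
    y = 2.0 * c + e
    cc = c - c.mean()
    b1 = (cc @ (y - y.mean())) / (cc @ cc)
    b0 = y.mean() - b1 * c.mean()
    resid = y - b0 - b1 * c
    expected = resid / resid.std(ddof=1)
    out = residualize(y[:, None], c)
    assert np.allclose(out[:, 0], expected, atol=1e-12)


def test_rank_deficient_covariates_are_an_error(rng):
    x = rng.standard_normal((20, 2))
    cov = np.ones((20, 2))  # duplicates the intercept twice over
    with pytest.raises(ValueError, match="rank deficient"):
        residualize(x, cov)


# ---------------------------------------------------------------- fit_cca


def test_copied_columns_give_perfect_canonical_correlations(rng):
    X = rng.standard_normal((80, 3))
    Y = np.column_stack([X, rng.standard_normal((80, 5))])
    res = fit_cca(AdjustedBlocks(X=residualize(X), Y=residualize(Y)))
    assert np.allclose(res.canonical_corr, 1.0, atol=1e-8)


def test_exactly_three_modes_for_three_by_eight_blocks(rng):
    res = fit_cca(random_blocks(rng))
    assert res.K == 3
    assert res.weights_x.shape == (3, 3)
    assert res.weights_y.shape == (8, 3)


def test_canonical_correlations_are_sorted_and_bounded(rng):
    res = fit_cca(random_blocks(rng, rho=0.4))
    assert np.all(np.diff(res.canonical_corr) <= 1e-12)
    assert np.all((res.canonical_corr >= 0) & (res.canonical_corr <= 1))


def test_within_block_variates_are_uncorrelated(rng):
    res = fit_cca(random_blocks(rng, rho=0.5))
    for scores in (res.scores_x, res.scores_y):
        corr = np.corrcoef(scores.T)
        off = corr[~np.eye(3, dtype=bool)]
        assert np.abs(off).max() < 1e-8
        assert np.allclose(scores.std(axis=0, ddof=1), 1.0)


def test_first_canonical_corr_matches_grid_oracle_on_2x2_blocks(rng):
    for seed in range(20):
        r = np.random.default_rng(seed)
        X = r.standard_normal((50, 2))
        Y = 0.3 * X @ r.standard_normal((2, 2)) + r.standard_normal((50, 2))
        res = fit_cca(
            AdjustedBlocks(X=residualize(X), Y=residualize(Y),
                           x_labels=("a", "b"), y_labels=("c", "d"))
        )
        oracle = grid_cca_first_corr(X - X.mean(0), Y - Y.mean(0))
        assert abs(res.canonical_corr[0] - oracle) < 1e-3


def test_first_canonical_corr_matches_optimizer_oracle_on_3x3_blocks():
    for seed in (1, 2, 3):
        r = np.random.default_rng(seed)
        X = r.standard_normal((60, 3))
        Y = 0.4 * X @ r.standard_normal((3, 3)) + r.standard_normal((60, 3))
        res = fit_cca(
            AdjustedBlocks(X=residualize(X), Y=residualize(Y),
                           x_labels=("a", "b", "c"), y_labels=("d", "e", "f"))
        )
        oracle = optim_cca_first_corr(X - X.mean(0), Y - Y.mean(0), seed=seed)
        assert abs(res.canonical_corr[0] - oracle) < 1e-3


def test_canonical_correlations_invariant_to_invertible_maps(rng):
    blocks = random_blocks(rng, rho=0.3)
    A = rng.standard_normal((3, 3)) + 3 * np.eye(3)
    B = rng.standard_normal((8, 8)) + 3 * np.eye(8)
    mapped = AdjustedBlocks(
        X=blocks.X @ A, Y=blocks.Y @ B,
        x_labels=blocks.x_labels, y_labels=blocks.y_labels,
    )
    r1 = fit_cca(blocks).canonical_corr
    r2 = fit_cca(mapped).canonical_corr
    assert np.allclose(r1, r2, atol=1e-8)


def test_sign_convention_is_stable_under_joint_row_permutation(rng):
    blocks = random_blocks(rng, rho=0.4)
    perm = rng.permutation(blocks.n)
    permuted = AdjustedBlocks(
        X=blocks.X[perm], Y=blocks.Y[perm],
        x_labels=blocks.x_labels, y_labels=blocks.y_labels,
    )
    res1, res2 = fit_cca(blocks), fit_cca(permuted)
    assert np.allclose(res1.weights_x, res2.weights_x, atol=1e-8)
    assert np.allclose(res1.weights_y, res2.weights_y, atol=1e-8)
    for k in range(res1.K):
        j = np.argmax(np.abs(res1.weights_x[:, k]))
        assert res1.weights_x[j, k] > 0


def test_singular_block_is_reported(rng):
    X = rng.standard_normal((50, 3))
    X[:, 2] = X[:, 0] + X[:, 1]  # exactly collinear
    Xs = (X - X.mean(0)) / X.std(0, ddof=1)
    Y = residualize(rng.standard_normal((50, 8)))
    with pytest.raises(SingularBlockError, match="singular"):
        fit_cca(AdjustedBlocks(X=Xs, Y=Y))


def test_too_few_rows_is_an_error(rng):
    blocks = random_blocks(rng, n=200)
    small = AdjustedBlocks(X=blocks.X[:10], Y=blocks.Y[:10])
    with pytest.raises(ValueError, match="need n >"):
        fit_cca(small)


# ------------------------------------------------------- permutation test


def test_permutation_null_is_deterministic_under_a_seed(rng):
    blocks = random_blocks(rng, rho=0.3)
    a = permutation_test(blocks, B=120, seed=9)
    b = permutation_test(blocks, B=120, seed=9)
    assert np.array_equal(a.null, b.null)
    assert np.array_equal(a.passed, b.passed)
    assert np.array_equal(a.p_empirical, b.p_empirical)


def test_too_few_permutations_is_an_error(rng):
    with pytest.raises(ValueError, match="at least 100"):
        permutation_test(random_blocks(rng), B=50, seed=0)


def test_permutation_pass_rule_and_empirical_p(rng):
    blocks = random_blocks(rng, n=300, rho=0.6)
    null = permutation_test(blocks, B=150, seed=4)
    assert null.passed[0]
    assert np.all(null.passed == (null.observed > null.p95))
    assert np.all(null.p_empirical >= 1.0 / 151.0)
    assert np.all(null.p_empirical <= 1.0)
    assert null.p_fdr[0] == pytest.approx(null.p_empirical[0], abs=1e-12) or (
        null.passed.sum() > 1
    )


def test_max_statistic_variant_is_more_conservative(rng):
    blocks = random_blocks(rng, n=300, rho=0.25)
    per_mode = permutation_test(blocks, B=150, seed=4)
    fam = permutation_test(blocks, B=150, seed=4, statistic="max")
    assert np.all(fam.p95 >= per_mode.p95 - 1e-12)


# --------------------------------------------------------------- loadings


def test_variable_identical_to_score_loads_at_one(rng):
    scores = rng.standard_normal(60)
    block = np.column_stack([scores, rng.standard_normal(60)])
    table = mode_loadings(block, scores, ["self", "noise"])
    self_row = table.set_index("variable").loc["self"]
    assert self_row.spearman_r == pytest.approx(1.0)
    assert self_row.r_squared == pytest.approx(1.0)


def test_loadings_match_rank_then_pearson_oracle_with_ties():
    block = np.array(
        [[1.0], [2.0], [2.0], [3.0], [4.0], [5.0], [6.0], [7.0]]
    )
    scores = np.array([2.0, 1.0, 3.0, 5.0, 4.0, 7.0, 6.0, 8.0])
    table = mode_loadings(block, scores, ["v"])
    assert table.loc[0, "spearman_r"] == pytest.approx(
        rank_then_pearson(block[:, 0], scores), abs=1e-12
    )


def test_r_squared_is_the_square_of_spearman_r(rng):
    blocks = random_blocks(rng, rho=0.5)
    res = fit_cca(blocks)
    table = mode_loadings(blocks.Y, res.scores_y[:, 0], blocks.y_labels)
    assert np.allclose(table.r_squared, table.spearman_r**2, atol=1e-9)
    assert (table.p_fdr >= table.p - 1e-15).all()


def test_constant_variable_is_an_error(rng):
    block = np.column_stack([np.ones(30), rng.standard_normal(30)])
    with pytest.raises(DegenerateColumnError, match="constant"):
        mode_loadings(block, rng.standard_normal(30), ["flat", "ok"])


def test_loading_p_values_use_t_approximation(rng):
    blocks = random_blocks(rng, rho=0.5)
    res = fit_cca(blocks)
    table = mode_loadings(blocks.Y, res.scores_y[:, 0], blocks.y_labels)
    ref = [
        stats.spearmanr(blocks.Y[:, j], res.scores_y[:, 0]).pvalue
        for j in range(8)
    ]
    assert np.allclose(table.p, ref, atol=1e-12)


def test_null_first_canonical_corr_sits_at_the_overfitting_level(
    filtered_summary,
):
    """With no planted mode the fitted first canonical correlation is not
    near zero but near the small-sample overfitting level, roughly
    sqrt((p+q)/n) for standardized blocks."""
    res = fit_cca(build_adjusted_blocks(filtered_summary))
    n = len(filtered_summary)
    level = np.sqrt((3 + 8) / n)  # ~0.15 at the study scale
    assert 0.4 * level < res.canonical_corr[0] < 2.0 * level


# ------------------------------------------------------------ end to end


def test_planted_mode_is_recovered_end_to_end(planted_summary):
    """A planted rho=0.5 mode passes validation with the planted sign
    pattern (PM10-positive, NO2-negative exposure loadings). Under the
    family-wise max-statistic null the unplanted modes 2-3 do not pass
    (the default per-mode null is anti-conservative for later modes in the
    presence of a strong first mode; see the methods note)."""
    analysis = run_full_cca(planted_summary, B=300, seed=17)
    assert analysis.result.K == 3
    assert bool(analysis.null.passed[0])
    fam = run_full_cca(planted_summary, B=300, seed=17, statistic="max")
    assert bool(fam.null.passed[0])
    assert not fam.null.passed[1:].any()
    lx, ly = analysis.loadings[1]
    lx = lx.set_index("variable")
    assert lx.loc["pm10", "spearman_r"] > 0
    assert lx.loc["no2", "spearman_r"] < 0
    ly = ly.set_index("variable")
    assert ly.spearman_r.abs().idxmax() == "ventricles"


def test_trimester_signal_is_diluted_by_weekly_noise():
    """A mode planted in whole-pregnancy exposure survives the
    whole-pregnancy CCA but is mostly lost in trimester windows when the
    spatial exposure contrast is weak relative to week-to-week variability
    (whole-pregnancy means average the weekly noise away; trimester means
    do not)."""
    from airbrain.config import DEFAULT_POLLUTANT_MARGINALS

    narrow = {
        pol: (med, med * (lo / med) ** (1 / 6), med * (hi / med) ** (1 / 6))
        for pol, (med, lo, hi) in DEFAULT_POLLUTANT_MARGINALS.items()
    }
    whole_pass, t_pass = 0, 0
    n_rep = 10
    for rep in range(n_rep):
        cfg = SimulationConfig(
            seed=7000 + rep, planted_rho=0.4, pollutant_marginals=narrow
        )
        filtered, _ = apply_exclusions(simulate_cohort(cfg))
        summary = summarize_cohort(filtered)
        whole = run_full_cca(summary, window="whole_pregnancy", B=150,
                             seed=rep)
        t1 = run_full_cca(summary, window="t1", B=150, seed=rep)
        whole_pass += bool(whole.null.passed[0])
        t_pass += bool(t1.null.passed[0])
    assert whole_pass == n_rep
    assert t_pass <= 0.2 * n_rep + 1e-9  # planted mode lost in >=80% of runs


def test_sex_subgroup_filter_and_empty_subgroup(planted_summary):
    male = run_full_cca(planted_summary, B=120, seed=3, subgroup_sex="male")
    assert male.n == (planted_summary.sex == "male").sum()
    none_left = planted_summary[planted_summary.sex == "male"].head(0)
    with pytest.raises(ValueError, match="subgroup too small"):
        run_full_cca(
            pd.concat([none_left]), B=120, seed=3, subgroup_sex="female"
        )
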