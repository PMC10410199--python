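"""Independent oracles used by the tests.

These deliberately avoid the package's own linear-algebra path: the first
canonical correlation is found by brute force over unit-vector grids (or
multi-start optimization for three-column blocks), and rank correlations by
explicit rank-then-Pearson computation.
"""

import numpy as np
from scipy import optimize, stats


def _corr(u: np.ndarray, v: np.ndarray) -> float:
    u = u - u.mean()
    v = v - v.mean()
    return float((u @ v) / np.sqrt((u @ u) * (v @ v)))


def grid_cca_first_corr(X: np.ndarray, Y: np.ndarray, n_grid: int = 500) -> float:
    """Max |corr(Xa, Yb)| over a grid of unit vectors, for 2-column blocks."""
    assert X.shape[1] == 2 and Y.shape[1] == 2
    theta = np.linspace(0.0, np.pi, n_grid, endpoint=False)
    A = np.stack([np.cos(theta), np.sin(theta)])  # 2 x g
    U = X @ A
    V = Y @ A
    U = U - U.mean(axis=0)
    V = V - V.mean(axis=0)
    U /= np.linalg.norm(U, axis=0)
    V /= np.linalg.norm(V, axis=0)
    return float(np.abs(U.T @ V).max())


def optim_cca_first_corr(
    X: np.ndarray, Y: np.ndarray, n_starts: int = 30, seed: int = 0
) -> float:
    """Max |corr(Xa, Yb)| by multi-start optimization (any block widths)."""
    rng = np.random.default_rng(seed)
    p, q = X.shape[1], Y.shape[1]

    def neg_abs_corr(w):
        a, b = w[:p], w[p:]
        if np.linalg.norm(a) < 1e-12 or np.linalg.norm(b) < 1e-12:
            return 0.0
        return -abs(_corr(X @ a, Y @ b))

    best = 0.0
    for _ in range(n_starts):
        w0 = rng.standard_normal(p + q)
        res = optimize.minimize(neg_abs_corr, w0, method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-12,
                                         "maxiter": 20000, "maxfev": 20000})
        best = max(best, -res.fun)
    return best


def rank_then_pearson(x, y) -> float:
    """Spearman correlation computed as Pearson on average ranks."""
    rx = stats.rankdata(x, method="average")
    ry = stats.rankdata(y, method="average")
    return _corr(rx, ry)
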