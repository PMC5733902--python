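"""Mantel and partial Mantel permutation tests, the IBR support criterion,
and commonality analysis of multiple regression on distance matrices.

All tests are one-tailed for positive association. Permutation p-values use
the add-one estimator p = (1 + #{r_perm >= r_obs}) / (1 + n_perm), permuting
rows and columns of one matrix jointly.
"""
from __future__ import annotations

import dataclasses
from itertools import combinations
from typing import Sequence

import numpy as np

from ._util import condensed_index_matrix


@dataclasses.dataclass
class MantelResult:
    r: float
    p: float
    n_perm: int
    partialled: str | None = None
    seed: int | None = None

    def __post_init__(self):
        if not -1.0 - 1e-9 <= self.r <= 1.0 + 1e-9:
            raise ValueError("r outside [-1, 1]")
        if not 0.0 < self.p <= 1.0:
            raise ValueError("p outside (0, 1]")


@dataclasses.dataclass
class SupportDecision:
    hypothesis: str
    p_ibr_given_ibd: float
    p_ibd_given_ibr: float
    alpha: float
    supported: bool


@dataclasses.dataclass
class CommonalityResult:
    subsets: list[tuple[str, ...]]
    coefficients: np.ndarray
    percent_total: np.ndarray
    r2_full: float
    labels: list[str]


def _condensed(matrix: np.ndarray) -> np.ndarray:
    matrix = np.asarray(matrix, dtype=float)
    n = matrix.shape[0]
    iu = np.triu_indices(n, k=1)
    return matrix[iu]


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    if denom == 0:
        raise ValueError("zero-variance matrix in Mantel test")
    return float((a @ b) / denom)


def _permuted_condensed(vec: np.ndarray, idx_matrix: np.ndarray,
                        perm: np.ndarray, iu) -> np.ndarray:
    return vec[idx_matrix[np.ix_(perm, perm)][iu]]


def mantel(x: np.ndarray, y: np.ndarray, n_perm: int = 999,
           seed: int | None = None) -> MantelResult:
    """Simple Mantel test: Pearson r of the off-diagonal vectors, one-tailed
    permutation p-value (rows/columns of `y` permuted jointly)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.shape[0]
    if n < 4:
        raise ValueError("need n >= 4")
    if y.shape != (n, n):
        raise ValueError("matrix shapes disagree")
    xv = _condensed(x)
    yv = _condensed(y)
    r_obs = _pearson(xv, yv)
    rng = np.random.default_rng(seed)
    idx = condensed_index_matrix(n)
    iu = np.triu_indices(n, k=1)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r_p = _pearson(xv, _permuted_condensed(yv, idx, perm, iu))
        if r_p >= r_obs - 1e-12:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return MantelResult(r_obs, p, n_perm, seed=seed)


def _residualize(vec: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Residual of `vec` against the orthonormal design `q`."""
    return vec - q @ (q.T @ vec)


def partial_mantel(g: np.ndarray, x: np.ndarray, z: np.ndarray,
                   n_perm: int = 999, seed: int | None = None,
                   label: str | None = None) -> MantelResult:
    """Partial Mantel test of `g` vs `x` controlling for `z`.

    The off-diagonal vectors of `g` and `x` are residualized on `z` (with
    intercept); r is the correlation of residuals. Permutations relabel `g`
    (rows and columns jointly) and residuals are recomputed each time.
    """
    g = np.asarray(g, dtype=float)
    x = np.asarray(x, dtype=float)
    z = np.asarray(z, dtype=float)
    n = g.shape[0]
    if n < 4:
        raise ValueError("need n >= 4")
    gv, xv, zv = _condensed(g), _condensed(x), _condensed(z)
    if np.std(xv) == 0:
        raise ValueError("zero-variance matrix")
    z_constant = np.std(zv) <= 1e-12 * max(1.0, float(np.abs(zv).max()))
    if z_constant:
        # a constant covariate carries no information: the test reduces to a
        # simple Mantel test
        design = np.ones((zv.size, 1))
    else:
        if abs(np.corrcoef(xv, zv)[0, 1]) >= 1.0 - 1e-12:
            raise ValueError("X is affinely identical to Z: degenerate design")
        design = np.column_stack([np.ones_like(zv), zv])
    q, _ = np.linalg.qr(design)
    x_res = _residualize(xv, q)
    r_obs = _pearson(_residualize(gv, q), x_res)
    rng = np.random.default_rng(seed)
    idx = condensed_index_matrix(n)
    iu = np.triu_indices(n, k=1)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        g_perm = _permuted_condensed(gv, idx, perm, iu)
        r_p = _pearson(_residualize(g_perm, q), x_res)
        if r_p >= r_obs - 1e-12:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return MantelResult(r_obs, p, n_perm, partialled=label, seed=seed)


def support_criterion(p_ibr_given_ibd: float, p_ibd_given_ibr: float,
                      alpha: float = 0.05,
                      hypothesis: str = "") -> SupportDecision:
    """Supported iff the resistance matrix is significant controlling for
    distance (p < alpha) and distance is non-significant controlling for
    resistance (p >= alpha)."""
    for p in (p_ibr_given_ibd, p_ibd_given_ibr):
        if not 0.0 < p <= 1.0:
            raise ValueError("p-values must lie in (0, 1]")
    supported = (p_ibr_given_ibd < alpha) and (p_ibd_given_ibr >= alpha)
    return SupportDecision(hypothesis, p_ibr_given_ibd, p_ibd_given_ibr,
                           alpha, supported)


def _ols_r2(y: np.ndarray, columns: list[np.ndarray]) -> float:
    design = np.column_stack([np.ones_like(y)] + columns)
    coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    sst = np.sum((y - y.mean()) ** 2)
    if sst == 0:
        raise ValueError("zero-variance response")
    return float(1.0 - np.sum(resid ** 2) / sst)


def subset_order(labels: Sequence[str]) -> list[tuple[int, ...]]:
    """All non-empty predictor subsets: singletons in predictor order, then
    pairs lexicographically, then triples, etc."""
    p = len(labels)
    order: list[tuple[int, ...]] = []
    for size in range(1, p + 1):
        order.extend(combinations(range(p), size))
    return order


def commonality(g: np.ndarray, predictors: Sequence[np.ndarray],
                labels: Sequence[str] | None = None) -> CommonalityResult:
    """Commonality analysis of the OLS regression of `g`'s off-diagonal
    vector on the predictors' vectors.

    Solves the linear system R^2(A) = sum over subsets S intersecting A of
    C_S, for every non-empty predictor subset A; this is the standard
    inclusion-exclusion decomposition and guarantees that the coefficients
    sum to the full-model R^2.
    """
    p = len(predictors)
    if not 1 <= p <= 6:
        raise ValueError("need 1..6 predictors")
    if labels is None:
        labels = [f"X{k + 1}" for k in range(p)]
    y = _condensed(np.asarray(g, dtype=float))
    cols = [_condensed(np.asarray(m, dtype=float)) for m in predictors]
    subsets = subset_order(labels)
    n_sub = len(subsets)
    r2 = np.array([_ols_r2(y, [cols[k] for k in s]) for s in subsets])
    sets = [frozenset(s) for s in subsets]
    m = np.zeros((n_sub, n_sub))
    for a_i, a in enumerate(sets):
        for s_i, s in enumerate(sets):
            if a & s:
                m[a_i, s_i] = 1.0
    coef = np.linalg.solve(m, r2)
    r2_full = float(r2[-1])
    percent = 100.0 * coef / r2_full if r2_full != 0 else np.full(n_sub, np.nan)
    named = [tuple(labels[k] for k in s) for s in subsets]
    return CommonalityResult(named, coef, percent, r2_full, list(labels))
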