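"""Permutation inference on similarity/distance matrices.

Simple and partial Mantel tests and multiple matrix regression (MRM).
Entries of each matrix's lower triangle are unfolded into vectors;
significance comes from simultaneously permuting the rows and columns
of one matrix (the first, for Mantel; the response, for regression),
which respects the exchangeability of *objects*, not of pairs.

p-value conventions: one-sided (greater) for Mantel correlations, as
in vegan; two-sided on |t| for regression coefficients; both with +1
smoothing, so the smallest attainable p is 1 / (n_perm + 1) — 0.0001
at the default 9999 permutations. Similarity matrices are used as-is;
the sign of r is interpreted directly.

Pairs that are missing (NaN) in any matrix of a joint analysis are
masked out of all unfolded vectors; the mask is fixed by the observed
matrices and applied to permuted values as well.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import SquareMatrix

__all__ = [
    "MantelResult",
    "MatrixRegressionResult",
    "unfold",
    "refold",
    "mantel",
    "partial_mantel",
    "matrix_regression",
    "variance_partition",
]

DEFAULT_N_PERM = 9999
_PERM_CHUNK = 500


@dataclass(frozen=True)
class MantelResult:
    r: float
    p: float
    n_perm: int
    n_obs: int  # matrix dimension
    method: str = "mantel"


@dataclass(frozen=True)
class MatrixRegressionResult:
    predictor_names: tuple[str, ...]  # excludes intercept
    coefficients: np.ndarray  # intercept first, then predictors
    t_statistics: np.ndarray
    p_values: np.ndarray  # permutation, two-sided; intercept slot is NaN
    f_statistic: float
    f_p_value: float
    r_squared: float
    n_perm: int
    n_obs: int

    def coefficient(self, name: str) -> float:
        return float(self.coefficients[1 + self.predictor_names.index(name)])

    def p_value(self, name: str) -> float:
        return float(self.p_values[1 + self.predictor_names.index(name)])


def _check_aligned(*mats: SquareMatrix) -> None:
    labels = mats[0].labels
    for m in mats[1:]:
        if m.labels != labels:
            raise ValueError(
                "matrices are not label-aligned; use align_matrices first"
            )


def _tril_indices(n: int) -> tuple[np.ndarray, np.ndarray]:
    return np.tril_indices(n, k=-1)


def unfold(m: SquareMatrix) -> np.ndarray:
    """Lower-triangle off-diagonal values in fixed label order.

    NaNs propagate; more than 50% missing is an error.
    """
    ii, jj = _tril_indices(m.n)
    v = m.values[ii, jj]
    if v.size and np.isnan(v).sum() > 0.5 * v.size:
        raise ValueError(">50% of pairwise entries missing")
    return v


def refold(vec: np.ndarray, labels: list[str]) -> SquareMatrix:
    """Inverse of :func:`unfold` (diagonal set to 0)."""
    n = len(labels)
    out = np.zeros((n, n))
    ii, jj = _tril_indices(n)
    out[ii, jj] = vec
    out[jj, ii] = vec
    return SquareMatrix(list(labels), out)


def _joint_mask(vectors: list[np.ndarray]) -> np.ndarray:
    valid = ~np.isnan(vectors[0])
    for v in vectors[1:]:
        valid &= ~np.isnan(v)
    if valid.sum() < 3:
        raise ValueError("fewer than 3 complete pairs after masking")
    return valid


def _perm_vectors(
    values: np.ndarray,
    perms: np.ndarray,
    ii: np.ndarray,
    jj: np.ndarray,
) -> np.ndarray:
    """Unfolded lower triangles of values[p][:, p] for each permutation
    p (rows of ``perms``); shape (n_perm, n_pairs)."""
    return values[perms[:, ii], perms[:, jj]]

def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt((xc * xc).sum())
    sy = np.sqrt((yc * yc).sum())
    if sx == 0.0 or sy == 0.0:
        raise ValueError("zero variance in unfolded matrix")
    return float((xc * yc).sum() / (sx * sy))


def _pearson_rows(xm: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson r of each row of ``xm`` against ``y`` (NaN-aware)."""
    if np.isnan(xm).any():
        out = np.empty(xm.shape[0])
        for k in range(xm.shape[0]):
            row = xm[k]
            ok = ~np.isnan(row)
            out[k] = _pearson(row[ok], y[ok]) if ok.sum() >= 3 else np.nan
        return out
    xc = xm - xm.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    sx = np.sqrt((xc * xc).sum(axis=1))
    sy = np.sqrt((yc * yc).sum())
    sx[sx == 0.0] = np.nan
    return (xc @ yc) / (sx * sy)


def _permutations(
    rng: np.random.Generator, n: int, n_perm: int
) -> np.ndarray:
    out = np.empty((n_perm, n), dtype=np.intp)
    for k in range(n_perm):
        out[k] = rng.permutation(n)
    return out


def mantel(
    A: SquareMatrix,
    B: SquareMatrix,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | np.random.Generator | None = None,
) -> MantelResult:
    """Simple Mantel test: Pearson r between unfolded matrices; null
    from simultaneous row/column permutation of A; one-sided
    (greater) p with +1 smoothing."""
    _check_aligned(A, B)
    n = A.n
    if n < 4:
        raise ValueError("need at least 4 objects")
    ii, jj = _tril_indices(n)
    a, b = unfold(A), unfold(B)
    valid = _joint_mask([a, b])
    r_obs = _pearson(a[valid], b[valid])

    rng = np.random.default_rng(seed)
    count = 0
    for start in range(0, n_perm, _PERM_CHUNK):
        k = min(_PERM_CHUNK, n_perm - start)
        perms = _permutations(rng, n, k)
        ap = _perm_vectors(A.values, perms, ii, jj)[:, valid]
        r_perm = _pearson_rows(ap, b[valid])
        count += int(np.sum(r_perm >= r_obs - 1e-15))
    p = (count + 1) / (n_perm + 1)
    return MantelResult(r=r_obs, p=p, n_perm=n_perm, n_obs=n)


def _partial_r(rab: float, rac: float, rbc: float) -> float:
    denom = np.sqrt((1.0 - rac**2) * (1.0 - rbc**2))
    if denom == 0.0:
        raise ValueError("degenerate conditioning (|r| = 1 with C)")
    return (rab - rac * rbc) / denom


def partial_mantel(
    A: SquareMatrix,
    B: SquareMatrix,
    C: SquareMatrix,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | np.random.Generator | None = None,
) -> MantelResult:
    """Partial Mantel test of A vs B controlling for C.

    r_AB.C is the first-order partial correlation of the unfolded
    vectors; the null permutes A's rows/columns and recomputes the
    partial statistic (r_BC is unchanged by the permutation).
    """
    _check_aligned(A, B, C)
    n = A.n
    if n < 4:
        raise ValueError("need at least 4 objects")
    ii, jj = _tril_indices(n)
    a, b, c = unfold(A), unfold(B), unfold(C)
    valid = _joint_mask([a, b, c])
    b_, c_ = b[valid], c[valid]
    if np.allclose(b_, c_, atol=1e-12):
        # conditioning on B itself: numerator and denominator both
        # vanish; the algebraic limit of r_AB.C is 0
        return MantelResult(r=0.0, p=1.0, n_perm=n_perm, n_obs=n,
                            method="partial_mantel")
    rab = _pearson(a[valid], b_)
    rac = _pearson(a[valid], c_)
    rbc = _pearson(b_, c_)
    if abs(rac) >= 1.0 - 1e-12 or abs(rbc) >= 1.0 - 1e-12:
        raise ValueError("degenerate conditioning (|r| = 1 with C)")
    r_obs = _partial_r(rab, rac, rbc)

    rng = np.random.default_rng(seed)
    count = 0
    for start in range(0, n_perm, _PERM_CHUNK):
        k = min(_PERM_CHUNK, n_perm - start)
        perms = _permutations(rng, n, k)
        ap = _perm_vectors(A.values, perms, ii, jj)[:, valid]
        rab_p = _pearson_rows(ap, b_)
        rac_p = _pearson_rows(ap, c_)
        with np.errstate(invalid="ignore", divide="ignore"):
            r_perm = (rab_p - rac_p * rbc) / np.sqrt(
                (1.0 - rac_p**2) * (1.0 - rbc**2)
            )
        count += int(np.nansum(r_perm >= r_obs - 1e-15))
    p = (count + 1) / (n_perm + 1)
    return MantelResult(
        r=r_obs, p=p, n_perm=n_perm, n_obs=n, method="partial_mantel"
    )


def _ols(x: np.ndarray, y: np.ndarray):
    """Classical OLS; returns beta, t, F, R^2 (x includes intercept)."""
    n, k1 = x.shape
    xtx_inv = np.linalg.inv(x.T @ x)
    beta = xtx_inv @ x.T @ y
    resid = y - x @ beta
    df = n - k1
    sigma2 = (resid @ resid) / df
    se = np.sqrt(np.diag(xtx_inv) * sigma2)
    t = beta / se
    ss_tot = ((y - y.mean()) ** 2).sum()
    ss_res = (resid**2).sum()
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    k = k1 - 1
    f = (r2 / k) / ((1.0 - r2) / df) if k > 0 and r2 < 1.0 else np.inf
    return beta, t, f, r2


def matrix_regression(
    Y: SquareMatrix,
    X: list[SquareMatrix],
    n_perm: int = DEFAULT_N_PERM,
    seed: int | np.random.Generator | None = None,
    predictor_names: list[str] | None = None,
) -> MatrixRegressionResult:
    """Multiple regression on distance/similarity matrices (MRM).

    OLS of unfolded Y on unfolded predictors with intercept; classical
    t, F and R^2; permutation p-values by jointly permuting Y's rows
    and columns and recomputing the statistics (two-sided on |t| for
    coefficients, one-sided greater for F).
    """
    if not X:
        raise ValueError("need at least one predictor matrix")
    _check_aligned(Y, *X)
    n = Y.n
    if n < 4:
        raise ValueError("need at least 4 objects")
    if predictor_names is None:
        predictor_names = [f"x{k + 1}" for k in range(len(X))]
    ii, jj = _tril_indices(n)
    y = unfold(Y)
    xs = [unfold(m) for m in X]
    valid = _joint_mask([y] + xs)
    y_ = y[valid]
    design = np.column_stack(
        [np.ones(valid.sum())] + [x[valid] for x in xs]
    )
    if np.linalg.cond(design.T @ design) > 1e10:
        raise ValueError("collinear predictors (condition number > 1e10)")
    beta, t_obs, f_obs, r2 = _ols(design, y_)

    rng = np.random.default_rng(seed)
    xtx_inv = np.linalg.inv(design.T @ design)
    hat = xtx_inv @ design.T  # (k+1, m)
    diag = np.diag(xtx_inv)
    m_pairs, k1 = design.shape
    df = m_pairs - k1
    count_t = np.zeros(k1)
    count_f = 0
    for start in range(0, n_perm, _PERM_CHUNK):
        k = min(_PERM_CHUNK, n_perm - start)
        perms = _permutations(rng, n, k)
        yp = _perm_vectors(Y.values, perms, ii, jj)[:, valid]
        if np.isnan(yp).any():
            # rare NaN-shuffle path: per-permutation fallback
            for row in yp:
                ok = ~np.isnan(row)
                bb, tt, ff, _ = _ols(design[ok], row[ok])
                count_t += np.abs(tt) >= np.abs(t_obs) - 1e-15
                count_f += ff >= f_obs - 1e-15
            continue
        bet = hat @ yp.T  # (k1, k)
        resid = yp.T - design @ bet
        sigma2 = (resid**2).sum(axis=0) / df
        tt = bet / np.sqrt(diag[:, None] * sigma2[None, :])
        yc = yp.T - yp.T.mean(axis=0)
        ss_tot = (yc**2).sum(axis=0)
        ss_res = (resid**2).sum(axis=0)
        r2p = 1.0 - ss_res / np.where(ss_tot > 0, ss_tot, np.nan)
        ffp = (r2p / (k1 - 1)) / ((1.0 - r2p) / df)
        count_t += (np.abs(tt) >= np.abs(t_obs)[:, None] - 1e-15).sum(axis=1)
        count_f += int(np.nansum(ffp >= f_obs - 1e-15))
    p_t = (count_t + 1) / (n_perm + 1)
    p_t[0] = np.nan  # intercept has no meaningful permutation p
    p_f = (count_f + 1) / (n_perm + 1)
    return MatrixRegressionResult(
        predictor_names=tuple(predictor_names),
        coefficients=beta,
        t_statistics=t_obs,
        p_values=p_t,
        f_statistic=float(f_obs),
        f_p_value=float(p_f),
        r_squared=float(r2),
        n_perm=n_perm,
        n_obs=n,
    )


def variance_partition(
    full: MatrixRegressionResult, reduced: MatrixRegressionResult
) -> float:
    """R^2 difference between nested regressions: the variance
    explained by the predictors the full model adds (e.g., a genomic
    index over phylogeny alone)."""
    if not set(reduced.predictor_names) <= set(full.predictor_names):
        raise ValueError(
            "reduced model predictors must be a subset of the full model's"
        )
    return full.r_squared - reduced.r_squared
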