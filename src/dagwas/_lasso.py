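"""Cross-validated lasso in covariance form, vectorised over responses.

The nuisance regressions inside the double machine learning loop share one
small design matrix (the principal-component scores) across thousands of
response vectors (marker dosages plus the trait).  Fitting a separate
cross-validated lasso object per marker per fold would dominate the runtime
of the stability screen, so this module solves the same optimisation

    min_b  1/(2n) ||y - X b||^2 + alpha ||b||_1

by cyclic coordinate descent expressed purely in terms of the Gram matrix
X'X/n and the covariance block X'Y/n.  Because the iteration never touches
the raw n-vector residuals, its cost is independent of the sample size and
it vectorises trivially across the columns of Y.  Coefficients agree with
``sklearn.linear_model.Lasso`` to solver tolerance (verified in the tests).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["lasso_fit", "lasso_cv", "LassoCVResult"]


def _soft_threshold(x: np.ndarray, t: np.ndarray | float) -> np.ndarray:
    return np.sign(x) * np.maximum(np.abs(x) - t, 0.0)


def _cd_solve(
    gram: np.ndarray,
    cov: np.ndarray,
    alpha: np.ndarray | float,
    coef0: np.ndarray | None = None,
    max_iter: int = 1000,
    tol: float = 1e-10,
) -> np.ndarray:
    """Coordinate descent on the covariance form of the lasso.

    Parameters
    ----------
    gram : (k, k) array, X'X/n of the centred design.
    cov : (k, T) array, X'Y/n for T centred response columns.
    alpha : scalar or length-T penalty, one per response column.
    coef0 : optional (k, T) warm start.

    Returns the (k, T) coefficient matrix.
    """
    k, n_targets = cov.shape
    coef = np.zeros((k, n_targets)) if coef0 is None else coef0.copy()
    diag = np.diag(gram).copy()
    zero_var = diag <= 0
    diag[zero_var] = 1.0  # constant columns get coefficient 0 below
    for _ in range(max_iter):
        max_delta = 0.0
        max_coef = 0.0
        for j in range(k):
            old = coef[j].copy()
            # residual covariance of coordinate j with coordinate j removed
            rho = cov[j] - gram[j] @ coef + diag[j] * old
            new = _soft_threshold(rho, alpha) / diag[j]
            if zero_var[j]:
                new = np.zeros_like(new)
            coef[j] = new
            max_delta = max(max_delta, float(np.max(np.abs(new - old), initial=0.0)))
            max_coef = max(max_coef, float(np.max(np.abs(new), initial=0.0)))
        if max_delta <= tol * max(max_coef, 1.0):
            break
    return coef


def lasso_fit(
    X: np.ndarray,
    Y: np.ndarray,
    alpha: np.ndarray | float,
    max_iter: int = 1000,
    tol: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray]:
    """Lasso with intercept for each column of ``Y`` at a fixed penalty.

    ``X`` is used as given (no internal rescaling), matching the
    parametrisation of ``sklearn.linear_model.Lasso(alpha, fit_intercept=True)``.
    Returns ``(coef, intercept)`` with shapes (k, T) and (T,).
    """
    X = np.asarray(X, dtype=float)
    Y = np.atleast_2d(np.asarray(Y, dtype=float).T).T
    x_mean = X.mean(axis=0)
    y_mean = Y.mean(axis=0)
    Xc = X - x_mean
    Yc = Y - y_mean
    n = X.shape[0]
    gram = Xc.T @ Xc / n
    cov = Xc.T @ Yc / n
    coef = _cd_solve(gram, cov, np.broadcast_to(np.atleast_1d(alpha), (Y.shape[1],)),
                     max_iter=max_iter, tol=tol)
    intercept = y_mean - x_mean @ coef
    return coef, intercept


@dataclass
class LassoCVResult:
    """Fitted cross-validated lasso for a batch of response columns."""

    coef: np.ndarray        # (k, T), on the original X scale
    intercept: np.ndarray   # (T,)
    alpha: np.ndarray       # (T,) selected penalty per response

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.coef + self.intercept


def _alpha_grid(cov_abs_max: np.ndarray, n_alphas: int, eps: float) -> np.ndarray:
    """Per-target geometric penalty path from alpha_max down to eps*alpha_max."""
    amax = np.maximum(cov_abs_max, 1e-12)
    ratios = np.logspace(0.0, np.log10(eps), n_alphas)
    return amax[None, :] * ratios[:, None]  # (n_alphas, T), descending


def lasso_cv(
    X: np.ndarray,
    Y: np.ndarray,
    n_alphas: int = 30,
    eps: float = 1e-3,
    cv: int = 5,
    rng: np.random.Generator | None = None,
    max_iter: int = 1000,
    tol: float = 1e-9,
) -> LassoCVResult:
    """K-fold cross-validated lasso for every column of ``Y``.

    Columns of ``X`` are standardised internally (the penalty path is defined
    on the standardised scale); returned coefficients are mapped back to the
    original scale.  The penalty minimising the summed validation squared
    error across folds is selected per response column, ties resolved toward
    the larger (sparser) penalty.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    X = np.asarray(X, dtype=float)
    Y = np.atleast_2d(np.asarray(Y, dtype=float).T).T
    n, k = X.shape
    n_targets = Y.shape[1]

    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    Xs = X / scale

    full_cov = np.abs((Xs - Xs.mean(axis=0)).T @ (Y - Y.mean(axis=0)) / n)
    grid = _alpha_grid(full_cov.max(axis=0), n_alphas, eps)

    order = rng.permutation(n)
    folds = np.array_split(order, cv)
    cv_sse = np.zeros((n_alphas, n_targets))
    for val_idx in folds:
        mask = np.ones(n, dtype=bool)
        mask[val_idx] = False
        Xtr, Ytr = Xs[mask], Y[mask]
        Xva, Yva = Xs[val_idx], Y[val_idx]
        xm, ym = Xtr.mean(axis=0), Ytr.mean(axis=0)
        Xc, Yc = Xtr - xm, Ytr - ym
        ntr = Xc.shape[0]
        gram = Xc.T @ Xc / ntr
        cov = Xc.T @ Yc / ntr
        Xva_c = Xva - xm
        coef = None
        for a in range(n_alphas):
            coef = _cd_solve(gram, cov, grid[a], coef0=coef, max_iter=max_iter, tol=tol)
            resid = (Yva - ym) - Xva_c @ coef
            cv_sse[a] += np.einsum("ij,ij->j", resid, resid)

    # first index attaining the minimum == largest penalty among ties
    best = np.argmin(cv_sse, axis=0)
    alpha_sel = grid[best, np.arange(n_targets)]

    xm, ym = Xs.mean(axis=0), Y.mean(axis=0)
    Xc, Yc = Xs - xm, Y - ym
    gram = Xc.T @ Xc / n
    cov = Xc.T @ Yc / n
    coef = _cd_solve(gram, cov, alpha_sel, max_iter=max_iter, tol=tol)
    coef = coef / scale[:, None]
    intercept = ym - X.mean(axis=0) @ coef
    return LassoCVResult(coef=coef, intercept=intercept, alpha=alpha_sel)
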