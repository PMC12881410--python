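"""De-confounded per-marker effect estimation and stability screening.

Each marker's effect on the trait is estimated under the partially linear
model

    Y = theta * D + g(X) + zeta,      D = m(X) + nu,

where D is the marker dosage and X the principal-component confounder
scores.  Cross-fitted lasso regressions estimate the nuisance functions g
and m; the de-confounded effect is the partialling-out estimator

    theta_hat = sum(nu_hat * y_tilde) / sum(nu_hat^2)

with the sandwich variance sum(psi^2) / (sum(nu_hat^2))^2,
psi = nu_hat * (y_tilde - theta_hat * nu_hat), and a normal-approximation
p-value.  The screen repeats the whole cross-fitting ``n_rep`` times with
fresh fold assignments and retains markers whose p-value clears the
significance threshold in at least a ``stability_pi`` fraction of
repetitions (stability selection).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._lasso import lasso_cv
from .io import marker_positions

__all__ = [
    "PLRFit",
    "ScreenConfig",
    "dml_plr_single",
    "dml_plr_batch",
    "run_screen",
    "naive_scan",
    "genomic_inflation",
    "bonferroni_threshold",
    "screening_report",
]

_Z975 = 1.96


@dataclass
class PLRFit:
    """Cross-fitted partially-linear-model fit for one marker."""

    theta: float
    se: float
    p: float
    ci_low: float
    ci_high: float
    n_eff: int
    degenerate: bool = False


@dataclass
class ScreenConfig:
    n_rep: int = 100
    n_folds: int = 5
    p_thresh: float = 1e-4
    stability_pi: float = 0.8
    n_pcs: int = 10
    nuisance: str = "lasso_cv"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if not (0 < self.p_thresh < 1 and 0 < self.stability_pi <= 1):
            raise ValueError("thresholds must lie in (0, 1)")
        if self.nuisance != "lasso_cv":
            raise ValueError(f"unknown nuisance learner {self.nuisance!r}")


def _fold_assignment(n: int, n_folds: int, seed: int) -> list[np.ndarray]:
    """Fold indices as a pure function of (n, n_folds, seed): a fixed
    seed-keyed shuffle split into contiguous chunks."""
    order = np.random.default_rng(seed % 2**31).permutation(n)
    return np.array_split(order, n_folds)


def dml_plr_batch(
    y: np.ndarray,
    D: np.ndarray,
    X: np.ndarray,
    n_folds: int = 5,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Cross-fitted partialling-out estimates for every column of ``D``.

    Returns arrays theta, se, p, ci_low, ci_high and a degenerate flag
    (markers whose residual treatment variance vanishes — e.g. constant
    dosage or dosage fully explained by X — get theta 0 and p 1).
    """
    y = np.asarray(y, dtype=float)
    D = np.atleast_2d(np.asarray(D, dtype=float).T).T
    X = np.asarray(X, dtype=float)
    n, n_markers = D.shape
    if len(y) != n or X.shape[0] != n:
        raise ValueError("y, D and X must share the sample dimension")
    if n <= n_folds:
        raise ValueError("need more samples than folds")

    y_res = np.empty(n)
    d_res = np.empty((n, n_markers))
    rng = np.random.default_rng((seed + 1) % 2**31)
    for fold in _fold_assignment(n, n_folds, seed):
        mask = np.ones(n, dtype=bool)
        mask[fold] = False
        targets = np.column_stack([y[mask], D[mask]])
        fit = lasso_cv(X[mask], targets, rng=rng)
        pred = fit.predict(X[fold])
        y_res[fold] = y[fold] - pred[:, 0]
        d_res[fold] = D[fold] - pred[:, 1:]

    nu2 = np.einsum("ij,ij->j", d_res, d_res)
    # degenerate when the residual treatment variance is a negligible share
    # of the dosage variance (constant marker, or dosage explained by X up
    # to lasso solver error)
    d_var = ((D - D.mean(axis=0)) ** 2).sum(axis=0)
    degenerate = nu2 <= np.maximum(1e-4 * d_var, 1e-12 * n)
    nu2_safe = np.where(degenerate, 1.0, nu2)
    theta = (d_res * y_res[:, None]).sum(axis=0) / nu2_safe
    psi = d_res * (y_res[:, None] - theta[None, :] * d_res)
    # HC1-style small-sample correction: the two cross-fitted nuisance
    # regressions consume ~(k+1) parameters each, which the plain sandwich
    # ignores and which otherwise inflates the null statistics at n ~ 500
    k = X.shape[1]
    dof = max(n - 2 * (k + 1), 1)
    var = (n / dof) * np.einsum("ij,ij->j", psi, psi) / nu2_safe**2
    se = np.sqrt(np.maximum(var, np.finfo(float).tiny))
    z = np.where(se > 0, theta / se, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.clip(p, np.finfo(float).tiny, 1.0)

    theta = np.where(degenerate, 0.0, theta)
    se = np.where(degenerate, np.nan, se)
    p = np.where(degenerate, 1.0, p)
    return {
        "theta": theta,
        "se": se,
        "p": p,
        "ci_low": theta - _Z975 * se,
        "ci_high": theta + _Z975 * se,
        "degenerate": degenerate,
        "n_eff": np.full(n_markers, n),
    }


def dml_plr_single(
    y: np.ndarray, d: np.ndarray, X: np.ndarray, n_folds: int = 5, seed: int = 0
) -> PLRFit:
    """Partially-linear-model fit for a single marker (see ``dml_plr_batch``)."""
    res = dml_plr_batch(y, np.asarray(d, dtype=float).reshape(-1, 1), X,
                        n_folds=n_folds, seed=seed)
    return PLRFit(
        theta=float(res["theta"][0]),
        se=float(res["se"][0]),
        p=float(res["p"][0]),
        ci_low=float(res["ci_low"][0]),
        ci_high=float(res["ci_high"][0]),
        n_eff=int(res["n_eff"][0]),
        degenerate=bool(res["degenerate"][0]),
    )


def run_screen(
    dosages: pd.DataFrame,
    phenotype: pd.Series,
    pcs: pd.DataFrame,
    config: ScreenConfig | None = None,
) -> pd.DataFrame:
    """Stability-selection screen over all markers.

    Repetition r reruns the cross-fitted estimator with fold assignment
    seeded from ``seed + r``; ``stability_freq`` is the fraction of
    repetitions with p below ``p_thresh`` and a marker is selected when that
    fraction reaches ``stability_pi``.  The reported per-marker effect,
    standard error and p-value come from the repetition whose p-value is the
    (lower) median across repetitions — a stable summary that avoids the
    optimism of the minimum.  Output is sorted by genome position.
    """
    config = config or ScreenConfig()
    if not dosages.index.equals(phenotype.index) or not dosages.index.equals(pcs.index):
        raise ValueError("dosages, phenotype and PC scores must share individual IDs")
    y = phenotype.to_numpy(dtype=float)
    D = dosages.to_numpy(dtype=float)
    if np.isnan(D).any():
        raise ValueError("impute missing dosages before screening")
    X = pcs.to_numpy(dtype=float)[:, : config.n_pcs]

    n_rep, m = config.n_rep, D.shape[1]
    thetas = np.empty((n_rep, m))
    ses = np.empty((n_rep, m))
    ps = np.empty((n_rep, m))
    degen = np.zeros(m, dtype=bool)
    for r in range(n_rep):
        res = dml_plr_batch(y, D, X, n_folds=config.n_folds,
                            seed=(config.seed + r) % 2**31)
        thetas[r], ses[r], ps[r] = res["theta"], res["se"], res["p"]
        degen |= res["degenerate"]

    stability_freq = (ps < config.p_thresh).mean(axis=0)
    selected = (stability_freq >= config.stability_pi) & ~degen
    order = np.argsort(ps, axis=0, kind="stable")
    med = order[(n_rep - 1) // 2, np.arange(m)]
    cols = np.arange(m)
    theta = thetas[med, cols]
    se = ses[med, cols]
    p = ps[med, cols]

    table = pd.DataFrame({
        "marker_id": dosages.columns,
        "theta": theta,
        "se": se,
        "p": p,
        "ci_low": theta - _Z975 * se,
        "ci_high": theta + _Z975 * se,
        "stability_freq": stability_freq,
        "selected": selected,
        "degenerate": degen,
    })
    pos = marker_positions(dosages.columns)
    table = table.join(pos, on="marker_id")
    return table.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)


def naive_scan(dosages: pd.DataFrame, phenotype: pd.Series) -> pd.DataFrame:
    """Unadjusted per-marker simple regression (y ~ dosage), the associative
    baseline the de-confounded screen is compared against."""
    y = phenotype.to_numpy(dtype=float)
    D = dosages.to_numpy(dtype=float)
    n = len(y)
    yc = y - y.mean()
    Dc = D - D.mean(axis=0)
    ssd = np.einsum("ij,ij->j", Dc, Dc)
    ssd_safe = np.where(ssd > 0, ssd, 1.0)
    beta = yc @ Dc / ssd_safe
    resid2 = (yc**2).sum() - beta**2 * ssd_safe
    sigma2 = np.maximum(resid2, 0.0) / max(n - 2, 1)
    se = np.sqrt(sigma2 / ssd_safe)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, 0.0)
    p = np.clip(2.0 * stats.t.sf(np.abs(t), df=n - 2), np.finfo(float).tiny, 1.0)
    p = np.where(ssd > 0, p, 1.0)
    return pd.DataFrame({"marker_id": dosages.columns, "beta": beta,
                         "se": se, "p": p})


def genomic_inflation(pvals: np.ndarray) -> float:
    """Genomic inflation factor: median of the chi-square(1) statistics
    implied by the p-values over the null chi-square(1) median."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if (p <= 0).any():
        warnings.warn("p-values of 0 clamped to the smallest positive float")
        p = np.clip(p, np.finfo(float).tiny, 1.0)
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / stats.chi2.ppf(0.5, df=1))


def bonferroni_threshold(n_markers: int, alpha: float = 0.05) -> float:
    if n_markers < 1:
        raise ValueError("n_markers must be >= 1")
    return alpha / n_markers


def screening_report(table: pd.DataFrame, top_k: int = 20) -> dict[str, pd.DataFrame]:
    """Plot-ready diagnostic tables: Manhattan, Q-Q (with lambda_GC), volcano
    and forest (top selected markers with confidence intervals)."""
    if table.empty:
        raise ValueError("empty screening table")
    neglog = -np.log10(table["p"].to_numpy())
    manhattan = table[["chrom", "pos", "marker_id"]].copy()
    manhattan["neglog10_p"] = neglog

    p_sorted = np.sort(table["p"].to_numpy())
    m = len(p_sorted)
    expected = (np.arange(1, m + 1) - 0.5) / m
    qq = pd.DataFrame({
        "expected_neglog10_p": -np.log10(expected),
        "observed_neglog10_p": -np.log10(p_sorted),
    })
    qq["lambda_gc"] = genomic_inflation(table["p"].to_numpy())

    volcano = table[["marker_id", "chrom", "theta"]].copy()
    volcano["neglog10_p"] = neglog
    volcano["significant"] = table["p"].to_numpy() < 0.05

    forest = table[table["selected"]].sort_values("p", kind="stable").head(top_k)
    forest = forest[["marker_id", "theta", "ci_low", "ci_high", "se", "p"]].reset_index(drop=True)
    return {"manhattan": manhattan, "qq": qq, "volcano": volcano, "forest": forest}
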