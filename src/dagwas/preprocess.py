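"""Quality control, imputation, PC confounders and spatial BLUP adjustment.

Filters follow the standard dosage-marker QC recipe: markers with strictly
more than 10% missing calls are dropped first, then markers with minor
allele frequency strictly below 0.05 (frequency estimated as mean non-missing
dosage / 4, so exactly-at-threshold markers are retained in both cases).
Principal components are computed on centred, unit-variance markers and
serve as the confounding covariates of the partially linear screening model.
The spatial adjustment is a deliberately lightweight row/column random-effects
mixed model fitted by EM-REML — a simplified stand-in for a full spatial
REML package, adequate for de-noising replicated plot scores into per-genotype
BLUPs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "QCReport",
    "PCMatrix",
    "filter_call_rate",
    "filter_maf",
    "run_qc",
    "impute_mean",
    "compute_pcs",
    "spatial_adjust",
]


@dataclass
class QCReport:
    n_markers_in: int
    n_removed_call_rate: int
    n_removed_maf: int
    n_markers_out: int
    call_rate: pd.Series
    maf: pd.Series
    removed_call_rate: list[str] = field(default_factory=list)
    removed_maf: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"call_rate": self.call_rate, "maf": self.maf})
        df["removed"] = "retained"
        df.loc[df.index.isin(self.removed_call_rate), "removed"] = "call_rate"
        df.loc[df.index.isin(self.removed_maf), "removed"] = "maf"
        df.index.name = "marker_id"
        return df


@dataclass
class PCMatrix:
    scores: pd.DataFrame                  # individuals x k
    explained_variance_ratio: np.ndarray  # length k, nonincreasing

    @property
    def k(self) -> int:
        return self.scores.shape[1]


def _check_nonempty(X: pd.DataFrame) -> None:
    if X.shape[0] == 0 or X.shape[1] == 0:
        raise ValueError("empty dosage matrix")


def filter_call_rate(
    X: pd.DataFrame, max_missing: float = 0.10
) -> tuple[pd.DataFrame, list[str]]:
    """Drop markers whose missing fraction is strictly greater than
    ``max_missing``; column order of survivors is preserved."""
    _check_nonempty(X)
    if not 0.0 <= max_missing <= 1.0:
        raise ValueError("max_missing must lie in [0, 1]")
    missing_frac = X.isna().mean(axis=0)
    removed = list(X.columns[missing_frac > max_missing])
    return X.drop(columns=removed), removed


def marker_maf(X: pd.DataFrame) -> pd.Series:
    """Minor allele frequency per marker: min(p, 1-p) with
    p = mean(non-missing dosage)/4.  All-missing markers get NaN."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        p_hat = X.mean(axis=0, skipna=True) / 4.0
    return np.minimum(p_hat, 1.0 - p_hat)


def filter_maf(
    X: pd.DataFrame, min_maf: float = 0.05
) -> tuple[pd.DataFrame, list[str]]:
    """Drop markers with MAF strictly below ``min_maf``.  Markers with no
    non-missing calls are removed with a warning."""
    _check_nonempty(X)
    maf = marker_maf(X)
    all_missing = list(X.columns[maf.isna()])
    if all_missing:
        warnings.warn(f"{len(all_missing)} marker(s) with no non-missing calls removed")
    removed = list(X.columns[(maf < min_maf) | maf.isna()])
    return X.drop(columns=removed), removed


def run_qc(
    X: pd.DataFrame, max_missing: float = 0.10, min_maf: float = 0.05
) -> tuple[pd.DataFrame, QCReport]:
    """Sequential QC: call-rate filter, then MAF filter on the survivors."""
    call_rate = 1.0 - X.isna().mean(axis=0)
    X1, removed_cr = filter_call_rate(X, max_missing)
    maf = marker_maf(X1)
    if X1.shape[1] == 0:  # every marker failed the call-rate filter
        X2, removed_maf = X1, []
    else:
        X2, removed_maf = filter_maf(X1, min_maf)
    report = QCReport(
        n_markers_in=X.shape[1],
        n_removed_call_rate=len(removed_cr),
        n_removed_maf=len(removed_maf),
        n_markers_out=X2.shape[1],
        call_rate=call_rate,
        maf=maf.reindex(X.columns),
        removed_call_rate=removed_cr,
        removed_maf=removed_maf,
    )
    return X2, report


def impute_mean(X: pd.DataFrame) -> pd.DataFrame:
    """Replace missing calls by the marker's non-missing mean (real valued;
    dosages are treated as quasi-continuous downstream)."""
    if X.isna().all(axis=0).any():
        raise ValueError("all-missing marker present; run QC first")
    if not X.isna().to_numpy().any():
        return X.copy()
    return X.fillna(X.mean(axis=0, skipna=True))


def compute_pcs(X: pd.DataFrame, k: int = 10) -> PCMatrix:
    """Leading principal components of the marker matrix.

    Markers are centred and scaled to unit variance (constant markers are
    left at zero), scores are U * S from the thin SVD.  Column signs follow
    the convention that each component's largest-magnitude marker loading is
    positive, which makes the decomposition fully deterministic.
    """
    n, m = X.shape
    if X.isna().to_numpy().any():
        raise ValueError("impute missing dosages before PCA")
    if not 1 <= k <= min(n - 1, m):
        raise ValueError(f"k must lie in [1, {min(n - 1, m)}]")
    vals = X.to_numpy(dtype=float)
    vals = vals - vals.mean(axis=0)
    sd = vals.std(axis=0)
    sd[sd == 0] = 1.0
    vals = vals / sd
    u, s, vt = np.linalg.svd(vals, full_matrices=False)
    for j in range(k):
        lead = np.argmax(np.abs(vt[j]))
        if vt[j, lead] < 0:
            vt[j] = -vt[j]
            u[:, j] = -u[:, j]
    scores = u[:, :k] * s[:k]
    evr = (s**2 / max((s**2).sum(), np.finfo(float).tiny))[:k]
    return PCMatrix(
        scores=pd.DataFrame(scores, index=X.index,
                            columns=[f"PC{j + 1}" for j in range(k)]),
        explained_variance_ratio=evr,
    )


# ---------------------------------------------------------------------------
# spatial adjustment


def spatial_adjust(
    plots: pd.DataFrame,
    value_col: str = "value",
    tol: float = 1e-6,
    max_iter: int = 500,
) -> tuple[pd.Series, dict[str, float]]:
    """Per-genotype BLUPs from a row/column random-effects model.

    Fits y = mu + g + r + c + e with independent random genotype, row and
    column effects via Henderson's mixed-model equations, the variance
    components estimated by EM-REML (convergence when the relative change of
    every component falls below ``tol``).  Returns the genotype predictions
    on the trait scale (mu + BLUP) and the estimated variance components.
    """
    required = {"genotype_id", "row", "column", value_col}
    if missing := required - set(plots.columns):
        raise ValueError(f"plot table missing columns: {sorted(missing)}")
    y = plots[value_col].to_numpy(dtype=float)
    n = len(y)
    if n < 2:
        raise ValueError("need at least two plots to fit the spatial model")

    factors = {}
    Zs = {}
    for name, col in (("genotype", "genotype_id"), ("row", "row"), ("column", "column")):
        codes, levels = pd.factorize(plots[col], sort=True)
        Z = np.zeros((n, len(levels)))
        Z[np.arange(n), codes] = 1.0
        factors[name] = levels
        Zs[name] = Z

    X = np.ones((n, 1))
    Z = np.hstack([Zs[k] for k in ("genotype", "row", "column")])
    q = {k: Zs[k].shape[1] for k in Zs}
    offsets = np.cumsum([0, q["genotype"], q["row"], q["column"]])

    var = {"genotype": np.var(y) / 2, "row": np.var(y) / 4,
           "column": np.var(y) / 4, "residual": np.var(y) / 2}
    floor = 1e-8 * max(np.var(y), 1.0)

    W = np.hstack([X, Z])
    WtW = W.T @ W
    Wty = W.T @ y
    p_fixed = X.shape[1]

    for _ in range(max_iter):
        lam = np.concatenate([
            np.zeros(p_fixed),
            np.full(q["genotype"], var["residual"] / max(var["genotype"], floor)),
            np.full(q["row"], var["residual"] / max(var["row"], floor)),
            np.full(q["column"], var["residual"] / max(var["column"], floor)),
        ])
        C = WtW + np.diag(lam)
        try:
            Cinv = np.linalg.inv(C)
        except np.linalg.LinAlgError as err:
            raise ValueError("singular mixed-model equations "
                             "(too few plots or confounded design)") from err
        sol = Cinv @ Wty
        beta, u = sol[:p_fixed], sol[p_fixed:]
        resid = y - X @ beta - Z @ u

        new = {}
        for i, name in enumerate(("genotype", "row", "column")):
            sl = slice(p_fixed + offsets[i], p_fixed + offsets[i + 1])
            uk = sol[sl]
            tr = np.trace(Cinv[sl, sl])
            new[name] = max((uk @ uk + var["residual"] * tr) / q[name], floor)
        # REML residual update in the y'Py = y'(y - W sol) form
        new["residual"] = max(float(y @ (y - W @ sol)) / (n - p_fixed), floor)

        delta = max(abs(new[k] - var[k]) / max(var[k], floor) for k in var)
        var = new
        if delta < tol:
            break

    g_slice = slice(p_fixed, p_fixed + q["genotype"])
    blups = pd.Series(beta[0] + sol[g_slice], index=pd.Index(factors["genotype"],
                      name="genotype_id"), name="blup")
    return blups, {f"var_{k}": float(v) for k, v in var.items()}
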