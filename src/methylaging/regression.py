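"""Per-CpG linear model of percent methylation on age (aDMP calling).

Each CpG is modelled independently by ordinary least squares:

    pct_methylation ~ age + covariates

with categorical covariates expanded to indicator columns. The age
coefficient (percentage points per year), its standard error and a
two-sided t-test p-value are reported per locus, with Benjamini-Hochberg
q-values across loci; loci with p below ``alpha`` (default 0.05) are the
age-associated differentially methylated positions (aDMPs). Missing
entries (uncovered loci) are dropped listwise per locus.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["fit_admp", "bh_adjust", "build_design"]


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg q-values; NaN entries propagate and are not
    counted toward the number of tests."""
    p = np.asarray(p_values, dtype=float)
    finite = np.isfinite(p)
    if np.any((p[finite] < 0) | (p[finite] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full(p.shape, np.nan)
    if finite.any():
        q[finite] = multipletests(p[finite], method="fdr_bh")[1]
    return q


def build_design(samples: pd.DataFrame, covariates: list[str]) -> tuple[np.ndarray, list[str]]:
    """Intercept + age + covariate design matrix (categoricals expanded to
    drop-first indicator columns)."""
    cols = [np.ones(len(samples)), samples["age"].to_numpy(float)]
    names = ["intercept", "age"]
    for cov in covariates:
        if cov not in samples.columns:
            raise ValueError(f"covariate {cov!r} not in sample table")
        col = samples[cov]
        if col.dtype.kind in "if":
            if col.isna().any():
                raise ValueError(f"covariate {cov!r} has missing values")
            cols.append(col.to_numpy(float))
            names.append(cov)
        else:
            dummies = pd.get_dummies(col.astype(str), prefix=cov, drop_first=True)
            for name in dummies.columns:
                cols.append(dummies[name].to_numpy(float))
                names.append(name)
    return np.column_stack(cols), names


def fit_admp(
    pct_matrix: np.ndarray,
    samples: pd.DataFrame,
    covariates: list[str] | None = None,
    alpha: float = 0.05,
    loci: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Fit the per-CpG age model over a loci x samples percent matrix.

    Returns one row per locus: beta_age, se, t, p, q, n_used, flag,
    significant (p < alpha). Rows are ordered as the input loci. Loci whose
    usable sample count is below (number of model terms + 2), or with
    zero-variance response, or a rank-deficient design after listwise
    deletion, get NaN statistics and a flag, and are excluded from the
    multiplicity correction.
    """
    P = np.asarray(pct_matrix, dtype=float)
    if P.ndim != 2 or P.shape[1] != len(samples):
        raise ValueError("pct_matrix must be loci x samples matching the table")
    covariates = list(covariates or [])
    X, names = build_design(samples, covariates)
    n_terms = X.shape[1] - 1          # model terms excluding the intercept
    n_params = X.shape[1]
    L = P.shape[0]

    beta = np.full(L, np.nan)
    se = np.full(L, np.nan)
    tval = np.full(L, np.nan)
    pval = np.full(L, np.nan)
    n_used = np.zeros(L, dtype=int)
    flag = np.array([""] * L, dtype=object)

    finite = np.isfinite(P)
    patterns, inverse = np.unique(finite, axis=0, return_inverse=True)
    for pi in range(patterns.shape[0]):
        rows = np.where(inverse == pi)[0]
        idx = np.where(patterns[pi])[0]
        n = len(idx)
        n_used[rows] = n
        if n < n_terms + 2:
            flag[rows] = "insufficient-samples"
            continue
        Xp = X[idx]
        # rank via SVD once per missingness pattern
        svals = np.linalg.svd(Xp, compute_uv=False)
        if svals[-1] < 1e-10 * svals[0]:
            flag[rows] = "collinear"
            continue
        XtX_inv = np.linalg.inv(Xp.T @ Xp)
        Y = P[np.ix_(rows, idx)].T                        # n x loci
        B = XtX_inv @ (Xp.T @ Y)                          # params x loci
        resid = Y - Xp @ B
        dof = n - n_params
        sigma2 = (resid ** 2).sum(axis=0) / dof
        se_age = np.sqrt(np.maximum(sigma2 * XtX_inv[1, 1], 0.0))
        zero_var = np.ptp(Y, axis=0) == 0
        with np.errstate(divide="ignore", invalid="ignore"):
            t_here = np.where(se_age > 0, B[1] / se_age, np.nan)
        p_here = 2.0 * stats.t.sf(np.abs(t_here), dof)
        beta[rows] = np.where(zero_var, np.nan, B[1])
        se[rows] = np.where(zero_var, np.nan, se_age)
        tval[rows] = np.where(zero_var, np.nan, t_here)
        pval[rows] = np.where(zero_var, np.nan, p_here)
        flag[rows[zero_var]] = "zero-variance"
        # an exact fit with nonzero slope: se == 0 -> p ~ 0 at machine precision
        exact = (~zero_var) & (se_age == 0)
        pval[rows[exact]] = 0.0
        tval[rows[exact]] = np.inf * np.sign(B[1][exact])

    qval = bh_adjust(pval)
    out = pd.DataFrame({
        "beta_age": beta,
        "se": se,
        "t_value": tval,
        "p_value": pval,
        "q_value": qval,
        "n_used": n_used,
        "flag": flag,
    })
    out["significant"] = out["p_value"] < alpha
    if loci is not None:
        out.insert(0, "chrom", np.asarray(loci["chrom"]))
        out.insert(1, "pos", np.asarray(loci["pos"]))
    return out
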