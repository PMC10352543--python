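"""Sliding-window age-course differential analysis (SWAN).

A window of fixed width (default 10 years) is moved along the cohort's age
axis in 1-year steps. At each center age the feature matrix (percent
methylation, or any feature x sample matrix such as protein abundances) is
tested between two subject groups; the per-center count of features
passing a Benjamini-Hochberg q < 0.05 traces when in the life course
features change.

Two grouping modes are provided:

* ``adjacent`` (default): the younger window [c - w, c) against the older
  window [c, c + w). The contrast peaks at ages where feature levels
  *change* (onsets/offsets of an age-localised effect).
* ``centered``: subjects with |age - c| <= w/2 against all other subjects,
  which peaks where an age-localised deviation is centred.

The per-feature test is the OLS linear model ``value ~ intercept + group``;
its group-coefficient t-test is algebraically the pooled two-sample t-test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .regression import bh_adjust, build_design

__all__ = ["SwanConfig", "SwanProfile", "swan_centers", "swan_test", "swan_profile"]


@dataclass(frozen=True)
class SwanConfig:
    window_width: float = 10.0
    step: float = 1.0
    q_alpha: float = 0.05
    min_per_window: int = 5
    covariates: tuple[str, ...] | None = None
    mode: str = "adjacent"          # or "centered"

    def __post_init__(self) -> None:
        if self.window_width <= 0 or self.step <= 0:
            raise ValueError("window_width and step must be positive")
        if self.min_per_window < 2:
            raise ValueError("min_per_window must be >= 2")
        if self.mode not in ("adjacent", "centered"):
            raise ValueError(f"unknown SWAN mode {self.mode!r}")


@dataclass
class SwanProfile:
    centers: np.ndarray
    n_tested: np.ndarray
    n_significant: np.ndarray
    p_values: pd.DataFrame          # features x centers
    union_set: np.ndarray           # feature indices significant at >= 1 center

    @property
    def peak_center(self) -> float:
        return float(self.centers[int(np.argmax(self.n_significant))])


def _window_masks(ages: np.ndarray, center: float, config: SwanConfig):
    if config.mode == "adjacent":
        young = (ages >= center - config.window_width) & (ages < center)
        old = (ages >= center) & (ages < center + config.window_width)
    else:
        inside = np.abs(ages - center) <= config.window_width / 2.0
        young, old = ~inside, inside
    return young, old


def swan_centers(ages, config: SwanConfig = SwanConfig()) -> np.ndarray:
    """Valid center ages: grid points (integer ages for step=1) whose two
    windows lie inside the observed age range and each hold at least
    ``min_per_window`` subjects. Centers whose windows would extend past
    the data are excluded (they would only report edge artefacts)."""
    ages = np.asarray(ages, dtype=float)
    if len(ages) < 2 * config.min_per_window:
        raise ValueError("too few subjects for any sliding window")
    lo, hi = float(ages.min()), float(ages.max())
    if config.mode == "adjacent":
        first = np.ceil((lo + config.window_width) / config.step) * config.step
        last = np.floor((hi - config.window_width) / config.step) * config.step
    else:
        half = config.window_width / 2.0
        first = np.ceil((lo + half) / config.step) * config.step
        last = np.floor((hi - half) / config.step) * config.step
    centers = []
    c = first
    while c <= last + 1e-9:
        yw, ow = _window_masks(ages, c, config)
        if yw.sum() >= config.min_per_window and ow.sum() >= config.min_per_window:
            centers.append(c)
        c += config.step
    if not centers:
        raise ValueError("no valid sliding-window centers for these ages")
    return np.asarray(centers)


def swan_test(feature_matrix, ages, center: float,
              config: SwanConfig = SwanConfig(),
              samples: pd.DataFrame | None = None) -> np.ndarray:
    """Per-feature two-sided p-values for the window contrast at ``center``.

    Degenerate features: zero pooled variance with a nonzero mean
    difference gives p=0 (perfect separation); a feature constant across
    both windows gives t=0, p=1; a window dropping below ``min_per_window``
    usable values gives NaN.
    """
    F = np.asarray(feature_matrix, dtype=float)
    ages = np.asarray(ages, dtype=float)
    young, old = _window_masks(ages, center, config)
    if config.covariates:
        return _swan_test_covariates(F, young, old, config, samples)
    return _pooled_t_pvalues(F[:, young], F[:, old], config.min_per_window)


def _pooled_t_pvalues(Y0: np.ndarray, Y1: np.ndarray, min_n: int) -> np.ndarray:
    """Closed form of the group-indicator OLS t-test (pooled two-sample t),
    nan-aware per feature."""
    n0 = np.isfinite(Y0).sum(axis=1)
    n1 = np.isfinite(Y1).sum(axis=1)
    with np.errstate(invalid="ignore"):
        m0 = np.nansum(Y0, axis=1) / n0
        m1 = np.nansum(Y1, axis=1) / n1
        ss0 = np.nansum((Y0 - m0[:, None]) ** 2, axis=1)
        ss1 = np.nansum((Y1 - m1[:, None]) ** 2, axis=1)
    ok = (n0 >= min_n) & (n1 >= min_n)
    p = np.full(Y0.shape[0], np.nan)
    dof = n0 + n1 - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        s2 = (ss0 + ss1) / dof
        se = np.sqrt(s2 * (1.0 / n0 + 1.0 / n1))
        diff = m1 - m0
        t = diff / se
    reg = ok & (se > 0)
    p[reg] = 2.0 * stats.t.sf(np.abs(t[reg]), dof[reg])
    sep = ok & (se == 0) & (diff != 0)
    p[sep] = 0.0
    const = ok & (se == 0) & (diff == 0)
    p[const] = 1.0
    return p


def _swan_test_covariates(F, young, old, config, samples):
    if samples is None:
        raise ValueError("covariate adjustment requires the sample table")
    used = young | old
    sub = samples.loc[used].reset_index(drop=True)
    X_cov, _ = build_design(sub, list(config.covariates))
    indicator = old[used].astype(float)
    X = np.column_stack([X_cov[:, 0], indicator, X_cov[:, 2:]])  # drop age term
    Fm = F[:, used]
    L = Fm.shape[0]
    p = np.full(L, np.nan)
    n_params = X.shape[1]
    for j in range(L):
        fin = np.isfinite(Fm[j])
        if fin[indicator == 1].sum() < config.min_per_window:
            continue
        if fin[indicator == 0].sum() < config.min_per_window:
            continue
        Xj, yj = X[fin], Fm[j, fin]
        dof = len(yj) - n_params
        if dof < 1:
            continue
        XtX_inv = np.linalg.pinv(Xj.T @ Xj)
        b = XtX_inv @ Xj.T @ yj
        resid = yj - Xj @ b
        sigma2 = resid @ resid / dof
        se = np.sqrt(sigma2 * XtX_inv[1, 1])
        if se == 0:
            p[j] = 1.0 if b[1] == 0 else 0.0
        else:
            p[j] = 2.0 * stats.t.sf(abs(b[1] / se), dof)
    return p


def swan_profile(feature_matrix, ages, config: SwanConfig = SwanConfig(),
                 samples: pd.DataFrame | None = None,
                 feature_ids: list | None = None) -> SwanProfile:
    """Run the contrast at every valid center with per-center BH correction."""
    F = np.asarray(feature_matrix, dtype=float)
    centers = swan_centers(ages, config)
    n_feat = F.shape[0]
    pmat = np.full((n_feat, len(centers)), np.nan)
    n_sig = np.zeros(len(centers), dtype=int)
    n_tested = np.zeros(len(centers), dtype=int)
    union = np.zeros(n_feat, dtype=bool)
    for ci, c in enumerate(centers):
        p = swan_test(F, ages, c, config, samples=samples)
        pmat[:, ci] = p
        q = bh_adjust(p)
        sig = np.nan_to_num(q, nan=1.0) < config.q_alpha
        n_sig[ci] = int(sig.sum())
        n_tested[ci] = int(np.isfinite(p).sum())
        union |= sig
    ids = feature_ids if feature_ids is not None else list(range(n_feat))
    pdf = pd.DataFrame(pmat, index=ids, columns=[f"{c:g}" for c in centers])
    return SwanProfile(centers, n_tested, n_sig, pdf, np.where(union)[0])
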