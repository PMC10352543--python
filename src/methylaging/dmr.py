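"""Smoothing-based two-group DMR detection.

The young-vs-old regional analysis follows the local-regression smoothing
approach for WGBS data: per sample, raw methylated fractions are smoothed
along the genome with a coverage-weighted local quadratic (tricube
kernel), imputing uncovered CpGs from their neighbours; a t-like statistic
is then formed at each locus from the difference in smoothed group means
scaled by the young-group baseline standard deviation (variability is
assumed to grow with age, so the young group anchors the variance
estimate); a running-mean local correction removes large-scale drift; and
maximal runs of consecutive, same-sign loci with |t| above the cutoff
(default 4.6) and inter-CpG gaps at most 300 bp are emitted as DMRs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import MethylationDataset

logger = logging.getLogger(__name__)

__all__ = [
    "SmoothParams",
    "TStatParams",
    "DMRecord",
    "cluster_loci",
    "smooth_sample",
    "smooth_dataset",
    "split_groups",
    "tstat",
    "local_correct",
    "call_dmrs",
    "find_dmrs",
]


@dataclass(frozen=True)
class SmoothParams:
    min_loci: int = 70
    min_width: int = 1000
    cluster_maxgap: int = 10**8
    degree: int = 2
    coverage_weighting: bool = True

    def __post_init__(self) -> None:
        if self.min_loci < 2:
            raise ValueError("min_loci must be >= 2")
        if self.min_width < 1:
            raise ValueError("min_width must be >= 1")


@dataclass(frozen=True)
class TStatParams:
    cutoff: float = 4.6
    dmr_maxgap: int = 300
    sd_floor_quantile: float = 0.75
    local_correct: bool = True
    correct_halfwidth: int = 50
    min_cpgs_per_dmr: int = 1
    old_threshold_age: float = 53.0
    inclusive: bool = True          # old group is age >= threshold (else >)
    scale_two_sample: bool = True   # multiply young sd by sqrt(1/n_y + 1/n_o)

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if self.dmr_maxgap < 1:
            raise ValueError("dmr_maxgap must be >= 1")


@dataclass(frozen=True)
class DMRecord:
    chrom: str
    start: int                      # 1-based inclusive
    end: int
    n_cpgs: int
    direction: str                  # hyper|hypo, old relative to young
    mean_diff: float                # smoothed old - young mean, fraction units
    area_stat: float                # sum of corrected t over member CpGs


def cluster_loci(chrom, pos, cluster_maxgap: int = 10**8) -> np.ndarray:
    """Label runs of same-chromosome loci whose consecutive gaps are at most
    ``cluster_maxgap``; chromosome boundaries always split."""
    chrom = np.asarray(chrom, dtype=object)
    pos = np.asarray(pos, dtype=np.int64)
    if len(pos) == 0:
        return np.zeros(0, dtype=np.int64)
    new = np.ones(len(pos), dtype=bool)
    same_chrom = chrom[1:] == chrom[:-1]
    gap_ok = np.diff(pos) <= cluster_maxgap
    new[1:] = ~(same_chrom & gap_ok)
    return np.cumsum(new) - 1


def _window_bounds(pos: np.ndarray, min_loci: int, min_width: int):
    """Per locus, the smallest symmetric-in-count window holding at least
    ``min_loci`` loci and spanning at least ``min_width`` bp, truncated at
    the cluster boundaries."""
    m = len(pos)
    need = min(min_loci, m)
    half = (need - 1) // 2
    lo = np.empty(m, dtype=np.int64)
    hi = np.empty(m, dtype=np.int64)
    for j in range(m):
        l = j - half
        h = l + need - 1
        if l < 0:
            h -= l
            l = 0
        if h > m - 1:
            l -= h - (m - 1)
            h = m - 1
            l = max(l, 0)
        while pos[h] - pos[l] < min_width and (l > 0 or h < m - 1):
            left = pos[j] - pos[l - 1] if l > 0 else np.iinfo(np.int64).max
            right = pos[h + 1] - pos[j] if h < m - 1 else np.iinfo(np.int64).max
            if left <= right:
                l -= 1
            else:
                h += 1
        lo[j], hi[j] = l, h
    return lo, hi


def _smooth_cluster(pos: np.ndarray, M: np.ndarray, N: np.ndarray,
                    params: SmoothParams):
    """Smooth one cluster for all samples at once. Returns (smoothed, flags)
    where flags marks samples that fell back to the cluster mean."""
    m, S = M.shape
    covered = N > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(covered, M / np.where(N > 0, N, 1), 0.0)
    out = np.full((m, S), np.nan)
    flags = np.zeros(S, dtype=bool)

    cov_per_sample = covered.sum(axis=0)
    fallback = cov_per_sample < 3
    weights_base = N.astype(float) if params.coverage_weighting else covered.astype(float)
    for s in np.where(fallback)[0]:
        flags[s] = True
        w = weights_base[:, s]
        if w.sum() > 0:
            out[:, s] = np.average(frac[:, s], weights=w)
        # else: no coverage at all in this cluster -> NaN
    active = np.where(~fallback)[0]
    if len(active) == 0:
        return np.clip(out, 0, 1, out=out), flags

    lo, hi = _window_bounds(pos, params.min_loci, params.min_width)
    Wb = weights_base[:, active]
    Fr = frac[:, active]
    Cv = covered[:, active]
    for j in range(m):
        sl = slice(lo[j], hi[j] + 1)
        d = (pos[sl] - pos[j]).astype(float)
        h = max(np.abs(d).max(), params.min_width / 2.0, 1.0)
        x = d / h
        kern = np.clip(1.0 - np.abs(x) ** 3, 0.0, None) ** 3
        kern = np.maximum(kern, 1e-8)       # keep boundary loci in the fit
        W = Wb[sl] * kern[:, None]          # window x samples
        npos = (Cv[sl]).sum(axis=0)
        X = np.column_stack([np.ones_like(x), x, x * x][: params.degree + 1])
        ok = npos >= X.shape[1]
        if ok.any():
            Wok = W[:, ok]
            A = np.einsum("ws,wi,wj->sij", Wok, X, X)
            b = np.einsum("ws,ws,wi->si", Wok, Fr[sl][:, ok], X)
            try:
                beta = np.linalg.solve(A, b[:, :, None])[:, :, 0]
                out[j, active[ok]] = beta[:, 0]
            except np.linalg.LinAlgError:
                for k, s in enumerate(np.where(ok)[0]):
                    coef, *_ = np.linalg.lstsq(
                        X * np.sqrt(W[:, s])[:, None],
                        Fr[sl][:, s] * np.sqrt(W[:, s]), rcond=None)
                    out[j, active[s]] = coef[0]
        weak = ~ok
        if weak.any():
            for s in np.where(weak)[0]:
                w = W[:, s]
                if w[Cv[sl][:, s]].sum() > 0:
                    out[j, active[s]] = np.average(Fr[sl][:, s], weights=w)
    return np.clip(out, 0.0, 1.0, out=out), flags


def smooth_dataset(dataset: MethylationDataset, params: SmoothParams = SmoothParams(),
                   clusters: np.ndarray | None = None) -> np.ndarray:
    """Smoothed methylated fractions (loci x samples) over every cluster."""
    if clusters is None:
        clusters = cluster_loci(dataset.chrom, dataset.pos, params.cluster_maxgap)
    out = np.full((dataset.n_loci, dataset.n_samples), np.nan)
    for cl in np.unique(clusters):
        idx = np.where(clusters == cl)[0]
        sm, flags = _smooth_cluster(
            dataset.pos[idx], dataset.M[idx].astype(float),
            dataset.N[idx].astype(float), params)
        out[idx] = sm
        if flags.any():
            logger.debug("cluster %d: %d sample(s) fell back to cluster mean",
                         cl, int(flags.sum()))
    return out


def smooth_sample(pos, M_col, N_col, params: SmoothParams = SmoothParams()) -> np.ndarray:
    """Smooth a single sample's counts over one pre-clustered locus run."""
    pos = np.asarray(pos, dtype=np.int64)
    M = np.asarray(M_col, dtype=float)[:, None]
    N = np.asarray(N_col, dtype=float)[:, None]
    sm, _ = _smooth_cluster(pos, M, N, params)
    return sm[:, 0]


def split_groups(samples: pd.DataFrame, old_threshold_age: float,
                 inclusive: bool = True) -> tuple[list[str], list[str]]:
    """Young/old subject-id split at a threshold age. ``inclusive`` puts
    subjects exactly at the threshold in the old group (age >= threshold);
    otherwise old means age > threshold."""
    ages = samples["age"].to_numpy(float)
    old_mask = ages >= old_threshold_age if inclusive else ages > old_threshold_age
    young = samples.loc[~old_mask, "subject_id"].tolist()
    old = samples.loc[old_mask, "subject_id"].tolist()
    if not young or not old:
        raise ValueError("age threshold leaves an empty group")
    return young, old


def tstat(smoothed: np.ndarray, young_idx, old_idx,
          params: TStatParams = TStatParams()) -> np.ndarray:
    """Per-locus t-like statistic: (old mean - young mean) / denominator.

    The denominator is the young-group standard deviation of smoothed
    values (scaled by sqrt(1/n_y + 1/n_o) for two-sample consistency),
    floored at the ``sd_floor_quantile`` quantile of all per-locus
    denominators so near-zero-variance loci cannot explode. Positive t
    means hypermethylated in old.
    """
    young_idx = np.asarray(young_idx, dtype=int)
    old_idx = np.asarray(old_idx, dtype=int)
    if len(young_idx) < 2 or len(old_idx) < 2:
        raise ValueError("need at least 2 samples per group")
    ym = np.nanmean(smoothed[:, young_idx], axis=1)
    om = np.nanmean(smoothed[:, old_idx], axis=1)
    sd = np.nanstd(smoothed[:, young_idx], axis=1, ddof=1)
    if params.scale_two_sample:
        sd = sd * np.sqrt(1.0 / len(young_idx) + 1.0 / len(old_idx))
    finite = np.isfinite(sd)
    if not finite.any():
        raise ValueError("no finite per-locus standard deviations")
    floor = np.nanquantile(sd[finite], params.sd_floor_quantile)
    if floor <= 0:
        positive = sd[finite][sd[finite] > 0]
        floor = positive.min() if len(positive) else 1.0
    denom = np.maximum(sd, floor)
    return (om - ym) / denom


def local_correct(t_values: np.ndarray, clusters: np.ndarray,
                  params: TStatParams = TStatParams()) -> np.ndarray:
    """Subtract a running mean of t over +/- ``correct_halfwidth`` loci
    within each cluster (window shrinks at cluster edges); identity when
    ``local_correct`` is off."""
    if not params.local_correct:
        return np.asarray(t_values, dtype=float).copy()
    t = np.asarray(t_values, dtype=float)
    out = np.empty_like(t)
    hw = params.correct_halfwidth
    for cl in np.unique(clusters):
        idx = np.where(clusters == cl)[0]
        tc = t[idx]
        m = len(tc)
        c = np.concatenate([[0.0], np.cumsum(np.nan_to_num(tc))])
        cnt = np.concatenate([[0], np.cumsum(np.isfinite(tc).astype(int))])
        j = np.arange(m)
        loj = np.maximum(j - hw, 0)
        hij = np.minimum(j + hw, m - 1)
        sums = c[hij + 1] - c[loj]
        ns = cnt[hij + 1] - cnt[loj]
        with np.errstate(invalid="ignore", divide="ignore"):
            run_mean = np.where(ns > 0, sums / ns, 0.0)
        out[idx] = tc - run_mean
    return out


def call_dmrs(corrected_t: np.ndarray, mean_diff: np.ndarray, chrom, pos,
              clusters: np.ndarray, params: TStatParams = TStatParams()) -> list[DMRecord]:
    """Emit maximal runs of consecutive loci with |t| >= cutoff, constant
    sign, gaps <= ``dmr_maxgap`` bp, within one cluster."""
    t = np.asarray(corrected_t, dtype=float)
    diff = np.asarray(mean_diff, dtype=float)
    chrom = np.asarray(chrom, dtype=object)
    pos = np.asarray(pos, dtype=np.int64)
    L = len(t)
    records: list[DMRecord] = []
    run: list[int] = []

    def flush():
        if len(run) >= params.min_cpgs_per_dmr:
            idx = np.asarray(run)
            area = float(t[idx].sum())
            records.append(DMRecord(
                chrom=str(chrom[idx[0]]),
                start=int(pos[idx[0]]),
                end=int(pos[idx[-1]]),
                n_cpgs=len(idx),
                direction="hyper" if area > 0 else "hypo",
                mean_diff=float(np.nanmean(diff[idx])),
                area_stat=area,
            ))
        run.clear()

    for j in range(L):
        passing = np.isfinite(t[j]) and abs(t[j]) >= params.cutoff
        if not passing:
            flush()
            continue
        if run:
            prev = run[-1]
            same_run = (
                clusters[j] == clusters[prev]
                and chrom[j] == chrom[prev]
                and pos[j] - pos[prev] <= params.dmr_maxgap
                and np.sign(t[j]) == np.sign(t[prev])
            )
            if not same_run:
                flush()
        run.append(j)
    flush()
    return records


def dmrs_to_frame(records: list[DMRecord]) -> pd.DataFrame:
    cols = ["chrom", "start", "end", "n_cpgs", "direction", "mean_diff", "area_stat"]
    return pd.DataFrame([{c: getattr(r, c) for c in cols} for r in records],
                        columns=cols)


def find_dmrs(dataset: MethylationDataset, samples: pd.DataFrame,
              smooth_params: SmoothParams = SmoothParams(),
              tparams: TStatParams = TStatParams()):
    """End-to-end regional analysis on a coverage-filtered dataset.

    Returns ``(records, track)`` where ``track`` is a per-locus DataFrame
    with smoothed group means, raw and corrected t.
    """
    samples = samples.set_index("subject_id", drop=False).loc[dataset.sample_ids].reset_index(drop=True)
    clusters = cluster_loci(dataset.chrom, dataset.pos, smooth_params.cluster_maxgap)
    smoothed = smooth_dataset(dataset, smooth_params, clusters)
    young_ids, old_ids = split_groups(samples, tparams.old_threshold_age, tparams.inclusive)
    young_idx = [dataset.sample_index(s) for s in young_ids]
    old_idx = [dataset.sample_index(s) for s in old_ids]
    raw_t = tstat(smoothed, young_idx, old_idx, tparams)
    corrected = local_correct(raw_t, clusters, tparams)
    mean_diff = (np.nanmean(smoothed[:, old_idx], axis=1)
                 - np.nanmean(smoothed[:, young_idx], axis=1))
    records = call_dmrs(corrected, mean_diff, dataset.chrom, dataset.pos,
                        clusters, tparams)
    track = pd.DataFrame({
        "chrom": dataset.chrom,
        "pos": dataset.pos,
        "cluster": clusters,
        "young_mean": np.nanmean(smoothed[:, young_idx], axis=1),
        "old_mean": np.nanmean(smoothed[:, old_idx], axis=1),
        "t_raw": raw_t,
        "t_corrected": corrected,
    })
    return records, track
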