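"""Coverage filtering, covariate construction and spike-in QC.

These steps run between dataset assembly and any statistics: the per-CpG
regression and the sliding-window analysis use a 10x-in-all-samples
coverage filter, the DMR analysis a 2x filter; percent methylation is
100*M/N with N=0 entries missing; bisulfite conversion efficiency is
monitored from an unmethylated spike-in contig.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import MethylationDataset

logger = logging.getLogger(__name__)

__all__ = [
    "CoveragePolicy",
    "filter_coverage",
    "fiber_ratio",
    "conversion_efficiency",
    "percent_methylation",
    "qc_report",
]


@dataclass(frozen=True)
class CoveragePolicy:
    """Minimum read depth required, by default in every sample.

    ``min_fraction`` relaxes the all-samples scope: a locus is kept when at
    least that fraction of samples meets ``min_coverage`` (1.0 = literal
    "all samples").
    """

    min_coverage: int = 10
    min_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.min_coverage < 1:
            raise ValueError("min_coverage must be >= 1")
        if not (0 < self.min_fraction <= 1):
            raise ValueError("min_fraction must be in (0, 1]")


def filter_coverage(dataset: MethylationDataset, policy: CoveragePolicy) -> MethylationDataset:
    """Retain loci meeting the coverage policy; locus order is preserved."""
    ok = dataset.N >= policy.min_coverage
    if policy.min_fraction >= 1.0:
        keep = ok.all(axis=1)
    else:
        need = math.ceil(policy.min_fraction * dataset.n_samples)
        keep = ok.sum(axis=1) >= need
    if not keep.any():
        logger.warning("coverage filter %sx removed every locus", policy.min_coverage)
    return dataset.subset_loci(keep)


def fiber_ratio(my7: float, my1: float, my2: float, my4: float) -> float:
    """Slow-fiber proxy: Myosin-7 over the sum of the fast isoforms
    (Myosin 1 + Myosin 2 + Myosin 4). NaN when the denominator is zero
    (subject flagged by the caller)."""
    if min(my7, my1, my2, my4) < 0:
        raise ValueError("myosin abundances must be non-negative")
    denom = my1 + my2 + my4
    if denom == 0:
        return float("nan")
    return my7 / denom


def conversion_efficiency(dataset: MethylationDataset, spike_contig: str) -> pd.Series:
    """Per-sample bisulfite conversion rate from an unmethylated spike-in.

    rate_s = 1 - sum_j M_sj / sum_j N_sj over spike-contig loci; NaN where
    the spike has no coverage in a sample.
    """
    on_spike = dataset.chrom == spike_contig
    if not on_spike.any():
        raise ValueError(f"spike contig {spike_contig!r} absent from dataset")
    m = dataset.M[on_spike].sum(axis=0).astype(float)
    n = dataset.N[on_spike].sum(axis=0).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = np.where(n > 0, 1.0 - m / n, np.nan)
    return pd.Series(rate, index=dataset.sample_ids, name="conversion_rate")


def percent_methylation(dataset: MethylationDataset) -> np.ndarray:
    """Loci x samples percent methylation (100*M/N); NaN where N=0."""
    M = dataset.M.astype(float)
    N = dataset.N.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = np.where(N > 0, 100.0 * M / N, np.nan)
    return pct


def qc_report(dataset: MethylationDataset, policies: dict[str, CoveragePolicy],
              spike_contig: str | None = None) -> pd.DataFrame:
    """Per-sample QC summary: mean coverage, loci surviving each policy,
    and conversion rate if a spike contig is present."""
    rows = pd.DataFrame({
        "sample_id": dataset.sample_ids,
        "mean_coverage": dataset.N.mean(axis=0),
        "covered_loci": (dataset.N > 0).sum(axis=0),
    })
    for name, pol in policies.items():
        survived = filter_coverage(dataset, pol).n_loci
        rows[f"loci_pass_{name}"] = survived
    if spike_contig is not None and (dataset.chrom == spike_contig).any():
        rows["conversion_rate"] = conversion_efficiency(dataset, spike_contig).to_numpy()
    return rows
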