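"""Synthetic WGBS cohorts with planted aging effects.

The generator emulates the study design the analyses assume: ~40 subjects
evenly spread over ages 22-83, ~10x Poisson read depth, CpGs clustered in
islands (low baseline methylation) against a sparse open sea (high
baseline), and three planted effect classes:

* ``linear``  - percent methylation drifts linearly with age,
* ``wave``    - a transient offset for subjects within ``half_width`` years
  of a center age (an age-window effect),
* ``dmr``     - a regional step between the young and old groups over a run
  of neighbouring CpGs.

Effects are specified in percentage points at the locus baseline and
converted to logit offsets, so that at the baseline the planted percent
change is exact: ``offset = logit(p0 + delta/100) - logit(p0)``. Counts are
binomial over a Poisson coverage, with per-subject-per-locus Gaussian logit
noise giving beta-binomial-like overdispersion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .core import GeneModel, IslandSet, MethylationDataset
from . import io as mio

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "simulate_genome",
    "simulate_cohort",
    "simulate_methylation",
    "simulate_all",
    "write_simulation",
]


@dataclass
class SimulationConfig:
    """Knobs of the synthetic cohort; defaults mirror the emulated study."""

    seed: int = 0
    n_subjects: int = 40
    age_min: float = 22.0
    age_max: float = 83.0
    ages: list[float] | None = None          # explicit ages override sampling
    n_chroms: int = 2
    chrom_length: int = 1_000_000
    n_cpgs: int = 5000
    island_count: int = 20
    island_width: int = 1500
    island_cpg_fraction: float = 0.5         # CpGs placed inside islands
    n_genes: int = 30
    gene_length: int = 20_000
    coverage_mean: float = 10.0
    logit_noise_sd: float = 0.3
    island_baseline: float = 0.15            # mean methylated fraction, islands
    opensea_baseline: float = 0.85
    baseline_jitter_sd: float = 0.5          # per-locus logit jitter
    planted_linear: list[tuple[int, float]] = field(default_factory=list)
    planted_wave: list[tuple[int, float, float, float]] = field(default_factory=list)
    planted_dmr: list[tuple[int, int, int, float, float]] = field(default_factory=list)
    batch_effect_sd: float = 0.0
    n_batches: int = 2
    bmi_mean: float = 27.0
    bmi_sd: float = 4.0
    spike_contig: str | None = "lambda"      # unmethylated spike-in contig
    spike_n_cpgs: int = 50
    spike_error: float = 0.005               # apparent methylation on spike
    genome_seed: int = 9001                  # layout seed, separate from counts

    def __post_init__(self) -> None:
        if self.age_min >= self.age_max:
            raise ValueError("age_min must be < age_max")
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")
        for planted in (self.planted_linear, self.planted_wave):
            for rec in planted:
                if not (0 <= rec[0] < self.n_cpgs):
                    raise ValueError(f"planted locus index {rec[0]} out of range")
        for rec in self.planted_wave:
            if not (-100 < rec[3] < 100):
                raise ValueError("wave delta must be in (-100, 100) points")


def simulate_genome(config: SimulationConfig):
    """Place islands, island-enriched CpGs and genes on each chromosome.

    Returns ``(loci, genes, islands)`` with loci as a (chrom, pos) DataFrame
    sorted by coordinate. CpG density is higher inside islands than in the
    open sea. Genome layout is a function of the structural config fields
    only (its own ``genome_seed``), so replicates that differ only in
    ``seed`` share coordinates and differ in counts.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.genome_seed, 101]))
    chroms = [f"chr{i + 1}" for i in range(config.n_chroms)]
    total_island_span = config.island_count * config.island_width
    if total_island_span > config.n_chroms * config.chrom_length // 2:
        raise ValueError("islands do not fit in the simulated genome")

    islands: list[tuple[str, int, int]] = []
    per_chrom = np.array_split(np.arange(config.island_count), config.n_chroms)
    for chrom, idxs in zip(chroms, per_chrom):
        k = len(idxs)
        if k == 0:
            continue
        # evenly spaced slots with jitter, keeping islands well separated
        slots = np.linspace(0.1, 0.9, k) * config.chrom_length
        spacing = slots[1] - slots[0] if k > 1 else 0.8 * config.chrom_length
        if k > 1 and spacing <= 2 * config.island_width:
            raise ValueError("island placement infeasible: islands would abut")
        jitter = rng.uniform(-0.2, 0.2, size=k) * max(spacing - config.island_width, 0)
        starts = np.clip(slots + jitter, 1, config.chrom_length - config.island_width)
        for s in np.sort(starts):
            islands.append((chrom, int(s), int(s) + config.island_width - 1))
    island_set = IslandSet.from_intervals(islands)
    if len(island_set) != len(islands):
        raise ValueError("island placement produced overlapping islands")

    n_island_cpgs = int(round(config.n_cpgs * config.island_cpg_fraction))
    n_sea_cpgs = config.n_cpgs - n_island_cpgs
    rows: list[tuple[str, int]] = []
    if islands:
        share = np.array_split(np.arange(n_island_cpgs), len(islands))
        for (chrom, s, e), idxs in zip(islands, share):
            k = len(idxs)
            if k == 0:
                continue
            if k > (e - s + 1):
                raise ValueError("island too narrow for requested CpG count")
            pos = np.sort(rng.choice(np.arange(s, e + 1), size=k, replace=False))
            rows += [(chrom, int(p)) for p in pos]
    else:
        n_sea_cpgs = config.n_cpgs
    sea_per_chrom = np.array_split(np.arange(n_sea_cpgs), config.n_chroms)
    island_lookup = {c: [(s, e) for cc, s, e in island_set if cc == c] for c in chroms}
    for chrom, idxs in zip(chroms, sea_per_chrom):
        k = len(idxs)
        got = 0
        while got < k:
            cand = rng.integers(1, config.chrom_length + 1, size=2 * (k - got))
            for p in cand:
                if any(s <= p <= e for s, e in island_lookup[chrom]):
                    continue
                rows.append((chrom, int(p)))
                got += 1
                if got == k:
                    break
    loci = (
        pd.DataFrame(rows, columns=["chrom", "pos"])
        .drop_duplicates()
        .sort_values(["chrom", "pos"], kind="mergesort")
        .reset_index(drop=True)
    )

    genes: list[GeneModel] = []
    gene_per_chrom = np.array_split(np.arange(config.n_genes), config.n_chroms)
    for chrom, idxs in zip(chroms, gene_per_chrom):
        k = len(idxs)
        if k == 0:
            continue
        max_start = config.chrom_length - config.gene_length
        if max_start < 1:
            raise ValueError("gene_length exceeds chrom_length")
        starts = np.sort(rng.integers(1, max_start, size=k))
        strands = rng.choice(["+", "-"], size=k)
        for gi, (s, st) in enumerate(zip(starts, strands)):
            genes.append(GeneModel(
                f"GENE_{chrom}_{gi:03d}", chrom, int(s),
                int(s) + config.gene_length - 1, str(st),
            ))
    return loci, genes, island_set


def simulate_cohort(config: SimulationConfig) -> pd.DataFrame:
    """Draw the subject table: ages, sex, race, BMI, batch, fiber ratio."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 202]))
    n = config.n_subjects
    if config.ages is not None:
        ages = np.asarray(config.ages, dtype=float)
        if len(ages) != n:
            raise ValueError("explicit age list length != n_subjects")
    else:
        ages = rng.uniform(config.age_min, config.age_max, size=n)
    sex = rng.choice(["F", "M"], size=n)
    race = rng.choice(["A", "B", "C"], size=n, p=[0.5, 0.3, 0.2])
    bmi = rng.normal(config.bmi_mean, config.bmi_sd, size=n)
    batch = rng.integers(0, config.n_batches, size=n)
    # slow fiber fraction rises mildly with age
    fiber = np.clip(0.45 + 0.002 * (ages - 50.0) + rng.normal(0, 0.05, size=n), 0, 1)
    return pd.DataFrame({
        "subject_id": [f"S{i:03d}" for i in range(n)],
        "age": ages,
        "sex": sex,
        "race": race,
        "bmi": bmi,
        "batch": [f"b{b}" for b in batch],
        "tissue": "muscle",
        "fiber_ratio": fiber,
    })


def _delta_to_logit_offset(baseline: np.ndarray, delta_points: float) -> np.ndarray:
    """Logit offset reproducing a shift of ``delta_points`` percentage points
    exactly at the baseline fraction (targets clamped into (0.001, 0.999))."""
    target = baseline + delta_points / 100.0
    clamped = np.clip(target, 0.001, 0.999)
    if np.any(clamped != target):
        logger.debug("planted effect clamped to keep fraction inside (0,1)")
    return logit(clamped) - logit(np.clip(baseline, 0.001, 0.999))


def simulate_methylation(config: SimulationConfig, loci: pd.DataFrame,
                         cohort: pd.DataFrame, islands: IslandSet | None = None):
    """Draw counts for every locus x subject and return the truth ledger.

    Model: p_sj = expit(a_j + b_j*(age_s - age_mid) + wave_j(age_s)
    + step_j(age_s) + batch_s,j + eps_sj); N_sj ~ Poisson(coverage_mean);
    M_sj ~ Binomial(N_sj, p_sj).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 303]))
    L = len(loci)
    S = len(cohort)
    ages = cohort["age"].to_numpy(float)
    age_mid = 0.5 * (config.age_min + config.age_max)

    in_island = np.zeros(L, dtype=bool)
    if islands is not None:
        for chrom, s, e in islands:
            sel = (loci["chrom"] == chrom) & (loci["pos"] >= s) & (loci["pos"] <= e)
            in_island |= sel.to_numpy()
    base_mean = np.where(in_island, config.island_baseline, config.opensea_baseline)
    a = logit(base_mean) + rng.normal(0, config.baseline_jitter_sd, size=L)
    baseline = expit(a)

    eta = np.tile(a[:, None], (1, S)).astype(float)
    effect_class = np.array(["none"] * L, dtype=object)
    effect_param = [""] * L

    for j, slope_pts in config.planted_linear:
        # slope in percentage points / year, linearised at the baseline
        b_logit = (slope_pts / 100.0) / (baseline[j] * (1 - baseline[j]))
        eta[j] += b_logit * (ages - age_mid)
        effect_class[j] = "linear"
        effect_param[j] = f"slope={slope_pts}"

    for j, center, half_width, delta in config.planted_wave:
        offset = _delta_to_logit_offset(baseline[j], delta)
        inside = np.abs(ages - center) <= half_width
        eta[j, inside] += offset
        effect_class[j] = "wave"
        effect_param[j] = f"center={center};half_width={half_width};delta={delta}"

    for start_idx, end_idx, delta, threshold in _normalise_dmrs(config, loci):
        for j in range(start_idx, end_idx + 1):
            offset = _delta_to_logit_offset(baseline[j], delta)
            old = ages >= threshold
            eta[j, old] += offset
            effect_class[j] = "dmr"
            effect_param[j] = f"delta={delta};threshold={threshold}"

    if config.batch_effect_sd > 0:
        batches = pd.Categorical(cohort["batch"]).codes
        offsets = rng.normal(0, config.batch_effect_sd, size=(L, batches.max() + 1))
        eta += offsets[:, batches]

    eta += rng.normal(0, config.logit_noise_sd, size=(L, S))
    p = expit(eta)
    N = rng.poisson(config.coverage_mean, size=(L, S))
    M = rng.binomial(N, p)

    chrom = loci["chrom"].to_numpy(object)
    pos = loci["pos"].to_numpy(np.int64)
    sample_ids = cohort["subject_id"].tolist()

    if config.spike_contig:
        sp_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 404]))
        sp_pos = np.sort(sp_rng.choice(
            np.arange(1, 48_502), size=config.spike_n_cpgs, replace=False))
        sp_N = sp_rng.poisson(config.coverage_mean, size=(config.spike_n_cpgs, S))
        sp_M = sp_rng.binomial(sp_N, config.spike_error)
        chrom = np.concatenate([chrom, np.array([config.spike_contig] * config.spike_n_cpgs, dtype=object)])
        pos = np.concatenate([pos, sp_pos])
        M = np.vstack([M, sp_M])
        N = np.vstack([N, sp_N])
        order = np.lexsort((pos, chrom.astype(str)))
        chrom, pos, M, N = chrom[order], pos[order], M[order], N[order]

    dataset = MethylationDataset(chrom, pos, sample_ids, M, N)

    truth = pd.DataFrame({
        "chrom": loci["chrom"],
        "pos": loci["pos"],
        "baseline_fraction": baseline,
        "effect_class": effect_class,
        "effect_param": effect_param,
    })
    return dataset, truth


def _normalise_dmrs(config: SimulationConfig, loci: pd.DataFrame):
    """Planted DMRs accept two forms: genomic
    ``(chrom, start, end, delta_points, old_threshold_age)`` or locus-index
    ``(start_index, end_index, delta_points, old_threshold_age)``. Returns
    inclusive locus-index ranges."""
    out = []
    for rec in config.planted_dmr:
        if len(rec) == 5 and isinstance(rec[0], str):
            chrom, start, end, delta, threshold = rec
            sel = np.where(
                (loci["chrom"] == chrom)
                & (loci["pos"] >= int(start)) & (loci["pos"] <= int(end))
            )[0]
            if len(sel) == 0:
                raise ValueError(f"planted DMR {rec} covers no simulated CpGs")
            start_idx, end_idx = int(sel[0]), int(sel[-1])
        elif len(rec) == 4:
            start_idx, end_idx, delta, threshold = (
                int(rec[0]), int(rec[1]), rec[2], rec[3])
        else:
            raise ValueError(f"unrecognised planted DMR record: {rec!r}")
        if start_idx > end_idx:
            raise ValueError("planted DMR start after end")
        if end_idx >= len(loci):
            raise ValueError("planted DMR index out of range")
        if not (-100 < float(delta) < 100):
            raise ValueError("dmr delta must be in (-100, 100) points")
        out.append((start_idx, end_idx, float(delta), float(threshold)))
    return out


def simulate_all(config: SimulationConfig):
    """Genome + cohort + counts in one call."""
    loci, genes, islands = simulate_genome(config)
    cohort = simulate_cohort(config)
    dataset, truth = simulate_methylation(config, loci, cohort, islands)
    return dataset, truth, cohort, genes, islands


def write_simulation(config: SimulationConfig, outdir) -> dict:
    """Emit cytosine reports, metadata, annotation BEDs, a small synthetic
    GMT built from the simulated genes, and the truth ledger."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dataset, truth, cohort, genes, islands = simulate_all(config)

    reports_dir = outdir / "reports"
    reports_dir.mkdir(exist_ok=True)
    report_paths = {}
    for sid in dataset.sample_ids:
        p = reports_dir / f"{sid}.CpG_report.txt"
        mio.write_cytosine_report(dataset, sid, p)
        report_paths[sid] = str(p)

    mio.write_metadata(cohort, outdir / "metadata.tsv")
    mio.write_bed(list(islands), outdir / "islands.bed")
    mio.write_bed(
        [(g.chrom, g.tx_start, g.tx_end) for g in genes],
        outdir / "genes.bed",
        names=[g.gene_id for g in genes],
        strands=[g.strand for g in genes],
    )
    mio.write_results_tsv(truth, outdir / "truth.tsv")

    gene_ids = [g.gene_id for g in genes]
    gmt_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 505]))
    sets = {}
    descriptions = {}
    for k in range(min(5, max(1, len(gene_ids) // 4))):
        size = max(2, min(len(gene_ids), int(gmt_rng.integers(3, 9))))
        members = sorted(gmt_rng.choice(gene_ids, size=size, replace=False).tolist())
        sets[f"SET_{k}"] = members
        descriptions[f"SET_{k}"] = "synthetic gene set"
    from .core import GeneSetCollection
    mio.write_gmt(GeneSetCollection(sets, descriptions), outdir / "genesets.gmt")

    return {
        "reports": report_paths,
        "metadata": str(outdir / "metadata.tsv"),
        "islands": str(outdir / "islands.bed"),
        "genes": str(outdir / "genes.bed"),
        "gmt": str(outdir / "genesets.gmt"),
        "truth": str(outdir / "truth.tsv"),
    }
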