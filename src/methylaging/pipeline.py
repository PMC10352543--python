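"""Stage orchestration shared by the CLI and scripted use.

Each stage reads its inputs from a :class:`RunConfig`, writes TSV/JSON
artifacts under ``outdir`` and returns a summary dict. All randomness
flows from the single config seed, so identical config + seed gives
byte-identical artifacts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotate as ann
from . import io as mio
from .core import MethylationDataset
from .dmr import SmoothParams, TStatParams, dmrs_to_frame, find_dmrs
from .preprocess import CoveragePolicy, filter_coverage, percent_methylation, qc_report
from .regression import fit_admp
from .simulate import SimulationConfig, write_simulation
from .swan import SwanConfig, swan_profile

logger = logging.getLogger(__name__)

STAGE_ORDER = ["qc", "regress", "swan", "dmr", "annotate", "enrich", "overlap"]


@dataclass
class RunConfig:
    seed: int = 0
    outdir: str = "methylaging_out"
    reports_dir: str | None = None
    metadata: str | None = None
    genes: str | None = None
    islands: str | None = None
    gmt: str | None = None
    spike_contig: str | None = "lambda"
    coverage_regression: int = 10
    coverage_swan: int = 10
    coverage_dmr: int = 2
    regression_covariates: list[str] = field(default_factory=lambda: ["sex", "race", "bmi"])
    regression_alpha: float = 0.05
    swan: SwanConfig = field(default_factory=SwanConfig)
    smooth: SmoothParams = field(default_factory=SmoothParams)
    tstat: TStatParams = field(default_factory=TStatParams)
    max_link_dist: int = 200
    enrich_alpha: float = 0.05
    simulation: SimulationConfig | None = None

    @classmethod
    def from_yaml(cls, path, overrides: dict | None = None) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update(overrides or {})
        kwargs = dict(raw)
        for key, klass in [("swan", SwanConfig), ("smooth", SmoothParams),
                           ("tstat", TStatParams)]:
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = klass(**kwargs[key])
        if "simulation" in kwargs and isinstance(kwargs["simulation"], dict):
            sim = dict(kwargs["simulation"])
            sim.setdefault("seed", kwargs.get("seed", 0))
            sim["planted_linear"] = [tuple(r) for r in sim.get("planted_linear", [])]
            sim["planted_wave"] = [tuple(r) for r in sim.get("planted_wave", [])]
            sim["planted_dmr"] = [tuple(r) for r in sim.get("planted_dmr", [])]
            kwargs["simulation"] = SimulationConfig(**sim)
        return cls(**kwargs)


def _out(config: RunConfig) -> Path:
    p = Path(config.outdir)
    p.mkdir(parents=True, exist_ok=True)
    return p


def _write_summary(config: RunConfig, stage: str, payload: dict) -> None:
    def default(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(type(o).__name__)

    path = _out(config) / f"{stage}_summary.json"
    with open(path, "w") as fh:
        json.dump({"stage": stage, "seed": config.seed, **payload},
                  fh, indent=2, sort_keys=True, default=default)
        fh.write("\n")


def _load_dataset(config: RunConfig) -> tuple[MethylationDataset, pd.DataFrame]:
    if config.reports_dir is None or config.metadata is None:
        raise FileNotFoundError("reports_dir and metadata must be set (run simulate first?)")
    reports_dir = Path(config.reports_dir)
    if not reports_dir.is_dir():
        raise FileNotFoundError(f"reports directory not found: {reports_dir}")
    samples = mio.read_metadata(config.metadata)
    paths = {}
    for sid in samples["subject_id"]:
        p = reports_dir / f"{sid}.CpG_report.txt"
        if not p.exists():
            raise FileNotFoundError(f"missing cytosine report: {p}")
        paths[sid] = p
    dataset = mio.read_dataset(paths)
    return dataset, samples


def _analysis_subset(dataset: MethylationDataset, config: RunConfig) -> MethylationDataset:
    """Drop the spike contig before any statistics."""
    if config.spike_contig is not None:
        return dataset.subset_loci(dataset.chrom != config.spike_contig)
    return dataset


def stage_simulate(config: RunConfig) -> dict:
    if config.simulation is None:
        raise ValueError("config has no simulation section")
    simdir = _out(config) / "sim"
    paths = write_simulation(config.simulation, simdir)
    config.reports_dir = str(simdir / "reports")
    config.metadata = paths["metadata"]
    config.genes = paths["genes"]
    config.islands = paths["islands"]
    if config.gmt is None:
        config.gmt = paths["gmt"]
    base = _out(config)

    def rel(v):
        if isinstance(v, dict):
            return {k: rel(x) for k, x in v.items()}
        try:
            return str(Path(v).relative_to(base))
        except ValueError:
            return str(v)

    summary = {"paths": rel(paths), "n_subjects": config.simulation.n_subjects,
               "n_cpgs": config.simulation.n_cpgs}
    _write_summary(config, "simulate", summary)
    return summary


def stage_qc(config: RunConfig) -> dict:
    dataset, _ = _load_dataset(config)
    policies = {
        f"{config.coverage_regression}x": CoveragePolicy(config.coverage_regression),
        f"{config.coverage_dmr}x": CoveragePolicy(config.coverage_dmr),
    }
    spike = config.spike_contig if (
        config.spike_contig and (dataset.chrom == config.spike_contig).any()) else None
    report = qc_report(_analysis_subset(dataset, config) if spike is None else dataset,
                       policies, spike_contig=spike)
    mio.write_results_tsv(report, _out(config) / "qc.tsv")
    summary = {"n_samples": dataset.n_samples, "n_loci": dataset.n_loci}
    _write_summary(config, "qc", summary)
    return summary


def stage_regress(config: RunConfig) -> dict:
    dataset, samples = _load_dataset(config)
    dataset = _analysis_subset(dataset, config)
    dataset = dataset.reorder_samples(samples["subject_id"].tolist())
    filt = filter_coverage(dataset, CoveragePolicy(config.coverage_regression))
    pct = percent_methylation(filt)
    loci = pd.DataFrame({"chrom": filt.chrom, "pos": filt.pos})
    covs = [c for c in config.regression_covariates if c in samples.columns]
    table = fit_admp(pct, samples, covs, alpha=config.regression_alpha, loci=loci)
    mio.write_results_tsv(table, _out(config) / "admp.tsv")
    summary = {
        "n_loci_tested": int(table["p_value"].notna().sum()),
        "n_significant": int(table["significant"].sum()),
        "covariates": covs,
        "alpha": config.regression_alpha,
    }
    _write_summary(config, "regress", summary)
    return summary


def stage_swan(config: RunConfig) -> dict:
    dataset, samples = _load_dataset(config)
    dataset = _analysis_subset(dataset, config)
    dataset = dataset.reorder_samples(samples["subject_id"].tolist())
    filt = filter_coverage(dataset, CoveragePolicy(config.coverage_swan))
    pct = percent_methylation(filt)
    ids = [f"{c}:{p}" for c, p in filt.locus_keys()]
    profile = swan_profile(pct, samples["age"].to_numpy(), config.swan,
                           samples=samples, feature_ids=ids)
    per_center = pd.DataFrame({
        "center": profile.centers,
        "n_tested": profile.n_tested,
        "n_significant": profile.n_significant,
    })
    mio.write_results_tsv(per_center, _out(config) / "swan_profile.tsv")
    long = profile.p_values.reset_index(names="locus").melt(
        id_vars="locus", var_name="center", value_name="p_value").dropna()
    mio.write_results_tsv(long, _out(config) / "swan_pvalues.tsv")
    union = pd.DataFrame({"locus": [ids[i] for i in profile.union_set]})
    mio.write_results_tsv(union, _out(config) / "swan_union.tsv")
    summary = {
        "n_centers": len(profile.centers),
        "peak_center": profile.peak_center,
        "union_size": len(profile.union_set),
    }
    _write_summary(config, "swan", summary)
    return summary


def stage_dmr(config: RunConfig) -> dict:
    dataset, samples = _load_dataset(config)
    dataset = _analysis_subset(dataset, config)
    dataset = dataset.reorder_samples(samples["subject_id"].tolist())
    filt = filter_coverage(dataset, CoveragePolicy(config.coverage_dmr))
    records, track = find_dmrs(filt, samples, config.smooth, config.tstat)
    frame = dmrs_to_frame(records)
    # BED-compatible on disk: 0-based half-open start
    disk = frame.copy()
    if len(disk):
        disk["start"] = disk["start"] - 1
    mio.write_results_tsv(disk, _out(config) / "dmrs.tsv")
    bedgraph = pd.DataFrame({
        "chrom": track["chrom"], "start": track["pos"] - 1,
        "end": track["pos"], "t": track["t_corrected"],
    })
    mio.write_results_tsv(bedgraph, _out(config) / "tstat.bedgraph.tsv")
    summary = {
        "n_dmrs": len(frame),
        "n_hyper": int((frame["direction"] == "hyper").sum()) if len(frame) else 0,
        "n_hypo": int((frame["direction"] == "hypo").sum()) if len(frame) else 0,
        "n_loci": filt.n_loci,
    }
    _write_summary(config, "dmr", summary)
    return summary


def _require(path, what):
    if path is None or not Path(path).exists():
        raise FileNotFoundError(f"{what} not found: {path}")
    return path


def _read_stage_outputs(config: RunConfig):
    out = _out(config)
    admp = pd.read_csv(out / "admp.tsv", sep="\t")
    dmrs = pd.read_csv(out / "dmrs.tsv", sep="\t")
    if len(dmrs):
        dmrs["start"] = dmrs["start"] + 1  # back to 1-based inclusive
    return admp, dmrs


def stage_annotate(config: RunConfig) -> dict:
    genes = mio.read_bed(_require(config.genes, "gene BED"), kind="genes")
    islands = mio.read_bed(_require(config.islands, "island BED"), kind="islands")
    admp, dmrs = _read_stage_outputs(config)

    sig = admp[admp["significant"] == True]  # noqa: E712
    admp_feats = list(zip(sig["chrom"], sig["pos"]))
    dmr_feats = list(zip(dmrs["chrom"], dmrs["start"], dmrs["end"])) if len(dmrs) else []

    results = {}
    for name, feats in [("admp", admp_feats), ("dmr", dmr_feats)]:
        links = ann.link_genes(feats, genes, config.max_link_dist)
        ctx = ann.classify_island_context(feats, islands)
        lf = ann.links_to_frame(links)
        mio.write_results_tsv(lf, _out(config) / f"{name}_gene_links.tsv")
        mio.write_results_tsv(ctx, _out(config) / f"{name}_island_context.tsv")
        results[name] = {
            "intragenic": ann.intragenic_fraction(links),
            "island_class_counts": ctx["island_class"].value_counts().to_dict(),
        }
    _write_summary(config, "annotate", results)
    return results


def stage_enrich(config: RunConfig) -> dict:
    gene_sets = mio.read_gmt(_require(config.gmt, "GMT file"))
    genes = mio.read_bed(_require(config.genes, "gene BED"), kind="genes")
    universe = sorted({g.gene_id for g in genes})
    links = pd.read_csv(_out(config) / "dmr_gene_links.tsv", sep="\t")
    selected = sorted(set(links["gene_id"].dropna()) & set(universe))
    table = ann.ora_hypergeometric(selected, universe, gene_sets)
    mio.write_results_tsv(table, _out(config) / "enrichment.tsv")
    summary = {"n_selected": len(selected), "n_sets": len(table),
               "n_enriched": int((table["q_value"] < config.enrich_alpha).sum()) if len(table) else 0}
    _write_summary(config, "enrich", summary)
    return summary


def stage_overlap(config: RunConfig) -> dict:
    out = _out(config)
    admp, dmrs = _read_stage_outputs(config)
    swan_union = pd.read_csv(out / "swan_union.tsv", sep="\t")

    def parse_key(s):
        c, p = s.rsplit(":", 1)
        return (c, int(p))

    admp_set = {(c, int(p)) for c, p in
                zip(admp.loc[admp["significant"] == True, "chrom"],  # noqa: E712
                    admp.loc[admp["significant"] == True, "pos"])}  # noqa: E712
    swan_set = {parse_key(s) for s in swan_union["locus"]} if len(swan_union) else set()
    all_keys = list(zip(admp["chrom"], admp["pos"]))
    dmr_set = ann.loci_in_regions(
        all_keys, list(zip(dmrs["chrom"], dmrs["start"], dmrs["end"]))) if len(dmrs) else set()
    venn = ann.overlap_analyses(admp_set, swan_set, dmr_set)
    with open(out / "venn.json", "w") as fh:
        json.dump(venn, fh, indent=2, sort_keys=True)
        fh.write("\n")
    _write_summary(config, "overlap", venn)
    return venn


STAGES = {
    "simulate": stage_simulate,
    "qc": stage_qc,
    "regress": stage_regress,
    "swan": stage_swan,
    "dmr": stage_dmr,
    "annotate": stage_annotate,
    "enrich": stage_enrich,
    "overlap": stage_overlap,
}


def run_all(config: RunConfig) -> dict:
    """Chain every stage (simulate first when configured)."""
    results = {}
    if config.simulation is not None:
        results["simulate"] = stage_simulate(config)
    for stage in STAGE_ORDER:
        results[stage] = STAGES[stage](config)
    return results
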