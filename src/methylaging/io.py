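"""Readers and writers for the on-disk formats the pipeline touches.

Formats: Bismark-style per-cytosine reports (TSV, 1-based), BED3/BED6
(0-based half-open, converted at this boundary), GMT gene sets, and the
sample-metadata TSV. All readers are deterministic and order-normalising
(loci come back sorted by chromosome then position).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .core import (
    GeneModel,
    GeneSetCollection,
    IslandSet,
    MethylationDataset,
    validate_sample_table,
)

logger = logging.getLogger(__name__)

CYTOSINE_REPORT_COLUMNS = [
    "chrom", "pos", "strand", "count_methylated", "count_unmethylated",
    "context", "trinucleotide",
]


def read_cytosine_report(
    path,
    context_filter: str = "CG",
    collapse_strands: bool = True,
) -> pd.DataFrame:
    """Read one Bismark-style cytosine report into per-locus counts.

    Returns a DataFrame with columns ``chrom, pos, m, n`` sorted by
    (chrom, pos). Only rows whose context matches ``context_filter`` are
    kept (others are dropped with a logged count). With
    ``collapse_strands`` the minus-strand cytosine of a symmetric CpG at
    position p is merged into its plus-strand partner at p-1 by summing
    counts; an unpartnered minus-strand CpG still becomes a plus-strand
    locus at p-1.
    """
    raw = pd.read_csv(
        path, sep="\t", header=None, dtype=str, comment="#",
        names=CYTOSINE_REPORT_COLUMNS, usecols=range(7), engine="python",
    )
    if raw.empty:
        return pd.DataFrame({"chrom": [], "pos": [], "m": [], "n": []}).astype(
            {"chrom": object, "pos": np.int64, "m": np.int64, "n": np.int64}
        )
    pos = pd.to_numeric(raw["pos"], errors="coerce")
    mc = pd.to_numeric(raw["count_methylated"], errors="coerce")
    uc = pd.to_numeric(raw["count_unmethylated"], errors="coerce")
    bad = (
        raw["chrom"].isna() | pos.isna() | mc.isna() | uc.isna()
        | ~raw["strand"].isin(["+", "-"])
        | (pos < 1) | (mc < 0) | (uc < 0)
    )
    if bad.any():
        line = int(bad.idxmax()) + 1
        raise ValueError(f"{path}: malformed cytosine-report row at line {line}")
    df = pd.DataFrame({
        "chrom": raw["chrom"].astype(object),
        "pos": pos.astype(np.int64),
        "strand": raw["strand"],
        "m": mc.astype(np.int64),
        "u": uc.astype(np.int64),
        "context": raw["context"].fillna(""),
    })
    kept = df[df["context"] == context_filter]
    n_dropped = len(df) - len(kept)
    if n_dropped:
        logger.info("%s: dropped %d non-%s rows", path, n_dropped, context_filter)
    df = kept.copy()
    if collapse_strands:
        minus = df["strand"] == "-"
        df.loc[minus, "pos"] = df.loc[minus, "pos"] - 1
    out = (
        df.groupby(["chrom", "pos"], as_index=False)[["m", "u"]].sum()
        .sort_values(["chrom", "pos"], kind="mergesort")
        .reset_index(drop=True)
    )
    out["n"] = out["m"] + out["u"]
    return out[["chrom", "pos", "m", "n"]]


def write_cytosine_report(dataset: MethylationDataset, sample_id: str, path) -> None:
    """Write one sample of a (collapsed) dataset back to cytosine-report TSV."""
    j = dataset.sample_index(sample_id)
    m = dataset.M[:, j]
    n = dataset.N[:, j]
    df = pd.DataFrame({
        "chrom": dataset.chrom,
        "pos": dataset.pos,
        "strand": "+",
        "count_methylated": m,
        "count_unmethylated": n - m,
        "context": "CG",
        "trinucleotide": "CGN",
    })
    df.to_csv(path, sep="\t", header=False, index=False)


def assemble_dataset(reports: Mapping[str, pd.DataFrame]) -> MethylationDataset:
    """Combine per-sample count tables over the union of loci (N=0 fill).

    ``reports`` maps sample id -> DataFrame as returned by
    :func:`read_cytosine_report`. Downstream coverage filters decide which
    union loci are usable.
    """
    sample_ids = list(reports)
    if not sample_ids:
        raise ValueError("no samples to assemble")
    frames = []
    for sid in sample_ids:
        r = reports[sid]
        frames.append(r.set_index(["chrom", "pos"])[["m", "n"]])
    union = pd.concat(frames, axis=1, keys=sample_ids).fillna(0).sort_index()
    M = union.xs("m", axis=1, level=1).to_numpy(dtype=np.int64)
    N = union.xs("n", axis=1, level=1).to_numpy(dtype=np.int64)
    chrom = union.index.get_level_values(0).to_numpy(dtype=object)
    pos = union.index.get_level_values(1).to_numpy(dtype=np.int64)
    return MethylationDataset(chrom, pos, sample_ids, M, N)


def read_dataset(report_paths: Mapping[str, object], **kwargs) -> MethylationDataset:
    """Read and assemble cytosine reports for a whole cohort."""
    return assemble_dataset(
        {sid: read_cytosine_report(p, **kwargs) for sid, p in report_paths.items()}
    )


def _read_bed_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    start = pd.to_numeric(df[1])
    end = pd.to_numeric(df[2])
    if (end <= start).any():
        row = int((end <= start).idxmax()) + 1
        raise ValueError(f"{path}: BED end <= start at line {row}")
    out = pd.DataFrame({"chrom": df[0].astype(object)})
    # BED 0-based half-open -> internal 1-based inclusive
    out["start"] = start.astype(np.int64) + 1
    out["end"] = end.astype(np.int64)
    if df.shape[1] >= 6:
        out["name"] = df[3]
        out["strand"] = df[5]
    return out


def read_bed(path, kind: str = "islands"):
    """Read a BED file as merged islands (``kind='islands'``) or gene models
    (``kind='genes'``, requires BED6 with name and strand)."""
    tab = _read_bed_table(path)
    if kind == "islands":
        return IslandSet.from_intervals(
            zip(tab["chrom"], tab["start"], tab["end"])
        )
    if kind == "genes":
        if "strand" not in tab.columns:
            raise ValueError(f"{path}: gene BED needs >= 6 columns (name, strand)")
        return [
            GeneModel(str(r.name), str(r.chrom), int(r.start), int(r.end), str(r.strand))
            for r in tab.itertuples(index=False)
        ]
    raise ValueError(f"unknown BED kind {kind!r}")


def write_bed(intervals: Iterable[tuple], path, names: Iterable[str] | None = None,
              strands: Iterable[str] | None = None) -> None:
    """Write 1-based inclusive (chrom, start, end) intervals as BED (0-based)."""
    rows = []
    names = list(names) if names is not None else None
    strands = list(strands) if strands is not None else None
    for i, (c, s, e) in enumerate(intervals):
        row = [c, int(s) - 1, int(e)]
        if names is not None:
            row += [names[i], 0, strands[i] if strands is not None else "+"]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def read_gmt(path) -> GeneSetCollection:
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: GMT line {i} has fewer than 3 fields")
            name, desc, genes = fields[0], fields[1], [g for g in fields[2:] if g]
            if name in sets:
                raise ValueError(f"{path}: duplicate gene-set name {name!r}")
            sets[name] = genes
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *genes]) + "\n")


def read_metadata(path, age_range: tuple[float, float] | None = None) -> pd.DataFrame:
    """Read the sample-metadata TSV (requires subject_id and age columns)."""
    table = pd.read_csv(path, sep="\t")
    return validate_sample_table(table, age_range=age_range)


def write_metadata(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def write_results_tsv(df: pd.DataFrame, path, float_format: str = "%.6g") -> None:
    """Deterministic TSV writer used for all result tables."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format=float_format)
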