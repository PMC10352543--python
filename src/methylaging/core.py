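"""Core containers for bisulfite-sequencing methylation data.

Coordinates are 1-based inclusive everywhere inside the package; BED's
0-based half-open convention is converted at the I/O boundary only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Locus",
    "MethylationDataset",
    "GeneModel",
    "IslandSet",
    "GeneSetCollection",
    "validate_sample_table",
]


@dataclass(frozen=True, order=True)
class Locus:
    """A single cytosine position (1-based, plus strand after collapse)."""

    chrom: str
    pos: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


@dataclass
class MethylationDataset:
    """Loci x samples matrices of methylated (M) and total (N) read counts.

    Loci are stored as parallel ``chrom``/``pos`` arrays sorted by
    (chrom, pos) and unique; all loci are plus-strand (post collapse).
    """

    chrom: np.ndarray
    pos: np.ndarray
    sample_ids: list[str]
    M: np.ndarray
    N: np.ndarray

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.sample_ids = list(self.sample_ids)
        self.M = np.asarray(self.M, dtype=np.int64)
        self.N = np.asarray(self.N, dtype=np.int64)
        L, S = self.M.shape
        if self.N.shape != (L, S):
            raise ValueError("M and N shapes differ")
        if len(self.chrom) != L or len(self.pos) != L:
            raise ValueError("locus arrays do not match matrix rows")
        if len(self.sample_ids) != S:
            raise ValueError("sample_ids do not match matrix columns")
        if len(set(self.sample_ids)) != S:
            raise ValueError("duplicate sample ids")
        if np.any(self.N < 0) or np.any(self.M < 0) or np.any(self.M > self.N):
            raise ValueError("require 0 <= M <= N elementwise")
        # strictly increasing positions within each chromosome
        same = self.chrom[1:] == self.chrom[:-1]
        if np.any(same & (np.diff(self.pos) <= 0)):
            raise ValueError("loci must be strictly increasing within chromosome")

    @property
    def n_loci(self) -> int:
        return self.M.shape[0]

    @property
    def n_samples(self) -> int:
        return self.M.shape[1]

    def loci(self) -> list[Locus]:
        return [Locus(c, int(p)) for c, p in zip(self.chrom, self.pos)]

    def locus_keys(self) -> list[tuple[str, int]]:
        return [(str(c), int(p)) for c, p in zip(self.chrom, self.pos)]

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample id: {sample_id!r}") from None

    def subset_loci(self, mask: np.ndarray) -> "MethylationDataset":
        mask = np.asarray(mask)
        return MethylationDataset(
            self.chrom[mask], self.pos[mask], self.sample_ids,
            self.M[mask], self.N[mask],
        )

    def reorder_samples(self, sample_ids: list[str]) -> "MethylationDataset":
        idx = [self.sample_index(s) for s in sample_ids]
        return MethylationDataset(
            self.chrom, self.pos, list(sample_ids), self.M[:, idx], self.N[:, idx]
        )


@dataclass(frozen=True)
class GeneModel:
    """Transcript span, 1-based inclusive; TSS is the strand-aware 5' end."""

    gene_id: str
    chrom: str
    tx_start: int
    tx_end: int
    strand: str

    def __post_init__(self) -> None:
        if self.tx_start > self.tx_end:
            raise ValueError(f"tx_start > tx_end for {self.gene_id}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r} for {self.gene_id}")

    @property
    def tss(self) -> int:
        return self.tx_start if self.strand == "+" else self.tx_end


@dataclass
class IslandSet:
    """Merged CpG-island intervals, 1-based inclusive, sorted, non-overlapping."""

    intervals: list[tuple[str, int, int]] = field(default_factory=list)

    @classmethod
    def from_intervals(cls, intervals) -> "IslandSet":
        """Build from arbitrary (chrom, start, end) triples, merging overlaps
        and bookended records."""
        ivs = sorted((str(c), int(s), int(e)) for c, s, e in intervals)
        for c, s, e in ivs:
            if s > e:
                raise ValueError(f"island start > end: {(c, s, e)}")
        merged: list[tuple[str, int, int]] = []
        for c, s, e in ivs:
            if merged and merged[-1][0] == c and s <= merged[-1][2] + 1:
                pc, ps, pe = merged[-1]
                merged[-1] = (pc, ps, max(pe, e))
            else:
                merged.append((c, s, e))
        return cls(merged)

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)


@dataclass
class GeneSetCollection:
    """Named gene sets with free-text descriptions (GMT semantics)."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def items(self):
        return self.sets.items()


REQUIRED_METADATA_COLUMNS = ("subject_id", "age")


def validate_sample_table(table: pd.DataFrame, age_range: tuple[float, float] | None = None) -> pd.DataFrame:
    """Validate a per-subject covariate table (SampleTable contract).

    Requires unique ``subject_id`` and numeric ``age``; optional columns
    (sex, race, bmi, batch, tissue, fiber_ratio) pass through untouched.
    """
    for col in REQUIRED_METADATA_COLUMNS:
        if col not in table.columns:
            raise ValueError(f"metadata missing required column {col!r}")
    if table["subject_id"].duplicated().any():
        dups = table.loc[table["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValueError(f"duplicate subject_id: {dups}")
    ages = pd.to_numeric(table["age"], errors="raise")
    if ages.isna().any():
        raise ValueError("missing age values")
    if age_range is not None:
        lo, hi = age_range
        if (ages < lo).any() or (ages > hi).any():
            raise ValueError(f"ages outside declared range [{lo}, {hi}]")
    out = table.copy()
    out["age"] = ages.astype(float)
    out["subject_id"] = out["subject_id"].astype(str)
    return out.reset_index(drop=True)
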