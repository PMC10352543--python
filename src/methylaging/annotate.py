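"""Gene linkage, CpG-island context, set overlap and over-representation.

Features (single CpGs or called regions, 1-based inclusive intervals) are
linked to genes when they overlap a transcript span (intragenic) or lie
within 200 bp of a strand-aware transcription start site (TSS-proximal,
negative distances upstream by strand). Island context follows the usual
ladder: island (overlap), shore (within 2 kb), shelf (2-4 kb), open sea.
Over-representation of a selected gene list against GMT gene sets uses the
upper-tail hypergeometric test with BH correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import GeneModel, GeneSetCollection, IslandSet
from .regression import bh_adjust

__all__ = [
    "FeatureLink",
    "link_genes",
    "classify_island_context",
    "intragenic_fraction",
    "round_half_away",
    "overlap_analyses",
    "loci_in_regions",
    "ora_hypergeometric",
]

SHORE_BP = 2000
SHELF_BP = 4000


@dataclass(frozen=True)
class FeatureLink:
    feature_index: int
    gene_id: str | None
    link_type: str                  # intragenic | tss_proximal | none
    signed_distance: float          # 0 if overlapping; negative upstream of TSS


def _as_intervals(features) -> list[tuple[str, int, int]]:
    """Accept (chrom, pos) loci or (chrom, start, end) intervals."""
    out = []
    for f in features:
        if len(f) == 2:
            c, p = f
            out.append((str(c), int(p), int(p)))
        else:
            c, s, e = f[:3]
            out.append((str(c), int(s), int(e)))
    return out


def link_genes(features, genes: list[GeneModel], max_link_dist: int = 200) -> list[FeatureLink]:
    """One link per qualifying feature-gene pair; features with no
    qualifying gene get a single ``none`` link."""
    ivs = _as_intervals(features)
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    links: list[FeatureLink] = []
    for fi, (chrom, start, end) in enumerate(ivs):
        found = False
        for g in by_chrom.get(chrom, []):
            if start <= g.tx_end and end >= g.tx_start:
                links.append(FeatureLink(fi, g.gene_id, "intragenic", 0.0))
                found = True
                continue
            tss = g.tss
            mag = start - tss if tss < start else (tss - end if tss > end else 0)
            if mag <= max_link_dist:
                upstream = (g.strand == "+" and end < tss) or (g.strand == "-" and start > tss)
                links.append(FeatureLink(
                    fi, g.gene_id, "tss_proximal", -float(mag) if upstream else float(mag)))
                found = True
        if not found:
            links.append(FeatureLink(fi, None, "none", float("nan")))
    return links


def links_to_frame(links: list[FeatureLink]) -> pd.DataFrame:
    return pd.DataFrame([{
        "feature_index": l.feature_index,
        "gene_id": l.gene_id,
        "link_type": l.link_type,
        "signed_distance": l.signed_distance,
    } for l in links])


def classify_island_context(features, islands: IslandSet) -> pd.DataFrame:
    """Per feature: distance to the nearest merged island on the same
    chromosome (0 when overlapping, inf when the chromosome has none) and
    the island/shore/shelf/open-sea class."""
    ivs = _as_intervals(features)
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in {c for c, _, _ in islands}:
        recs = [(s, e) for c, s, e in islands if c == chrom]
        starts = np.array([s for s, _ in recs])
        ends = np.array([e for _, e in recs])
        by_chrom[chrom] = (starts, ends)
    dist = np.full(len(ivs), np.inf)
    for fi, (chrom, start, end) in enumerate(ivs):
        if chrom not in by_chrom:
            continue
        starts, ends = by_chrom[chrom]
        gap = np.where(ends < start, start - ends,
                       np.where(starts > end, starts - end, 0))
        dist[fi] = gap.min()
    cls = np.select(
        [dist == 0, dist <= SHORE_BP, dist <= SHELF_BP],
        ["island", "shore", "shelf"],
        default="open_sea",
    )
    return pd.DataFrame({"distance_to_island": dist, "island_class": cls})


def round_half_away(x: float) -> int:
    """Nearest integer, ties away from zero (reporting convention for
    percentages)."""
    return int(np.floor(abs(x) + 0.5) * np.sign(x)) if x else 0


def intragenic_fraction(links: list[FeatureLink] | None = None,
                        n_intragenic: int | None = None,
                        n_features: int | None = None):
    """Fraction (and rounded percent) of features with an intragenic link;
    intragenic wins over tss_proximal per feature. Accepts either a link
    list or explicit counts."""
    if links is not None:
        per_feature: dict[int, str] = {}
        for l in links:
            cur = per_feature.get(l.feature_index)
            rank = {"intragenic": 2, "tss_proximal": 1, "none": 0}
            if cur is None or rank[l.link_type] > rank[cur]:
                per_feature[l.feature_index] = l.link_type
        n_features = len(per_feature)
        n_intragenic = sum(1 for v in per_feature.values() if v == "intragenic")
    if not n_features:
        return {"n_intragenic": 0, "n_features": 0,
                "fraction": float("nan"), "percent": None}
    frac = n_intragenic / n_features
    return {"n_intragenic": int(n_intragenic), "n_features": int(n_features),
            "fraction": frac, "percent": round_half_away(100.0 * frac)}


def overlap_analyses(admp_set, swan_set, dmr_set) -> dict[str, int]:
    """Exclusive region counts of the three-set Venn over locus keys."""
    a, s, d = set(admp_set), set(swan_set), set(dmr_set)
    return {
        "admp_only": len(a - s - d),
        "swan_only": len(s - a - d),
        "dmr_only": len(d - a - s),
        "admp_swan": len((a & s) - d),
        "admp_dmr": len((a & d) - s),
        "swan_dmr": len((s & d) - a),
        "all_three": len(a & s & d),
    }


def loci_in_regions(locus_keys, regions) -> set:
    """Locus keys (chrom, pos) falling inside any (chrom, start, end) region."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for c, s, e in _as_intervals(regions):
        by_chrom.setdefault(c, []).append((s, e))
    out = set()
    for c, p in locus_keys:
        for s, e in by_chrom.get(str(c), []):
            if s <= int(p) <= e:
                out.add((str(c), int(p)))
                break
    return out


def ora_hypergeometric(selected_genes, universe, gene_sets: GeneSetCollection) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation test per gene set.

    p = P(X >= k) with population ``len(universe)``, successes the set size
    within the universe, draws ``len(selected)``; BH across sets.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty gene universe")
    sel = set(selected_genes)
    if not sel <= uni:
        raise ValueError("selected genes must be a subset of the universe")
    rows = []
    for name, genes in gene_sets.items():
        in_uni = set(genes) & uni
        k = len(in_uni & sel)
        p = float(stats.hypergeom.sf(k - 1, len(uni), len(in_uni), len(sel)))
        rows.append({
            "set_name": name,
            "n_set": len(in_uni),
            "n_overlap": k,
            "universe_size": len(uni),
            "n_selected": len(sel),
            "p_value": p,
        })
    out = pd.DataFrame(rows)
    if len(out):
        out["q_value"] = bh_adjust(out["p_value"].to_numpy())
    return out
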