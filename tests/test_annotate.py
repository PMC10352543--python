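"""Gene linkage, island context, Venn overlap and over-representation."""

import numpy as np
import pytest
from scipy import stats

from methylaging.annotate import (
    classify_island_context,
    intragenic_fraction,
    link_genes,
    loci_in_regions,
    ora_hypergeometric,
    overlap_analyses,
    round_half_away,
)
from methylaging.core import GeneModel, GeneSetCollection, IslandSet


def brute_force_links(features, genes, maxd):
    out = []
    for fi, f in enumerate(features):
        chrom, start, end = (f[0], f[1], f[1]) if len(f) == 2 else f
        hits = []
        for g in genes:
            if g.chrom != chrom:
                continue
            if start <= g.tx_end and end >= g.tx_start:
                hits.append((g.gene_id, "intragenic", 0.0))
            else:
                tss = g.tss
                mag = start - tss if tss < start else (tss - end if tss > end else 0)
                if mag <= maxd:
                    up = (g.strand == "+" and end < tss) or (g.strand == "-" and start > tss)
                    hits.append((g.gene_id, "tss_proximal", -mag if up else mag))
        out.append((fi, sorted(hits)) if hits else (fi, []))
    return out


class TestLinkGenes:
    GENE = GeneModel("G1", "chr1", 100, 900, "+")

    def test_intragenic(self):
        (link,) = link_genes([("chr1", 150)], [self.GENE])
        assert (link.link_type, link.signed_distance) == ("intragenic", 0.0)

    def test_upstream_tss_negative_distance(self):
        gene = GeneModel("G2", "chr1", 1000, 2000, "+")
        (link,) = link_genes([("chr1", 950)], [gene])
        assert (link.link_type, link.signed_distance) == ("tss_proximal", -50.0)

    def test_minus_strand_upstream(self):
        gene = GeneModel("G3", "chr1", 500, 900, "-")
        (link,) = link_genes([("chr1", 950)], [gene])  # 3' of span? no: past tx_end
        assert link.link_type == "tss_proximal"
        assert link.signed_distance == -50.0  # downstream coords, upstream by strand

    def test_unlinked_feature(self):
        (link,) = link_genes([("chr2", 150)], [self.GENE])
        assert link.link_type == "none"

    def test_matches_brute_force_on_random_fixture(self):
        rng = np.random.default_rng(41)
        genes = []
        for i in range(50):
            c = f"chr{rng.integers(1, 3)}"
            s = int(rng.integers(1, 90_000))
            genes.append(GeneModel(f"G{i}", c, s, s + int(rng.integers(100, 5000)),
                                   str(rng.choice(["+", "-"]))))
        feats = [(f"chr{rng.integers(1, 3)}", int(rng.integers(1, 100_000)))
                 for _ in range(1000)]
        links = link_genes(feats, genes, 200)
        expect = brute_force_links(feats, genes, 200)
        got: dict[int, list] = {}
        for l in links:
            got.setdefault(l.feature_index, [])
            if l.link_type != "none":
                got[l.feature_index].append((l.gene_id, l.link_type, l.signed_distance))
        for fi, hits in expect:
            assert sorted(got[fi]) == hits


class TestIslandContext:
    ISLANDS = IslandSet.from_intervals([("chr1", 1000, 2000)])

    @pytest.mark.parametrize("pos,expect", [
        (1500, "island"),
        (2001, "shore"),
        (4000, "shore"),      # 2000 bp from edge, inclusive
        (4001, "shelf"),
        (6000, "shelf"),
        (6001, "open_sea"),
    ])
    def test_boundaries(self, pos, expect):
        ctx = classify_island_context([("chr1", pos)], self.ISLANDS)
        assert ctx.loc[0, "island_class"] == expect

    def test_chromosome_without_islands(self):
        ctx = classify_island_context([("chr9", 10)], self.ISLANDS)
        assert ctx.loc[0, "island_class"] == "open_sea"
        assert np.isinf(ctx.loc[0, "distance_to_island"])

    def test_every_feature_classified_once(self):
        rng = np.random.default_rng(43)
        islands = IslandSet.from_intervals(
            [("chr1", int(s), int(s) + 500) for s in rng.choice(10**5, 5) * 10])
        feats = [("chr1", int(p)) for p in rng.integers(1, 10**6, size=400)]
        ctx = classify_island_context(feats, islands)
        assert len(ctx) == 400
        assert ctx["island_class"].value_counts().sum() == 400

    def test_matches_brute_force_distances(self):
        rng = np.random.default_rng(44)
        islands = IslandSet.from_intervals(
            [("chr1", int(s), int(e)) for s, e in
             [(1000, 1500), (5000, 5200), (9000, 9900)]])
        feats = [("chr1", int(p)) for p in rng.integers(1, 12_000, size=300)]
        ctx = classify_island_context(feats, islands)
        for i, (c, p) in enumerate(feats):
            d = min(max(s - p, p - e, 0) for _, s, e in islands)
            assert ctx.loc[i, "distance_to_island"] == d


class TestIntragenicFraction:
    @pytest.mark.parametrize("k,n,pct", [
        (16842, 29492, 57),
        (1741, 2372, 73),
        (1589, 2263, 70),
        (0, 10, 0),
    ])
    def test_reported_percent(self, k, n, pct):
        out = intragenic_fraction(n_intragenic=k, n_features=n)
        assert out["percent"] == pct

    def test_zero_features_undefined(self):
        out = intragenic_fraction(n_intragenic=0, n_features=0)
        assert np.isnan(out["fraction"])

    def test_intragenic_wins_over_tss(self):
        genes = [GeneModel("A", "chr1", 100, 200, "+"),
                 GeneModel("B", "chr1", 220, 400, "+")]
        links = link_genes([("chr1", 150)], genes)  # intragenic A, tss B
        assert {l.link_type for l in links} == {"intragenic", "tss_proximal"}
        out = intragenic_fraction(links)
        assert out == {"n_intragenic": 1, "n_features": 1,
                       "fraction": 1.0, "percent": 100}

    def test_rounding_half_away(self):
        assert round_half_away(56.5) == 57
        assert round_half_away(-0.5) == -1
        assert round_half_away(0.49) == 0


class TestOverlap:
    def test_hand_venn(self):
        counts = overlap_analyses({"a", "b"}, {"b", "c"}, {"b"})
        assert counts["all_three"] == 1
        assert counts["admp_only"] == 1
        assert counts["swan_only"] == 1
        assert counts["dmr_only"] == 0

    def test_disjoint(self):
        counts = overlap_analyses({1}, {2}, {3})
        assert counts["all_three"] == 0
        assert sum(counts.values()) == 3

    def test_matches_set_algebra_on_random_sets(self):
        rng = np.random.default_rng(47)
        pool = [("chr1", int(p)) for p in range(200)]
        a = {pool[i] for i in rng.choice(200, 80, replace=False)}
        s = {pool[i] for i in rng.choice(200, 80, replace=False)}
        d = {pool[i] for i in rng.choice(200, 80, replace=False)}
        counts = overlap_analyses(a, s, d)
        for key, expect in {
            "admp_only": a - s - d, "swan_only": s - a - d, "dmr_only": d - a - s,
            "admp_swan": (a & s) - d, "admp_dmr": (a & d) - s,
            "swan_dmr": (s & d) - a, "all_three": a & s & d,
        }.items():
            assert counts[key] == len(expect)
        assert sum(counts.values()) == len(a | s | d)

    def test_loci_in_regions(self):
        keys = [("chr1", 5), ("chr1", 50), ("chr2", 5)]
        regions = [("chr1", 1, 10)]
        assert loci_in_regions(keys, regions) == {("chr1", 5)}


class TestOra:
    UNIVERSE = [f"g{i}" for i in range(10)]

    def test_zero_overlap_p_one(self):
        gs = GeneSetCollection({"S": ["g5", "g6"]})
        out = ora_hypergeometric(["g0"], self.UNIVERSE, gs)
        assert out.loc[0, "p_value"] == pytest.approx(1.0)

    def test_worked_closed_form(self):
        gs = GeneSetCollection({"S": [f"g{i}" for i in range(5)]})
        out = ora_hypergeometric([f"g{i}" for i in range(5)], self.UNIVERSE, gs)
        assert out.loc[0, "p_value"] == pytest.approx(1 / 252, rel=1e-12)

    def test_matches_fisher_exact(self):
        rng = np.random.default_rng(53)
        for _ in range(50):
            m = int(rng.integers(10, 60))
            universe = [f"g{i}" for i in range(m)]
            n_set = int(rng.integers(1, m))
            n_sel = int(rng.integers(1, m))
            gset = list(rng.choice(universe, n_set, replace=False))
            sel = list(rng.choice(universe, n_sel, replace=False))
            out = ora_hypergeometric(sel, universe, GeneSetCollection({"S": gset}))
            k = len(set(gset) & set(sel))
            table = [[k, n_set - k], [n_sel - k, m - n_set - n_sel + k]]
            ref = stats.fisher_exact(table, alternative="greater")[1]
            assert out.loc[0, "p_value"] == pytest.approx(ref, abs=1e-10)

    def test_empty_universe_errors(self):
        with pytest.raises(ValueError):
            ora_hypergeometric([], [], GeneSetCollection({"S": ["a"]}))

    def test_selected_outside_universe_errors(self):
        with pytest.raises(ValueError):
            ora_hypergeometric(["zz"], self.UNIVERSE, GeneSetCollection({"S": ["g1"]}))
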