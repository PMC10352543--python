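"""Clustering, smoothing, young-baseline t-statistic and region calling."""

import numpy as np
import pandas as pd
import pytest

from methylaging.core import MethylationDataset
from methylaging.dmr import (
    DMRecord,
    SmoothParams,
    TStatParams,
    call_dmrs,
    cluster_loci,
    local_correct,
    smooth_sample,
    smooth_dataset,
    split_groups,
    tstat,
)


class TestClusterLoci:
    def test_gap_rule(self):
        labels = cluster_loci(["chr1"] * 3, [100, 200, 10**9], 10**8)
        assert labels.tolist() == [0, 0, 1]

    def test_chromosome_boundary_splits(self):
        labels = cluster_loci(["chr1", "chr2"], [100, 100], 10**8)
        assert labels.tolist() == [0, 1]

    def test_matches_brute_force(self):
        rng = np.random.default_rng(2)
        pos = np.sort(rng.choice(np.arange(1, 10**6), size=300, replace=False))
        chrom = np.where(pos < 500_000, "chr1", "chr2").astype(object)
        maxgap = 5000
        labels = cluster_loci(chrom, pos, maxgap)
        expect = [0]
        for i in range(1, len(pos)):
            if chrom[i] != chrom[i - 1] or pos[i] - pos[i - 1] > maxgap:
                expect.append(expect[-1] + 1)
            else:
                expect.append(expect[-1])
        assert labels.tolist() == expect


def _dataset_from_fraction(pos, frac, coverage=50, n_samples=1):
    pos = np.asarray(pos)
    N = np.full((len(pos), n_samples), coverage, dtype=int)
    M = np.round(frac[:, None] * N).astype(int)
    return MethylationDataset(np.array(["chr1"] * len(pos), dtype=object),
                              pos, [f"s{i}" for i in range(n_samples)], M, N)


class TestSmoothing:
    def test_constant_profile_preserved(self):
        pos = np.arange(1000, 1000 + 50 * 40, 40)
        sm = smooth_sample(pos, np.full(50, 20), np.full(50, 50),
                           SmoothParams(min_loci=20, min_width=500))
        np.testing.assert_allclose(sm, 0.4, atol=1e-10)

    def test_exact_quadratic_reproduced(self):
        # window = whole cluster, full coverage: degree-2 fit is exact
        pos = np.arange(0, 2000, 40) + 1
        x = (pos - pos.mean()) / 1000.0
        frac = 0.5 + 0.2 * x - 0.3 * x**2
        assert (frac > 0).all() and (frac < 1).all()
        N = np.full(len(pos), 1000)
        M_exact = frac * N  # non-integer M is fine for the smoother itself
        sm = smooth_sample(pos, M_exact, N,
                           SmoothParams(min_loci=len(pos), min_width=1))
        np.testing.assert_allclose(sm, frac, atol=1e-8)

    def test_uncovered_locus_imputed_from_neighbours(self):
        pos = np.arange(0, 84, 4) + 1   # 21 loci
        frac = np.full(21, 0.2)
        ds = _dataset_from_fraction(pos, frac, coverage=100)
        M, N = ds.M.copy(), ds.N.copy()
        N[10, 0] = 0
        M[10, 0] = 0
        sm = smooth_sample(pos, M[:, 0], N[:, 0], SmoothParams(min_loci=10, min_width=20))
        assert 0.15 <= sm[10] <= 0.25

    def test_shift_equivariance(self):
        rng = np.random.default_rng(5)
        pos = np.sort(rng.choice(np.arange(1, 5000), size=60, replace=False))
        N = rng.poisson(30, size=60) + 1
        frac = rng.uniform(0.2, 0.4, size=60)
        M = frac * N
        params = SmoothParams(min_loci=15, min_width=300)
        base = smooth_sample(pos, M, N, params)
        shifted = smooth_sample(pos, M + 0.3 * N, N, params)
        np.testing.assert_allclose(shifted, np.clip(base + 0.3, 0, 1), atol=1e-8)

    def test_tiny_cluster_falls_back_to_mean(self):
        pos = np.array([10, 20])
        sm = smooth_sample(pos, np.array([5, 10]), np.array([10, 10]),
                           SmoothParams(min_loci=10, min_width=100))
        np.testing.assert_allclose(sm, 0.75)  # coverage-weighted mean

    def test_smooth_dataset_matches_per_sample(self, random_dataset):
        params = SmoothParams(min_loci=15, min_width=500)
        full = smooth_dataset(random_dataset, params)
        one = smooth_sample(random_dataset.pos, random_dataset.M[:, 2],
                            random_dataset.N[:, 2], params)
        np.testing.assert_allclose(full[:, 2], one, atol=1e-10, equal_nan=True)


class TestSplitGroups:
    def test_inclusive_threshold(self):
        tab = pd.DataFrame({"subject_id": ["a", "b"], "age": [52, 53]})
        young, old = split_groups(tab, 53, inclusive=True)
        assert (young, old) == (["a"], ["b"])

    def test_exclusive_threshold(self):
        tab = pd.DataFrame({"subject_id": ["a", "b"], "age": [51, 52]})
        young, old = split_groups(tab, 51, inclusive=False)
        assert (young, old) == (["a"], ["b"])

    def test_empty_group_errors(self):
        tab = pd.DataFrame({"subject_id": ["a", "b"], "age": [30, 40]})
        with pytest.raises(ValueError):
            split_groups(tab, 80)


class TestTstat:
    def test_zero_for_identical_means(self):
        sm = np.tile([[0.3, 0.3, 0.3, 0.3]], (5, 1))
        t = tstat(sm, [0, 1], [2, 3])
        np.testing.assert_allclose(t, 0.0)

    def test_closed_form(self):
        rng = np.random.default_rng(11)
        ny, no = 6, 5
        sm = np.empty((30, ny + no))
        sm[:, :ny] = rng.normal(0.4, 0.05, size=(30, ny))
        sm[:, ny:] = rng.normal(0.55, 0.05, size=(30, no))
        params = TStatParams(sd_floor_quantile=0.0)
        t = tstat(sm, list(range(ny)), list(range(ny, ny + no)), params)
        sd = sm[:, :ny].std(axis=1, ddof=1) * np.sqrt(1 / ny + 1 / no)
        floor = np.quantile(sd, 0.0)
        expect = (sm[:, ny:].mean(axis=1) - sm[:, :ny].mean(axis=1)) / np.maximum(sd, floor)
        np.testing.assert_allclose(t, expect, rtol=1e-12)

    def test_floor_engages_on_zero_variance(self):
        sm = np.zeros((4, 6))
        sm[:, 3:] = 0.2
        sm[3, :3] = [0.1, 0.2, 0.3]  # one locus with real young spread
        t = tstat(sm, [0, 1, 2], [3, 4, 5])
        assert np.isfinite(t).all()

    def test_label_flip_negates_sign(self):
        """Swapping young/old labels negates the numerator exactly; the
        denominator is re-anchored on the new baseline group, so signs flip
        at every locus (magnitudes may differ)."""
        rng = np.random.default_rng(19)
        sm = rng.uniform(0.2, 0.8, size=(40, 12))
        g1, g2 = [0, 1, 2, 3, 4, 5], [6, 7, 8, 9, 10, 11]
        t_fwd = tstat(sm, g1, g2)
        t_rev = tstat(sm, g2, g1)
        assert np.all(np.sign(t_rev) == -np.sign(t_fwd))


class TestLocalCorrect:
    def test_constant_removed(self):
        t = np.full(200, 3.3)
        cl = np.zeros(200, dtype=int)
        np.testing.assert_allclose(local_correct(t, cl), 0.0, atol=1e-12)

    def test_isolated_spike_running_mean(self):
        t = np.zeros(101)
        t[50] = 10.0
        cl = np.zeros(101, dtype=int)
        out = local_correct(t, cl, TStatParams(correct_halfwidth=50))
        # window at center spans all 101 loci: mean = 10/101
        assert out[50] == pytest.approx(10 - 10 / 101)
        assert out[0] == pytest.approx(-10 / 51)  # edge window shrinks to 51

    def test_off_is_identity(self):
        rng = np.random.default_rng(23)
        t = rng.normal(size=50)
        cl = np.zeros(50, dtype=int)
        np.testing.assert_array_equal(
            local_correct(t, cl, TStatParams(local_correct=False)), t)


def brute_force_runs(t, pos, chrom, clusters, cutoff, maxgap, min_cpgs):
    """Independent enumeration of sign-consistent threshold runs."""
    regions = []
    current = []
    for j in range(len(t)):
        if not (np.isfinite(t[j]) and abs(t[j]) >= cutoff):
            if current:
                regions.append(current)
            current = []
            continue
        if current:
            p = current[-1]
            if (clusters[j] != clusters[p] or chrom[j] != chrom[p]
                    or pos[j] - pos[p] > maxgap
                    or np.sign(t[j]) != np.sign(t[p])):
                regions.append(current)
                current = []
        current.append(j)
    if current:
        regions.append(current)
    return [(chrom[r[0]], pos[r[0]], pos[r[-1]], len(r)) for r in regions
            if len(r) >= min_cpgs]


class TestCallDmrs:
    def _call(self, t, pos, chrom=None, clusters=None, **kw):
        t = np.asarray(t, dtype=float)
        pos = np.asarray(pos)
        if chrom is None:
            chrom = np.array(["chr1"] * len(t), dtype=object)
        if clusters is None:
            clusters = np.zeros(len(t), dtype=int)
        params = TStatParams(**kw)
        return call_dmrs(t, np.sign(t) * 0.1, chrom, pos, clusters, params)

    def test_sign_change_splits(self):
        recs = self._call([5, 5, -5, 5], [100, 200, 300, 400])
        assert [(r.n_cpgs, r.direction) for r in recs] == [
            (2, "hyper"), (1, "hypo"), (1, "hyper")]

    def test_gap_splits(self):
        recs = self._call([5, 5], [100, 500], dmr_maxgap=300)
        assert len(recs) == 2

    def test_subthreshold_empty(self):
        assert self._call([4.5, -4.0, 1.0], [1, 2, 3]) == []

    def test_min_cpgs_filter(self):
        recs = self._call([5, 5, -5], [100, 200, 300], min_cpgs_per_dmr=2)
        assert len(recs) == 1 and recs[0].n_cpgs == 2

    def test_area_stat_and_bounds(self):
        recs = self._call([6.0, 7.0], [100, 150])
        (r,) = recs
        assert (r.start, r.end, r.area_stat) == (100, 150, 13.0)

    def test_matches_brute_force_on_random_tracks(self):
        rng = np.random.default_rng(31)
        L = 10_000
        pos = np.sort(rng.choice(np.arange(1, 4 * 10**6), size=L, replace=False))
        chrom = np.where(pos < 2 * 10**6, "chr1", "chr2").astype(object)
        clusters = cluster_loci(chrom, pos, 10**5)
        t = rng.normal(scale=3.2, size=L)       # heavy exceedance rate
        params = TStatParams()
        recs = call_dmrs(t, t, chrom, pos, clusters, params)
        expect = brute_force_runs(t, pos, chrom, clusters,
                                  params.cutoff, params.dmr_maxgap,
                                  params.min_cpgs_per_dmr)
        got = [(r.chrom, r.start, r.end, r.n_cpgs) for r in recs]
        assert got == expect
        assert len(got) > 50
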