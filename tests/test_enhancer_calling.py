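import numpy as np
import pytest

from somase.io_formats import GenomeModel, Region, TssAnnotation
from somase.signal_processing import SignalTrack
from somase.enhancer_calling import (
    call_candidate_regions, distance_to_nearest_tss, filter_to_predicted_enhancers,
    k4_log_ratio, merge_catalog, merge_regions, rank_product_recurrence,
    tss_position_index,
)


def flat_track(genome, value, mark="H3K4me3", lib=10_000_000):
    bins = {c: np.full(genome.n_bins(c), float(value)) for c in genome.chrom_names}
    return SignalTrack("agg", mark, lib, bins, genome)


def brute_force_runs(vec, bs, threshold, min_width):
    """Independent run-length scan."""
    runs, start = [], None
    for i, v in enumerate(list(vec) + [threshold]):  # sentinel closes final run
        if v > threshold and start is None:
            start = i
        elif v <= threshold and start is not None:
            if (i - start) * bs >= min_width:
                runs.append((start * bs, i * bs))
            start = None
    return runs


class TestCallCandidateRegions:
    def test_spec_example(self):
        genome = GenomeModel(("chr1",), (300,), 50)
        bins = {"chr1": np.array([0, 0, 5, 6, 7, 0], dtype=float)}
        regions = call_candidate_regions(bins, genome, threshold=4, min_width=100)
        assert [(r.start, r.end) for r in regions] == [(100, 250)]

    def test_all_below_threshold(self):
        genome = GenomeModel(("chr1",), (300,), 50)
        bins = {"chr1": np.full(6, 1.0)}
        assert call_candidate_regions(bins, genome, threshold=4) == []

    def test_single_bin_below_min_width_dropped(self):
        genome = GenomeModel(("chr1",), (300,), 50)
        bins = {"chr1": np.array([0, 0, 9, 0, 0, 0], dtype=float)}
        assert call_candidate_regions(bins, genome, threshold=4, min_width=200) == []

    def test_matches_run_length_oracle(self, rng):
        genome = GenomeModel(("chr1",), (50 * 200,), 50)
        for _ in range(200):
            vec = rng.uniform(0, 10, size=200)
            min_width = int(rng.choice([50, 100, 200]))
            got = call_candidate_regions({"chr1": vec}, genome, 5.0, min_width)
            assert [(r.start, r.end) for r in got] == \
                brute_force_runs(vec, 50, 5.0, min_width)


class TestDistalFilter:
    def _setup(self, genome):
        me3 = flat_track(genome, 0.0, "H3K4me3")
        me1 = flat_track(genome, 0.0, "H3K4me1")
        return me3, me1

    def test_distance_boundary_kept(self, genome):
        me3, me1 = self._setup(genome)
        tss = [TssAnnotation("g", "chr1", 13_499)]
        calls = filter_to_predicted_enhancers([Region("chr1", 10_000, 11_000)],
                                              tss, me3, me1)
        assert len(calls) == 1 and calls[0].distance_to_tss == 2_500

    def test_distance_below_excluded(self, genome):
        me3, me1 = self._setup(genome)
        tss = [TssAnnotation("g", "chr1", 13_400)]
        calls = filter_to_predicted_enhancers([Region("chr1", 10_000, 11_000)],
                                              tss, me3, me1)
        assert calls == []
        index = tss_position_index(tss)
        assert distance_to_nearest_tss(Region("chr1", 10_000, 11_000), index) == 2_401

    def test_tss_inside_region_distance_zero(self):
        index = tss_position_index([TssAnnotation("g", "chr1", 10_500)])
        assert distance_to_nearest_tss(Region("chr1", 10_000, 11_000), index) == 0

    def test_high_k4_ratio_excluded(self, genome):
        # flat value v/bin at lib 2e6 -> rpkm = v * 1e9 / (2e6 * 50) = 10 * v
        me3 = flat_track(genome, 1.0, "H3K4me3", lib=2_000_000)  # rpkm 10
        me1 = flat_track(genome, 0.1, "H3K4me1", lib=2_000_000)  # rpkm 1
        region = Region("chr1", 10_000, 11_000)
        ratio = k4_log_ratio(region, me3, me1, pseudocount=0.1)
        assert ratio == pytest.approx(np.log2(10.1 / 1.1), abs=1e-6)
        calls = filter_to_predicted_enhancers([region],
                                              [TssAnnotation("g", "chr1", 500_000)],
                                              me3, me1)
        assert calls == []  # 3.199 > 2.4

    def test_empty_tss_rejected(self, genome):
        me3, me1 = self._setup(genome)
        with pytest.raises(ValueError):
            filter_to_predicted_enhancers([Region("chr1", 0, 1000)], [], me3, me1)

    def test_filters_commute(self, genome, rng):
        """Distal filter and ratio filter retain the same set in either order."""
        me3 = flat_track(genome, 0.0, "H3K4me3")
        me1 = flat_track(genome, 0.0, "H3K4me1")
        me3.bins["chr1"][100:200] = 5.0  # promoter-like stretch
        tss = [TssAnnotation(f"g{i}", "chr1", int(p))
               for i, p in enumerate(sorted(rng.integers(0, 900_000, size=20)))]
        candidates = [Region("chr1", int(s), int(s) + 1000)
                      for s in rng.integers(0, 900_000, size=100)]
        both = filter_to_predicted_enhancers(candidates, tss, me3, me1)
        # manual other-order composition
        index = tss_position_index(tss)
        ratio_first = [r for r in candidates
                       if k4_log_ratio(r, me3, me1) <= 2.4]
        distal_second = [r for r in ratio_first
                         if distance_to_nearest_tss(r, index) >= 2_500]
        assert [c.region for c in both] == distal_second


def brute_force_merge(tagged):
    """O(n^2) transitive-closure union-find oracle for >=1 bp overlap."""
    items = [(r, {s}) for r, s in tagged]
    changed = True
    while changed:
        changed = False
        out = []
        for r, samples in items:
            merged = False
            for i, (q, qs) in enumerate(out):
                if r.chrom == q.chrom and r.start < q.end and q.start < r.end:
                    out[i] = (Region(q.chrom, min(q.start, r.start), max(q.end, r.end)),
                              qs | samples)
                    merged = changed = True
                    break
            if not merged:
                out.append((r, samples))
        items = out
    return sorted(((r.chrom, r.start, r.end, frozenset(s)) for r, s in items))


class TestMergeCatalog:
    def test_overlap_merges_with_present_in(self):
        merged = merge_catalog({"A": [Region("chr1", 0, 100)],
                                "B": [Region("chr1", 50, 150)]})
        assert len(merged) == 1
        assert (merged[0].region.start, merged[0].region.end) == (0, 150)
        assert merged[0].present_in == {"A", "B"}

    def test_disjoint_stay_separate(self):
        merged = merge_catalog({"A": [Region("chr1", 0, 100), Region("chr1", 200, 300)]})
        assert len(merged) == 2

    def test_book_ended_not_merged(self):
        merged = merge_catalog({"A": [Region("chr1", 0, 100)],
                                "B": [Region("chr1", 100, 200)]})
        assert len(merged) == 2

    def test_matches_union_find_oracle(self, rng):
        for _ in range(100):
            tagged = []
            for s in ("A", "B", "C"):
                for _ in range(int(rng.integers(0, 8))):
                    start = int(rng.integers(0, 5_000))
                    tagged.append((Region("chr1", start, start + int(rng.integers(1, 800))), s))
            got = merge_regions(tagged)
            assert sorted((r.chrom, r.start, r.end, frozenset(s)) for r, s in got) == \
                brute_force_merge(tagged)

    def test_idempotent(self, rng):
        tagged = [(Region("chr1", int(s), int(s) + 500), "A")
                  for s in rng.integers(0, 20_000, size=40)]
        once = merge_regions(tagged)
        twice = merge_regions([(r, next(iter(s))) for r, s in once])
        assert [(r.start, r.end) for r, _ in once] == [(r.start, r.end) for r, _ in twice]


class TestRankProduct:
    def test_rank_one_everywhere_is_minimum(self, rng):
        mat = rng.uniform(0, 1, size=(50, 4))
        mat[7] = 10.0  # strongest in every line
        res = rank_product_recurrence(mat, n_perm=100, seed=1)
        assert res[7].rank_product == 1.0
        assert min(r.rank_product for r in res) == 1.0

    def test_rank_arithmetic(self):
        mat = np.array([[3.0, 2.0, 3.0],
                        [2.0, 3.0, 2.0],
                        [1.0, 1.0, 1.0]])
        res = rank_product_recurrence(mat, n_perm=100, seed=1)
        assert res[0].rank_product == pytest.approx(1 * 2 * 1)  # ranks (1,2,1)

    def test_p_never_zero_and_bounded(self, rng):
        mat = rng.uniform(0, 1, size=(30, 3))
        for r in rank_product_recurrence(mat, n_perm=200, seed=0):
            assert 0.0 < r.p_empirical <= 1.0

    def test_small_n_perm_rejected(self, rng):
        with pytest.raises(ValueError):
            rank_product_recurrence(rng.uniform(size=(10, 2)), n_perm=99)

    def test_single_line_rejected(self, rng):
        with pytest.raises(ValueError):
            rank_product_recurrence(rng.uniform(size=(10, 1)), n_perm=100)

    def test_deterministic_given_seed(self, rng):
        mat = rng.uniform(size=(40, 4))
        a = rank_product_recurrence(mat, n_perm=300, seed=5)
        b = rank_product_recurrence(mat, n_perm=300, seed=5)
        assert [r.p_empirical for r in a] == [r.p_empirical for r in b]

    def test_recurrence_flag(self, rng):
        mat = rng.uniform(size=(3, 3))
        present = np.array([[1, 1, 0], [1, 0, 0], [1, 1, 1]], dtype=bool)
        res = rank_product_recurrence(mat, n_perm=100, seed=0, present_matrix=present)
        assert [r.is_recurrent for r in res] == [True, False, True]
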