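import numpy as np
import pandas as pd
import pytest
from scipy import stats

from somase.io_formats import Region
from somase.signal_processing import SignalTrack
from somase.integration_stats import (
    binned_profile, conservation_max, cooccupancy, depletion_se_vs_typical,
    geneset_enrichment, knockdown_depletion, snp_enrichment, summit_positions,
    target_downregulation_permutation, tf_density, tile_regions,
    expression_correlation_screen,
)
from .conftest import make_track


def snp_df(chrom_pos, trait="t"):
    return pd.DataFrame({
        "chrom": [c for c, _ in chrom_pos],
        "pos": [p for _, p in chrom_pos],
        "id": [f"s{i}" for i in range(len(chrom_pos))],
        "trait": trait,
    })


class TestSnpEnrichment:
    def _sets(self, g_in, g_out, b_in, b_out):
        ses = [Region("chr1", 0, 10_000)]
        trait = snp_df([("chr1", 5)] * g_in + [("chr1", 50_000)] * g_out)
        background = snp_df([("chr1", 7)] * b_in + [("chr1", 60_000)] * b_out, "background")
        return trait, background, ses

    def test_ratio_and_chi2_oracle(self):
        trait, background, ses = self._sets(12, 88, 1000, 9000)
        res = snp_enrichment(trait, background, ses)[0]
        assert res.enrichment_ratio == pytest.approx((12 / 88) / (1000 / 9000))
        oracle = stats.chi2_contingency([[12, 88], [1000, 9000]], correction=False)[1]
        assert res.chi2_p == pytest.approx(oracle, rel=1e-12)

    def test_null_identity(self):
        trait, background, ses = self._sets(10, 90, 100, 900)
        res = snp_enrichment(trait, background, ses)[0]
        assert res.enrichment_ratio == pytest.approx(1.0)
        stat = stats.chi2_contingency([[10, 90], [100, 900]], correction=False)[0]
        assert stat == pytest.approx(0.0, abs=1e-12)

    def test_min_trait_snps_filter(self):
        trait, background, ses = self._sets(8, 92, 100, 900)
        assert snp_enrichment(trait, background, ses) == []

    def test_empty_background_rejected(self):
        trait, _, ses = self._sets(10, 0, 1, 1)
        with pytest.raises(ValueError):
            snp_enrichment(trait, trait.iloc[:0], ses)


class TestGenesetEnrichment:
    def test_hypergeometric_oracle(self):
        # table [[20, 80], [100, 9800]]
        universe = {f"g{i}" for i in range(10_000)}
        gene_set = {f"g{i}" for i in range(120)}
        query = {f"g{i}" for i in range(20)} | {f"g{i}" for i in range(5000, 5080)}
        res = geneset_enrichment(query, gene_set, universe)
        assert res.p_value == pytest.approx(
            stats.hypergeom.sf(20 - 1, 10_000, 120, 100), rel=1e-9)

    def test_planted_coupling_detected(self, rng):
        universe = {f"g{i}" for i in range(2000)}
        gene_set = {f"g{i}" for i in range(100)}
        gain = set(rng.choice(sorted(gene_set), 25, replace=False)) | \
            set(rng.choice(sorted(universe), 25, replace=False))
        unaltered = set(rng.choice(sorted(universe), 50, replace=False))
        assert geneset_enrichment(gain, gene_set, universe).p_value < 0.01
        assert geneset_enrichment(unaltered, gene_set,
                                  universe | unaltered).p_value > 0.05


def brute_overlap_bp(site, regions):
    return sum(max(0, min(site.end, r.end) - max(site.start, r.start))
               for r in regions if r.chrom == site.chrom)


class TestTfDensity:
    def test_density_arithmetic(self):
        regions = [Region("chr1", 0, 250_000)]  # 0.25 Mbp
        sites = [Region("chr1", i * 1000, i * 1000 + 100) for i in range(30)]
        occ = tf_density(sites, regions)
        assert occ.n_sites == 30
        assert occ.density_per_mbp == pytest.approx(120.0)

    def test_half_overlap_not_counted(self):
        regions = [Region("chr1", 0, 10_000)]
        site = Region("chr1", 9_500, 10_500)  # 50% inside
        assert tf_density([site], regions).n_sites == 0

    def test_sixty_percent_boundary_counted(self):
        regions = [Region("chr1", 0, 10_000)]
        site = Region("chr1", 9_400, 10_400)  # exactly 60%
        assert tf_density([site], regions).n_sites == 1

    def test_matches_exhaustive_oracle(self, rng):
        for _ in range(50):
            starts = np.sort(rng.choice(np.arange(0, 100_000, 200), 20, replace=False))
            regions = [Region("chr1", int(s), int(s) + 150) for s in starts]
            sites = []
            for _ in range(40):
                s = int(rng.integers(0, 99_000))
                sites.append(Region("chr1", s, s + int(rng.integers(50, 900))))
            occ = tf_density(sites, regions)
            expected = sum(
                brute_overlap_bp(site, regions) >= 0.6 * len(site) for site in sites)
            assert occ.n_sites == expected

    def test_empty_region_set_rejected(self):
        with pytest.raises(ValueError):
            tf_density([Region("chr1", 0, 100)], [])


class TestCooccupancy:
    def test_example(self):
        a = [("chr1", 1000), ("chr1", 5000)]
        b = [("chr1", 1300), ("chr1", 99_000)]
        assert cooccupancy(a, b) == pytest.approx(0.5)

    def test_identity(self):
        a = [("chr1", 10), ("chr2", 500)]
        assert cooccupancy(a, a) == 1.0

    def test_empty_a_rejected(self):
        with pytest.raises(ValueError):
            cooccupancy([], [("chr1", 1)])

    def test_empty_b_zero(self):
        assert cooccupancy([("chr1", 1)], []) == 0.0

    def test_boundary_500(self):
        assert cooccupancy([("chr1", 1000)], [("chr1", 1500)]) == 1.0
        assert cooccupancy([("chr1", 1000)], [("chr1", 1501)]) == 0.0

    def test_matches_all_pairs_oracle(self, rng):
        for _ in range(50):
            a = [("chr1", int(p)) for p in rng.integers(0, 50_000, size=30)]
            b = [("chr1", int(p)) for p in rng.integers(0, 50_000, size=25)]
            expected = np.mean([min(abs(pa - pb) for _, pb in b) <= 500
                                for _, pa in a])
            assert cooccupancy(a, b) == pytest.approx(expected)

    def test_summit_positions_midpoint(self):
        assert summit_positions([Region("chr1", 100, 101)]) == [("chr1", 100)]


class TestBinnedProfile:
    def test_uniform_track_flat_profile(self, genome, rng):
        bins = {c: np.full(genome.n_bins(c), 4.0) for c in genome.chrom_names}
        track = SignalTrack("s", "TF", 10_000_000, bins, genome)
        prof = binned_profile(track, [Region("chr1", 10_000, 30_000)], n_bins=200)
        assert np.allclose(prof, prof[0, 0])

    def test_signal_conservation(self, genome, rng):
        track = make_track(genome, rng, mean=3.0)
        region = Region("chr1", 12_345, 14_345)  # 2000 bp -> 10 bp slices
        prof = binned_profile(track, [region], n_bins=200)
        slice_len = len(region) / 200
        total = prof[0].sum() * slice_len
        from somase.signal_processing import compute_rpkm
        assert total == pytest.approx(compute_rpkm(track, region) * len(region),
                                      rel=1e-6)

    def test_short_region_rejected(self, genome, track):
        with pytest.raises(ValueError):
            binned_profile(track, [Region("chr1", 0, 100)], n_bins=200)

    def test_center_peak_profile(self, genome, rng):
        track = make_track(genome, rng, mean=0.1)
        track.bins["chr1"][190:210] = 50.0  # peak at 9,500-10,500
        prof = binned_profile(track, [Region("chr1", 0, 20_000)], n_bins=200)
        mean_prof = prof.mean(axis=0)
        assert mean_prof[90:110].mean() > 5 * mean_prof[:50].mean()


class TestConservation:
    def test_constant_track(self):
        scores = {"chr1": np.full(1000, 0.3)}
        assert conservation_max(Region("chr1", 10_000, 12_000), scores, 50) == 0.3

    def test_spike_in_window(self):
        scores = {"chr1": np.full(1000, 0.1)}
        mid = 11_000
        scores["chr1"][(mid + 400) // 50] = 0.9
        assert conservation_max(Region("chr1", 10_000, 12_000), scores, 50) == 0.9

    def test_no_coverage_nan(self):
        assert np.isnan(conservation_max(Region("chr2", 0, 100), {"chr1": np.ones(10)}, 50))
        scores = {"chr1": np.full(1000, np.nan)}
        assert np.isnan(conservation_max(Region("chr1", 10_000, 12_000), scores, 50))

    def test_matches_window_scan_oracle(self, rng):
        scores = {"chr1": rng.uniform(0, 1, size=2000)}
        for _ in range(100):
            start = int(rng.integers(30_000, 60_000))
            region = Region("chr1", start, start + int(rng.integers(100, 5000)))
            mid = region.center
            lo, hi = mid - 500, mid + 500
            oracle = max(scores["chr1"][i] for i in range(lo // 50, hi // 50 + 1))
            assert conservation_max(region, scores, 50) == pytest.approx(oracle)


class TestKnockdown:
    def test_tiling_drops_remainder(self):
        tiles = tile_regions([Region("chr1", 0, 2_500)], width=1_000)
        assert [(t.start, t.end) for t in tiles] == [(0, 1000), (1000, 2000)]

    def test_state_rule(self, genome, rng):
        wt1 = make_track(genome, rng, mean=2.0)
        wt2 = make_track(genome, rng, mean=2.0)
        kd = make_track(genome, rng, mean=2.0)
        kd.bins["chr1"][:40] = 0.0    # depleted stretch [0, 2000)
        kd.bins["chr1"][40:80] = 30.0  # gained stretch [2000, 4000)
        regions = [Region("chr1", 0, 100_000)]
        calls, q1, q99 = knockdown_depletion([wt1, wt2], kd, regions)
        assert q1 < q99
        assert all(c.state == "depleted" for c in calls[:2])
        assert all(c.state == "gained" for c in calls[2:4])

    def test_single_wt_rejected(self, genome, rng, track):
        with pytest.raises(ValueError):
            knockdown_depletion([track], track, [Region("chr1", 0, 10_000)])

    def test_se_vs_typical_comparison(self, genome, rng):
        wt = [make_track(genome, rng, mean=2.0) for _ in range(3)]
        kd = make_track(genome, rng, mean=2.0)
        kd.bins["chr1"][:200] *= 0.2  # depletion inside SE territory [0, 10000)
        regions = [Region("chr1", 0, 100_000)]
        calls, _, _ = knockdown_depletion(wt, kd, regions)
        p = depletion_se_vs_typical(calls, [Region("chr1", 0, 10_000)],
                                    [Region("chr1", 10_000, 100_000)])
        assert p < 0.01


class TestTargetPermutation:
    def test_saturated_null(self):
        universe = [f"g{i}" for i in range(50)]
        flags = {g: True for g in universe}
        frac, p = target_downregulation_permutation(universe[:10], flags, universe,
                                                    n_perm=500, seed=1)
        assert frac == 1.0 and p == 1.0

    def test_zero_observed(self):
        universe = [f"g{i}" for i in range(50)]
        flags = {g: False for g in universe}
        frac, p = target_downregulation_permutation(universe[:10], flags, universe,
                                                    n_perm=500, seed=1)
        assert frac == 0.0 and p == 1.0

    def test_empty_links_rejected(self):
        with pytest.raises(ValueError):
            target_downregulation_permutation([], {}, ["g"], n_perm=100)

    def test_binomial_oracle(self):
        # 6/8 links down; universe down-rate 10%
        universe = [f"g{i}" for i in range(1000)]
        flags = {g: i < 100 for i, g in enumerate(universe)}
        links = universe[:6] + universe[990:992]
        frac, p = target_downregulation_permutation(links, flags, universe,
                                                    n_perm=10_000, seed=3)
        assert frac == pytest.approx(6 / 8)
        oracle = stats.hypergeom.sf(6 - 1, 1000, 100, 8)
        se = np.sqrt(oracle * (1 - oracle) / 10_000)
        assert abs(p - oracle) <= 3 * se + 2e-4

    def test_deterministic(self):
        universe = [f"g{i}" for i in range(100)]
        flags = {g: i % 3 == 0 for i, g in enumerate(universe)}
        a = target_downregulation_permutation(universe[:5], flags, universe, 1000, seed=9)
        b = target_downregulation_permutation(universe[:5], flags, universe, 1000, seed=9)
        assert a == b


def test_expression_correlation_screen(rng):
    x = rng.uniform(0, 10, size=30)
    assert expression_correlation_screen(x, x * 2 + rng.normal(0, 0.5, 30))
    assert not expression_correlation_screen(x, rng.uniform(0, 10, size=30))
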