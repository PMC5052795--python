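"""Downstream statistics: GWAS SNP enrichment against a background SNP
catalog, gene-set (hallmark/oncogene) Fisher enrichment, TF density and
summit co-occupancy, binned meta-profiles, knockdown H3K27ac-depletion
calls with their null from wild-type replicate variation, the
target-downregulation permutation test, and conservation scoring."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import Region
from .signal_processing import SignalTrack, compute_rpkm, empirical_quantile

log = logging.getLogger("somase")

MIN_TRAIT_SNPS = 10
TF_MIN_OVERLAP_FRAC = 0.6
COOCCUPANCY_WINDOW_BP = 500
SUBREGION_WIDTH_BP = 1_000
CONSERVATION_FLANK_BP = 500

# re-exported shared core
from .gene_assignment import EnrichmentResult, fisher_enrichment as geneset_enrichment  # noqa: E402,F401


@dataclass
class SnpEnrichmentResult:
    trait: str
    n_gwas_in: int
    n_gwas_out: int
    n_background_in: int
    n_background_out: int
    enrichment_ratio: float
    chi2_p: float


@dataclass
class DepletionCall:
    subregion: Region
    wt_minus_kd: float
    state: str  # depleted | gained | unchanged


@dataclass
class TfOccupancy:
    tf_name: str
    n_sites: int
    density_per_mbp: float


# ---------------------------------------------------------------------------
# interval membership helpers
# ---------------------------------------------------------------------------

class _RegionIndex:
    """Point/interval membership against a merged, sorted region set."""

    def __init__(self, regions: list[Region]):
        self.by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        tmp: dict[str, list[Region]] = {}
        for r in regions:
            tmp.setdefault(r.chrom, []).append(r)
        for chrom, regs in tmp.items():
            regs.sort(key=lambda r: r.start)
            for a, b in zip(regs, regs[1:]):
                if b.start < a.end:
                    raise ValueError("region set must be non-overlapping (merge first)")
            self.by_chrom[chrom] = (
                np.array([r.start for r in regs], dtype=np.int64),
                np.array([r.end for r in regs], dtype=np.int64),
            )
        self.total_bp = sum(len(r) for r in regions)

    def contains_point(self, chrom: str, pos: int) -> bool:
        idx = self.by_chrom.get(chrom)
        if idx is None:
            return False
        starts, ends = idx
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        return i >= 0 and pos < ends[i]

    def overlap_bp(self, region: Region) -> int:
        idx = self.by_chrom.get(region.chrom)
        if idx is None:
            return 0
        starts, ends = idx
        i0 = max(int(np.searchsorted(ends, region.start, side="right")), 0)
        i1 = int(np.searchsorted(starts, region.end, side="left"))
        total = 0
        for j in range(i0, i1):
            total += max(0, min(int(ends[j]), region.end) - max(int(starts[j]), region.start))
        return total


# ---------------------------------------------------------------------------
# SNP enrichment
# ---------------------------------------------------------------------------

def snp_enrichment(trait_snps: pd.DataFrame, background_snps: pd.DataFrame,
                   se_set: list[Region], min_trait_snps: int = MIN_TRAIT_SNPS,
                   continuity_correction: bool = False) -> list[SnpEnrichmentResult]:
    """Per-trait SNP enrichment in a super-enhancer set.

    enrichment_ratio = (nGWAS_in/nGWAS_out) / (nBackground_in/nBackground_out);
    significance by a 1-df chi-square on the 2x2 counts (no continuity
    correction by default).  Traits with fewer than ``min_trait_snps`` SNPs
    inside the SE set are excluded (logged).
    """
    if background_snps.empty:
        raise ValueError("empty background SNP catalog")
    index = _RegionIndex(se_set)

    def _counts(df: pd.DataFrame) -> tuple[int, int]:
        inside = sum(index.contains_point(c, p) for c, p in zip(df["chrom"], df["pos"]))
        return inside, len(df) - inside

    bg_in, bg_out = _counts(background_snps)
    results = []
    for trait, sub in trait_snps.groupby("trait"):
        g_in, g_out = _counts(sub)
        if g_in < min_trait_snps:
            log.info("trait %s excluded: only %d SNPs inside SE set", trait, g_in)
            continue
        if g_out == 0 or bg_in == 0 or bg_out == 0:
            ratio = float("nan")
        else:
            ratio = (g_in / g_out) / (bg_in / bg_out)
        table = np.array([[g_in, g_out], [bg_in, bg_out]])
        if table.sum() == 0 or (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
            p = float("nan")
        else:
            p = float(stats.chi2_contingency(table, correction=continuity_correction)[1])
        results.append(SnpEnrichmentResult(
            trait=str(trait), n_gwas_in=g_in, n_gwas_out=g_out,
            n_background_in=bg_in, n_background_out=bg_out,
            enrichment_ratio=ratio, chi2_p=p,
        ))
    return results


# ---------------------------------------------------------------------------
# TF occupancy
# ---------------------------------------------------------------------------

def tf_density(sites: list[Region], region_set: list[Region],
               min_overlap_frac: float = TF_MIN_OVERLAP_FRAC,
               tf_name: str = "TF") -> TfOccupancy:
    """Binding density: sites with >= 60% of their length inside the region
    set, divided by the total region size in Mbp."""
    index = _RegionIndex(region_set)
    if index.total_bp == 0:
        raise ValueError("zero-length region set")
    count = 0
    for s in sites:
        if index.overlap_bp(s) >= min_overlap_frac * len(s):
            count += 1
    return TfOccupancy(tf_name=tf_name, n_sites=count,
                       density_per_mbp=count / (index.total_bp / 1e6))


def cooccupancy(summits_a: list[tuple[str, int]], summits_b: list[tuple[str, int]],
                window: int = COOCCUPANCY_WINDOW_BP) -> float:
    """Fraction of A summits with a B summit within ``window`` bp."""
    if not summits_a:
        raise ValueError("empty summit set A")
    if not summits_b:
        return 0.0
    b_by_chrom: dict[str, np.ndarray] = {}
    for chrom, pos in summits_b:
        b_by_chrom.setdefault(chrom, []).append(pos)  # type: ignore[attr-defined]
    b_by_chrom = {c: np.sort(np.array(v, dtype=np.int64)) for c, v in b_by_chrom.items()}
    hits = 0
    for chrom, pos in summits_a:
        arr = b_by_chrom.get(chrom)
        if arr is None:
            continue
        i = int(np.searchsorted(arr, pos))
        dmin = min((abs(int(arr[j]) - pos) for j in (i - 1, i) if 0 <= j < len(arr)),
                   default=None)
        if dmin is not None and dmin <= window:
            hits += 1
    return hits / len(summits_a)


def summit_positions(summits: list[Region]) -> list[tuple[str, int]]:
    """Summit BED rows to (chrom, point) using the interval midpoint."""
    return [(s.chrom, s.center) for s in summits]


# ---------------------------------------------------------------------------
# profiles and conservation
# ---------------------------------------------------------------------------

def binned_profile(track: SignalTrack, regions: list[Region], n_bins: int = 200) -> np.ndarray:
    """Regions x n_bins RPKM matrix over equal-width slices of each region.

    Genome bins partially covered by a slice are prorated; per region,
    sum(slice_rpkm * slice_len) equals region_rpkm * region_len.
    """
    out = np.empty((len(regions), n_bins))
    for i, r in enumerate(regions):
        if len(r) < n_bins:
            raise ValueError(f"region {r} shorter than {n_bins} bp")
        edges = np.linspace(r.start, r.end, n_bins + 1)
        cum = np.array([track.reads_up_to(r.chrom, e) for e in edges])
        reads = np.diff(cum)
        widths = np.diff(edges)
        out[i] = reads * 1e9 / (track.library_size * widths)
    return out


def conservation_max(region: Region, scores: dict[str, np.ndarray], bin_size: int,
                     flank: int = CONSERVATION_FLANK_BP) -> float:
    """Maximum conservation score within ``flank`` bp of the region midpoint.

    ``scores`` are per-chromosome binned score vectors (NaN = no coverage).
    Returns NaN when the window has no covered score.
    """
    vec = scores.get(region.chrom)
    if vec is None:
        return float("nan")
    mid = region.center
    lo = max(mid - flank, 0)
    hi = min(mid + flank, len(vec) * bin_size - 1)
    window = vec[lo // bin_size : hi // bin_size + 1]
    window = window[~np.isnan(window)]
    if len(window) == 0:
        return float("nan")
    return float(np.max(window))


# ---------------------------------------------------------------------------
# knockdown depletion
# ---------------------------------------------------------------------------

def tile_regions(regions: list[Region], width: int = SUBREGION_WIDTH_BP) -> list[Region]:
    """Tile each region with fixed-width subregions (trailing remainder
    shorter than ``width`` is dropped)."""
    tiles = []
    for r in regions:
        for start in range(r.start, r.end - width + 1, width):
            tiles.append(Region(r.chrom, start, start + width, r.id))
    return tiles


def knockdown_depletion(wt_tracks: list[SignalTrack], kd_track: SignalTrack,
                        analysis_regions: list[Region],
                        subregion_width: int = SUBREGION_WIDTH_BP,
                        ) -> tuple[list[DepletionCall], float, float]:
    """Depletion/gain calls from wild-type background variation.

    Background variation pools, over all subregions, the leave-one-out
    differences mean(WT without i) - WT_i for every replicate i; q1/q99 are
    its empirical 1st/99th percentiles.  Per subregion the tested statistic
    is mean(WT) - KD: > q99 -> depleted, < q1 -> gained, else unchanged.
    """
    if len(wt_tracks) < 2:
        raise ValueError("need >= 2 wild-type replicates to estimate background variation")
    tiles = tile_regions(analysis_regions, subregion_width)
    if not tiles:
        raise ValueError("no subregions: analysis regions shorter than subregion width")
    wt = np.array([[compute_rpkm(t, s) for s in tiles] for t in wt_tracks])
    kd = np.array([compute_rpkm(kd_track, s) for s in tiles])
    n_rep = len(wt_tracks)
    background = []
    for i in range(n_rep):
        others = np.delete(wt, i, axis=0).mean(axis=0)
        background.append(others - wt[i])
    background = np.concatenate(background)
    q1 = empirical_quantile(background, 0.01)
    q99 = empirical_quantile(background, 0.99)
    diffs = wt.mean(axis=0) - kd
    calls = []
    for s, d in zip(tiles, diffs):
        state = "depleted" if d > q99 else ("gained" if d < q1 else "unchanged")
        calls.append(DepletionCall(subregion=s, wt_minus_kd=float(d), state=state))
    return calls, q1, q99


def depletion_se_vs_typical(calls: list[DepletionCall], se_set: list[Region],
                            typical_set: list[Region]) -> float:
    """One-sided Wilcoxon rank-sum p that depletion magnitude in SE
    subregions exceeds that in typical-enhancer subregions."""
    se_idx = _RegionIndex(se_set)
    te_idx = _RegionIndex(typical_set)
    se_vals, te_vals = [], []
    for c in calls:
        mid = c.subregion.center
        if se_idx.contains_point(c.subregion.chrom, mid):
            se_vals.append(c.wt_minus_kd)
        elif te_idx.contains_point(c.subregion.chrom, mid):
            te_vals.append(c.wt_minus_kd)
    if not se_vals or not te_vals:
        return float("nan")
    return float(stats.mannwhitneyu(se_vals, te_vals, alternative="greater").pvalue)


# ---------------------------------------------------------------------------
# target downregulation permutation
# ---------------------------------------------------------------------------

def target_downregulation_permutation(linked_genes: list[str],
                                      down_flags: dict[str, bool],
                                      universe: list[str],
                                      n_perm: int = 10_000,
                                      seed: int | None = None) -> tuple[float, float]:
    """Empirical test for downregulation of depleted-SE target genes.

    Observed statistic: number of downregulated genes among the links.
    Null: reassign the links to genes drawn uniformly without replacement
    from the universe; p = (1 + #{perm count >= observed}) / (1 + n_perm).
    Returns (observed fraction down, empirical p).
    """
    if not linked_genes:
        raise ValueError("empty link set")
    missing = [g for g in linked_genes if g not in down_flags]
    if missing:
        raise ValueError(f"genes without expression-change flags: {missing[:5]}")
    rng = np.random.default_rng(seed)
    observed = sum(bool(down_flags[g]) for g in linked_genes)
    k = len(linked_genes)
    n_down = sum(bool(down_flags[g]) for g in universe)
    n_univ = len(universe)
    if k > n_univ:
        raise ValueError("more links than universe genes")
    # drawing k genes without replacement and counting downregulated ones
    # is exactly a hypergeometric draw
    null_counts = rng.hypergeometric(n_down, n_univ - n_down, k, size=n_perm)
    p = (1.0 + int(np.sum(null_counts >= observed))) / (1.0 + n_perm)
    return observed / k, float(p)


def expression_correlation_screen(se_signals: np.ndarray, gene_fpkm: np.ndarray,
                                  r_min: float = 0.4, p_max: float = 0.05) -> bool:
    """Pearson screen for SE->gene pairs: keep iff r > 0.4 and two-sided
    t-test p < 0.05."""
    r, p = stats.pearsonr(se_signals, gene_fpkm)
    return bool(r > r_min and p < p_max)
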