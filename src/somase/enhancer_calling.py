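"""Candidate region calling, distal/ratio filtering into predicted
enhancers, cross-sample catalog merging, and rank-product recurrence.

Predicted enhancers are H3K27ac-enriched regions at least 2,500 bp from
every annotated TSS whose aggregate H3K4me3/H3K4me1 log2 ratio (with
pseudocount) is at most 2.4.  Recurrence is scored by the rank product of
per-line signal ranks against a permutation null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .io_formats import GenomeModel, Region, TssAnnotation
from .signal_processing import SignalTrack, compute_rpkm

log = logging.getLogger("somase")

DISTAL_MIN_BP = 2_500
K4_RATIO_MAX = 2.4
K4_PSEUDOCOUNT = 0.1


@dataclass
class EnhancerCall:
    region: Region
    distance_to_tss: int
    k4_log_ratio: float
    is_distal: bool
    sample_rpkm: dict[str, float] = field(default_factory=dict)
    present_in: set[str] = field(default_factory=set)


@dataclass
class RecurrenceResult:
    region_id: str
    ranks: np.ndarray
    rank_product: float
    p_empirical: float
    is_recurrent: bool


def call_candidate_regions(corrected_bins: dict[str, np.ndarray], genome: GenomeModel,
                           threshold: float, min_width: int = 200) -> list[Region]:
    """Maximal runs of contiguous bins with corrected signal strictly above
    ``threshold``, kept if at least ``min_width`` bp wide."""
    bs = genome.bin_size
    out: list[Region] = []
    for chrom in genome.chrom_names:
        vec = corrected_bins[chrom]
        above = vec > threshold
        if not above.any():
            continue
        edges = np.diff(above.astype(np.int8))
        starts = list(np.nonzero(edges == 1)[0] + 1)
        ends = list(np.nonzero(edges == -1)[0] + 1)
        if above[0]:
            starts.insert(0, 0)
        if above[-1]:
            ends.append(len(vec))
        for i0, i1 in zip(starts, ends):
            start, end = i0 * bs, min(i1 * bs, genome.lengths[chrom])
            if end - start >= min_width:
                out.append(Region(chrom, start, end))
    return out


def distance_to_nearest_tss(region: Region, tss_positions: dict[str, np.ndarray]) -> int:
    """Minimum over covered bases of |base - tss_pos| (0 if a TSS is inside)."""
    pos = tss_positions.get(region.chrom)
    if pos is None or len(pos) == 0:
        return np.iinfo(np.int64).max
    i = int(np.searchsorted(pos, region.start))
    best = np.iinfo(np.int64).max
    for j in (i - 1, i, i + 1):
        if 0 <= j < len(pos):
            t = int(pos[j])
            if region.start <= t < region.end:
                return 0
            best = min(best, min(abs(region.start - t), abs(region.end - 1 - t)))
    return best


def tss_position_index(tss: list[TssAnnotation]) -> dict[str, np.ndarray]:
    by_chrom: dict[str, list[int]] = {}
    for t in tss:
        by_chrom.setdefault(t.chrom, []).append(t.tss_pos)
    return {c: np.sort(np.array(p, dtype=np.int64)) for c, p in by_chrom.items()}


def k4_log_ratio(region: Region, k4me3: SignalTrack, k4me1: SignalTrack,
                 pseudocount: float = K4_PSEUDOCOUNT) -> float:
    """log2((H3K4me3 RPKM + c) / (H3K4me1 RPKM + c)) over a region."""
    me3 = compute_rpkm(k4me3, region)
    me1 = compute_rpkm(k4me1, region)
    return float(np.log2((me3 + pseudocount) / (me1 + pseudocount)))


def filter_to_predicted_enhancers(candidates: list[Region], tss: list[TssAnnotation],
                                  k4me3_aggregate: SignalTrack, k4me1_aggregate: SignalTrack,
                                  pseudocount: float = K4_PSEUDOCOUNT,
                                  min_distal_bp: int = DISTAL_MIN_BP,
                                  max_ratio: float = K4_RATIO_MAX) -> list[EnhancerCall]:
    """Keep candidates that are distal (>= 2.5 kb from every TSS) and not
    promoter-like (aggregate H3K4me3/H3K4me1 log2 ratio <= 2.4)."""
    if not tss:
        raise ValueError("empty TSS annotation")
    index = tss_position_index(tss)
    calls = []
    for region in candidates:
        d = distance_to_nearest_tss(region, index)
        ratio = k4_log_ratio(region, k4me3_aggregate, k4me1_aggregate, pseudocount)
        is_distal = d >= min_distal_bp
        if is_distal and ratio <= max_ratio:
            calls.append(EnhancerCall(region=region, distance_to_tss=d,
                                      k4_log_ratio=ratio, is_distal=True))
    return calls


def merge_regions(regions: list[tuple[Region, str]]) -> list[tuple[Region, set[str]]]:
    """Merge intervals overlapping by >= 1 bp (transitively) across samples.

    Returns the union span of each merged group with its contributing
    sample set.  Book-ended intervals (gap 0, overlap 0) are NOT merged.
    """
    tagged = sorted(regions, key=lambda x: (x[0].chrom, x[0].start, x[0].end))
    merged: list[tuple[Region, set[str]]] = []
    for region, sample in tagged:
        if merged and merged[-1][0].chrom == region.chrom and region.start < merged[-1][0].end:
            prev, samples = merged.pop()
            merged.append(
                (Region(prev.chrom, prev.start, max(prev.end, region.end)),
                 samples | {sample})
            )
        else:
            merged.append((region, {sample}))
    return merged


def merge_catalog(calls_by_sample: dict[str, list[Region]],
                  id_prefix: str = "region") -> list[EnhancerCall]:
    """Unified cross-sample catalog: one-base-overlap merging with
    ``present_in`` recording the contributing samples."""
    tagged = [(r, s) for s, regs in calls_by_sample.items() for r in regs]
    out = []
    for i, (region, samples) in enumerate(merge_regions(tagged)):
        r = Region(region.chrom, region.start, region.end, f"{id_prefix}_{i:05d}")
        out.append(EnhancerCall(region=r, distance_to_tss=-1, k4_log_ratio=np.nan,
                                is_distal=True, present_in=samples))
    return out


def rank_product_recurrence(signal_matrix: np.ndarray, n_perm: int = 10_000,
                            seed: int | None = None,
                            region_ids: list[str] | None = None,
                            present_matrix: np.ndarray | None = None,
                            ) -> list[RecurrenceResult]:
    """Rank-product recurrence scores with a permutation null.

    Per line, regions are ranked by descending signal (1 = strongest,
    average ranks on ties) and the ranks multiplied across lines.  The null
    reshuffles each line's rank vector independently ``n_perm`` times;
    ``p = (1 + #{null RP <= observed RP}) / (1 + n_perm)``.
    """
    mat = np.asarray(signal_matrix, dtype=float)
    if mat.ndim != 2 or mat.shape[1] < 2:
        raise ValueError("signal matrix must be regions x lines with >= 2 lines")
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    n_regions, n_lines = mat.shape
    ranks = rankdata(-mat, axis=0, method="average")
    # work in log space: monotone in the product, immune to overflow
    obs_log = np.sum(np.log(ranks), axis=1)
    rng = np.random.default_rng(seed)
    count = np.zeros(n_regions, dtype=np.int64)
    log_ranks = np.log(ranks)
    for _ in range(n_perm):
        null_log = np.zeros(n_regions)
        for j in range(n_lines):
            null_log += rng.permutation(log_ranks[:, j])
        count += null_log <= obs_log + 1e-12
    p = (1.0 + count) / (1.0 + n_perm)
    if region_ids is None:
        region_ids = [f"region_{i:05d}" for i in range(n_regions)]
    results = []
    for i in range(n_regions):
        if present_matrix is not None:
            recurrent = int(np.sum(present_matrix[i])) >= 2
        else:
            recurrent = False
        results.append(RecurrenceResult(
            region_id=region_ids[i], ranks=ranks[i],
            rank_product=float(np.prod(ranks[i])),
            p_empirical=float(p[i]), is_recurrent=recurrent,
        ))
    return results
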