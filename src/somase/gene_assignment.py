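"""Active-promoter definition and nearest-active-TSS assignment of
super-enhancers, plus the oncogene Fisher enrichment shared with the
gene-set statistics."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io_formats import Region, TssAnnotation
from .signal_processing import BackgroundModel, SignalTrack, corrected_rpkm

log = logging.getLogger("somase")

PROMOTER_FLANK_BP = 500


@dataclass
class GeneLink:
    se_id: str
    gene_id: str
    tss_pos: int
    distance: int
    is_closest_gene_overall: bool


@dataclass
class EnrichmentResult:
    n_overlap: int
    n_query: int
    n_set: int
    n_universe: int
    odds_ratio: float
    p_value: float


def promoter_window(tss: TssAnnotation, chrom_length: int,
                    flank: int = PROMOTER_FLANK_BP) -> Region:
    start = max(tss.tss_pos - flank, 0)
    end = min(tss.tss_pos + flank, chrom_length)
    return Region(tss.chrom, start, end, tss.gene_id)


def active_promoters(tss: list[TssAnnotation],
                     chip_tracks: list[tuple[SignalTrack, SignalTrack | None]],
                     background: BackgroundModel,
                     rule: str = "any") -> list[TssAnnotation]:
    """TSSs whose 500-bp-flanked promoter window has corrected H3K27ac RPKM
    strictly above the background 99th percentile.

    ``rule='any'`` (default): active if above threshold in at least one
    sample of the analysis set; ``rule='majority'`` requires more than half.
    """
    if rule not in ("any", "majority"):
        raise ValueError("rule must be 'any' or 'majority'")
    active = []
    for t in tss:
        genome = chip_tracks[0][0].genome
        window = promoter_window(t, genome.lengths[t.chrom])
        n_above = sum(
            corrected_rpkm(chip, inp, window) > background.threshold_p99
            for chip, inp in chip_tracks
        )
        ok = n_above >= 1 if rule == "any" else n_above > len(chip_tracks) / 2
        if ok:
            active.append(t)
    return active


def _nearest(center: int, positions: np.ndarray) -> int:
    """Index of the position nearest to ``center``; ties to the smaller
    coordinate."""
    i = int(np.searchsorted(positions, center))
    candidates = [j for j in (i - 1, i) if 0 <= j < len(positions)]
    # smaller coordinate first, so strict '<' keeps it on distance ties
    best = candidates[0]
    for j in candidates[1:]:
        if abs(int(positions[j]) - center) < abs(int(positions[best]) - center):
            best = j
    return best


def assign_nearest_active(se: Region, active_tss: list[TssAnnotation],
                          all_tss: list[TssAnnotation] | None = None) -> GeneLink | None:
    """Link a super-enhancer to the active TSS nearest its center.

    Distance is |center - tss_pos| with the center at floor((start+end)/2);
    equidistant TSSs resolve to the smaller coordinate.  Returns None (and
    logs) when the SE's chromosome has no active TSS.
    """
    on_chrom = sorted((t for t in active_tss if t.chrom == se.chrom),
                      key=lambda t: (t.tss_pos, t.gene_id))
    if not on_chrom:
        log.info("SE %s: no active TSS on %s; unassigned", se.id or se, se.chrom)
        return None
    center = se.center
    positions = np.array([t.tss_pos for t in on_chrom], dtype=np.int64)
    best = on_chrom[_nearest(center, positions)]

    is_closest_overall = True
    if all_tss is not None:
        overall = sorted((t for t in all_tss if t.chrom == se.chrom),
                         key=lambda t: (t.tss_pos, t.gene_id))
        if overall:
            opos = np.array([t.tss_pos for t in overall], dtype=np.int64)
            is_closest_overall = overall[_nearest(center, opos)].gene_id == best.gene_id

    return GeneLink(se_id=se.id or f"{se.chrom}:{se.start}-{se.end}",
                    gene_id=best.gene_id, tss_pos=best.tss_pos,
                    distance=abs(center - best.tss_pos),
                    is_closest_gene_overall=is_closest_overall)


def fisher_enrichment(query_genes: set[str], gene_set: set[str],
                      universe: set[str]) -> EnrichmentResult:
    """One-sided (greater) Fisher's exact test of query/set overlap.

    2x2 table: [[|Q&S|, |Q\\S|], [|S\\Q|, |U\\(Q|S)|]].
    """
    if not universe:
        raise ValueError("empty universe")
    if not (query_genes <= universe and gene_set <= universe):
        raise ValueError("universe must contain query genes and gene set")
    a = len(query_genes & gene_set)
    b = len(query_genes - gene_set)
    c = len(gene_set - query_genes)
    d = len(universe) - a - b - c
    odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
    return EnrichmentResult(n_overlap=a, n_query=len(query_genes), n_set=len(gene_set),
                            n_universe=len(universe), odds_ratio=float(odds),
                            p_value=float(p))


def oncogene_enrichment(linked_genes: set[str], oncogene_set: set[str],
                        universe: set[str]) -> EnrichmentResult:
    """Oncogene enrichment of SE-linked genes (top-500 list convention)."""
    return fisher_enrichment(linked_genes, oncogene_set, universe)
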