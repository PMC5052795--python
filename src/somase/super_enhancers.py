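"""Stitching of predicted enhancers into super-enhancer candidates and the
rank-signal elbow (hockey-stick) cutoff separating super from typical
enhancers."""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .io_formats import Region
from .enhancer_calling import EnhancerCall, merge_regions
from .signal_processing import SignalTrack, corrected_rpkm

log = logging.getLogger("somase")

STITCH_GAP_BP = 12_500


@dataclass
class StitchedRegion:
    region: Region
    constituents: list[Region]
    total_signal: float = 0.0
    is_super: bool = False


@dataclass
class CutoffResult:
    sorted_signals: np.ndarray
    scaled_x: np.ndarray
    scaled_y: np.ndarray
    cutoff_index: int
    cutoff_signal: float


def stitch(enhancers: list[Region], gap: int = STITCH_GAP_BP) -> list[StitchedRegion]:
    """Transitively chain sorted, non-overlapping enhancers whose
    inter-interval gap is at most ``gap`` bp."""
    for a, b in zip(enhancers, enhancers[1:]):
        if (a.chrom, a.start, a.end) > (b.chrom, b.start, b.end):
            raise ValueError("enhancers must be sorted by (chrom, start)")
        if a.chrom == b.chrom and b.start < a.end:
            raise ValueError("enhancers must be non-overlapping within a sample")
    out: list[StitchedRegion] = []
    current: list[Region] = []
    for r in enhancers:
        if current and r.chrom == current[-1].chrom and r.start - current[-1].end <= gap:
            current.append(r)
        else:
            if current:
                out.append(_close(current))
            current = [r]
    if current:
        out.append(_close(current))
    return out


def _close(constituents: list[Region]) -> StitchedRegion:
    span = Region(constituents[0].chrom, constituents[0].start, constituents[-1].end)
    return StitchedRegion(region=span, constituents=list(constituents))


def stitched_signal(stitched: StitchedRegion, chip: SignalTrack,
                    input_track: SignalTrack | None) -> float:
    """Ranking signal: input-corrected reads summed over constituents,
    RPKM-normalized on the stitched extent."""
    span_len = len(stitched.region)
    total = 0.0
    for c in stitched.constituents:
        total += corrected_rpkm(chip, input_track, c) * len(c)
    return total / span_len


def se_cutoff(signals: np.ndarray) -> tuple[CutoffResult, np.ndarray]:
    """Hockey-stick cutoff: the slope-1 tangent point of the ranked-signal
    curve scaled to the unit square.

    Signals are sorted ascending; with ``x_i = i/(n-1)`` and ``y`` min-max
    scaled, the cutoff index is ``argmax(x - y)`` (ties broken toward the
    largest index).  A region is super iff its signal strictly exceeds the
    cutoff signal.
    """
    s = np.asarray(signals, dtype=float)
    if len(s) < 3:
        raise ValueError("need at least 3 stitched regions")
    if np.any(s < 0):
        raise ValueError("signals must be non-negative")
    order = np.argsort(s, kind="stable")
    ss = s[order]
    n = len(ss)
    x = np.arange(n) / (n - 1)
    if ss[-1] == ss[0]:
        warnings.warn("all signals equal: no super-enhancers", stacklevel=2)
        y = np.zeros(n)
        cut = CutoffResult(ss, x, y, n - 1, float(ss[-1]))
        return cut, np.zeros(len(s), dtype=bool)
    y = (ss - ss[0]) / (ss[-1] - ss[0])
    d = x - y
    cutoff_index = int(len(d) - 1 - np.argmax(d[::-1]))  # ties -> largest index
    cutoff_signal = float(ss[cutoff_index])
    is_super = s > cutoff_signal
    return CutoffResult(ss, x, y, cutoff_index, cutoff_signal), is_super


def call_super_enhancers(stitched: list[StitchedRegion], chip: SignalTrack,
                         input_track: SignalTrack | None) -> CutoffResult:
    """Annotate stitched regions in place with total signal and is_super."""
    signals = np.array([stitched_signal(sr, chip, input_track) for sr in stitched])
    cut, flags = se_cutoff(signals)
    for sr, sig, flag in zip(stitched, signals, flags):
        sr.total_signal = float(sig)
        sr.is_super = bool(flag)
    return cut


def merge_se_across_lines(se_by_line: dict[str, list[Region]],
                          id_prefix: str = "SE") -> list[EnhancerCall]:
    """Non-redundant cross-line SE catalog (one-base-overlap merging)."""
    tagged = [(r, line) for line, regs in se_by_line.items() for r in regs]
    out = []
    for i, (region, lines) in enumerate(merge_regions(tagged)):
        r = Region(region.chrom, region.start, region.end, f"{id_prefix}_{i:05d}")
        out.append(EnhancerCall(region=r, distance_to_tss=-1, k4_log_ratio=np.nan,
                                is_distal=True, present_in=lines))
    return out


def typical_enhancers(enhancers: list[Region], se_catalog: list[Region]) -> list[Region]:
    """Predicted enhancers localizing to regions distinct from the merged
    super-enhancer territory (zero-overlap filter)."""
    by_chrom: dict[str, list[Region]] = {}
    for se in se_catalog:
        by_chrom.setdefault(se.chrom, []).append(se)
    for c in by_chrom:
        by_chrom[c].sort(key=lambda r: r.start)
    out = []
    for e in enhancers:
        ses = by_chrom.get(e.chrom, [])
        starts = np.array([r.start for r in ses])
        i = int(np.searchsorted(starts, e.end))  # SEs with start < e.end
        hit = False
        j = i - 1
        while j >= 0 and ses[j].end > e.start:  # SEs are disjoint and sorted
            if e.overlap(ses[j]) > 0:
                hit = True
                break
            j -= 1
        if not hit:
            out.append(e)
    return out
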