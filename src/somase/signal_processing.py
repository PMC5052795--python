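"""Window-based density quantification, input correction, empirical
background thresholds and library QC.

RPKM over a region is ``reads * 1e9 / (library_size * region_length)``,
computed from fixed-size bin counts with partial bins prorated by overlap
fraction.  Input correction is subtraction floored at zero.  The empirical
background threshold is the type-1 (inverted-CDF) 99th percentile of RPKM
over randomly sampled regions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io_formats import GenomeModel, Region

log = logging.getLogger("somase")


@dataclass
class SignalTrack:
    """Per-sample, per-mark binned read counts over a genome model."""

    sample_id: str
    mark: str
    library_size: int
    bins: dict[str, np.ndarray]
    genome: GenomeModel

    def __post_init__(self):
        if self.library_size <= 0:
            raise ValueError("library_size must be positive")
        for chrom, vec in self.bins.items():
            if np.any(vec < 0):
                raise ValueError(f"negative bin counts on {chrom}")
        self._cumsums: dict[str, np.ndarray] = {}

    def _cumsum(self, chrom: str) -> np.ndarray:
        cs = self._cumsums.get(chrom)
        if cs is None:
            cs = np.concatenate([[0.0], np.cumsum(self.bins[chrom])])
            self._cumsums[chrom] = cs
        return cs

    def reads_up_to(self, chrom: str, pos: float) -> float:
        """Cumulative reads in [0, pos), prorating the partial final bin."""
        bs = self.genome.bin_size
        vec = self.bins[chrom]
        cs = self._cumsum(chrom)
        pos = min(max(pos, 0.0), len(vec) * bs)
        i = int(pos // bs)
        if i >= len(vec):
            return float(cs[-1])
        return float(cs[i] + vec[i] * (pos - i * bs) / bs)

    def region_reads(self, region: Region) -> float:
        """Reads overlapping the region; partial bins prorated by overlap."""
        return self.reads_up_to(region.chrom, region.end) - self.reads_up_to(
            region.chrom, region.start
        )

    def bin_rpkm(self, chrom: str) -> np.ndarray:
        """Per-bin RPKM vector for one chromosome."""
        return self.bins[chrom] * (1e9 / (self.library_size * self.genome.bin_size))


def compute_rpkm(track: SignalTrack, region: Region) -> float:
    """Reads per million mapped reads per kilobase over a region."""
    if len(region) == 0:
        raise ValueError("zero-length region")
    if track.library_size <= 0:
        raise ValueError("library_size must be positive")
    track.genome.validate_region(region)
    return track.region_reads(region) * 1e9 / (track.library_size * len(region))


def input_correct(chip_rpkm, input_rpkm):
    """Input-corrected signal: ``max(chip - input, 0)``; vectorizes."""
    chip = np.asarray(chip_rpkm, dtype=float)
    inp = np.asarray(input_rpkm, dtype=float)
    if np.any(inp < 0) or np.any(chip < 0):
        raise ValueError("RPKM values must be non-negative")
    out = np.maximum(chip - inp, 0.0)
    return float(out) if out.ndim == 0 else out


def corrected_rpkm(chip: SignalTrack, inp: SignalTrack | None, region: Region) -> float:
    """Region RPKM of a ChIP track corrected against its matched input."""
    c = compute_rpkm(chip, region)
    if inp is None:
        return c
    return input_correct(c, compute_rpkm(inp, region))


def corrected_bin_rpkm(chip: SignalTrack, inp: SignalTrack | None, chrom: str) -> np.ndarray:
    """Per-bin input-corrected RPKM vector (floored at zero)."""
    c = chip.bin_rpkm(chrom)
    if inp is None:
        return c
    return np.maximum(c - inp.bin_rpkm(chrom), 0.0)


def empirical_quantile(values, q: float) -> float:
    """Type-1 (inverted-CDF) empirical quantile: ``sorted[ceil(q*n) - 1]``."""
    v = np.sort(np.asarray(values, dtype=float))
    n = len(v)
    if n == 0:
        raise ValueError("empty sample")
    idx = min(max(int(np.ceil(q * n)) - 1, 0), n - 1)
    return float(v[idx])


def _reads_up_to_vec(track: SignalTrack, chrom: str, positions: np.ndarray) -> np.ndarray:
    """Vectorized :meth:`SignalTrack.reads_up_to` for many positions."""
    bs = track.genome.bin_size
    vec = track.bins[chrom]
    cs = track._cumsum(chrom)
    pos = np.clip(positions.astype(float), 0.0, len(vec) * bs)
    i = np.minimum((pos // bs).astype(np.int64), len(vec) - 1)
    return cs[i] + vec[i] * (pos - i * bs) / bs


def region_rpkm_batch(track: SignalTrack, chroms: np.ndarray, starts: np.ndarray,
                      width: int, input_track: SignalTrack | None = None) -> np.ndarray:
    """Corrected RPKM for many fixed-width regions at once (background sampling)."""
    out = np.empty(len(starts))
    scale = 1e9 / (track.library_size * width)
    for chrom in np.unique(chroms):
        mask = chroms == chrom
        s = starts[mask]
        reads = _reads_up_to_vec(track, chrom, s + width) - _reads_up_to_vec(track, chrom, s)
        vals = reads * scale
        if input_track is not None:
            iscale = 1e9 / (input_track.library_size * width)
            ireads = (_reads_up_to_vec(input_track, chrom, s + width)
                      - _reads_up_to_vec(input_track, chrom, s))
            vals = np.maximum(vals - ireads * iscale, 0.0)
        out[mask] = vals
    return out


@dataclass
class BackgroundModel:
    """Empirical RPKM background from randomly sampled regions of one mark."""

    mark: str
    region_width: int
    n_samples: int
    values: np.ndarray
    threshold_p99: float


def sample_random_regions(genome: GenomeModel, width: int, n: int,
                          rng: np.random.Generator) -> list[Region]:
    """Uniformly sample ``n`` regions of ``width`` bp over the genome.

    Chromosomes are chosen proportionally to their placeable span; regions
    may overlap each other.
    """
    spans = np.array([max(genome.lengths[c] - width, 0) + 1 for c in genome.chrom_names],
                     dtype=float)
    if np.all(spans <= 1) and width > min(genome.chrom_lengths):
        raise ValueError("region width exceeds every chromosome length")
    probs = spans / spans.sum()
    chrom_idx = rng.choice(len(genome.chrom_names), size=n, p=probs)
    out = []
    for ci in chrom_idx:
        chrom = genome.chrom_names[ci]
        start = int(rng.integers(0, genome.lengths[chrom] - width + 1))
        out.append(Region(chrom, start, start + width))
    return out


def build_background(track: SignalTrack, region_width: int, n: int = 100_000,
                     seed: int | None = None, input_track: SignalTrack | None = None,
                     ) -> BackgroundModel:
    """Build an empirical background model from ``n`` random regions.

    The presence threshold is the type-1 99th percentile of the sampled
    (input-corrected, when an input track is given) RPKM values.
    """
    if n < 1_000:
        raise ValueError("n < 1000 gives an unstable 99th percentile")
    rng = np.random.default_rng(seed)
    regions = sample_random_regions(track.genome, region_width, n, rng)
    chroms = np.array([r.chrom for r in regions])
    starts = np.array([r.start for r in regions], dtype=np.int64)
    values = region_rpkm_batch(track, chroms, starts, region_width, input_track)
    return BackgroundModel(
        mark=track.mark, region_width=region_width, n_samples=n,
        values=values, threshold_p99=empirical_quantile(values, 0.99),
    )


def is_present(corrected_region_rpkm: float, model: BackgroundModel) -> bool:
    """Empirical presence call (P < 0.01): strictly above the 99th percentile."""
    return corrected_region_rpkm > model.threshold_p99


def qc_promoter_enrichment(chip: SignalTrack, input_track: SignalTrack,
                           promoters: list[Region]) -> tuple[float, bool]:
    """Promoter-enrichment QC for H3K27ac/H3K4me3 libraries.

    ratio = median promoter ChIP RPKM / median promoter input RPKM over the
    top promoters (500 bp flanked TSS windows); pass iff ratio > 4 (strict).
    A zero input median yields +inf and a pass.
    """
    if not promoters:
        raise ValueError("need at least one promoter region")
    chip_med = float(np.median([compute_rpkm(chip, p) for p in promoters]))
    inp_med = float(np.median([compute_rpkm(input_track, p) for p in promoters]))
    if inp_med == 0.0:
        return float("inf"), True
    ratio = chip_med / inp_med
    return ratio, ratio > 4.0


def aggregate_tracks(tracks: list[SignalTrack], mark: str | None = None) -> SignalTrack:
    """Pool tracks: summed bin counts, pooled library size."""
    if not tracks:
        raise ValueError("no tracks to aggregate")
    genome = tracks[0].genome
    bins = {c: np.zeros(genome.n_bins(c)) for c in genome.chrom_names}
    lib = 0
    for t in tracks:
        for c in genome.chrom_names:
            bins[c] += t.bins[c]
        lib += t.library_size
    return SignalTrack(sample_id="aggregate", mark=mark or tracks[0].mark,
                       library_size=lib, bins=bins, genome=genome)
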