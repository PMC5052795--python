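"""Seeded generator of a full multi-sample dataset with planted ground
truth, plus the truth-vs-calls recovery report.

The generator plants enhancer-shaped peaks (high H3K27ac + H3K4me1, low
H3K4me3 away from promoters; high H3K27ac + H3K4me3 at promoters of
expressed genes) as multiplicative enrichment over a negative-binomial
background, clusters constituents within stitchable gaps, applies
tumor/normal fold effects per somatic class, and couples expression,
methylation, TF summits and trait SNPs to the planted classes.  Identical
seeds give byte-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .io_formats import (Dataset, GenomeModel, Region, SampleInfo, TssAnnotation,
                         write_bed, write_bedgraph, write_snp_table, write_tss_table)
from .signal_processing import SignalTrack

log = logging.getLogger("somase")

SOMATIC_CLASSES = ("gain", "loss", "unaltered", "inactive")


class PlacementError(RuntimeError):
    """Cluster placement failed within the retry budget."""


@dataclass
class SomaticDesign:
    fractions: dict = field(default_factory=lambda: {
        "gain": 0.4, "loss": 0.2, "unaltered": 0.2, "inactive": 0.2})
    gain_fold: float = 3.0
    loss_fold: float = 1.0 / 3.0

    def __post_init__(self):
        total = sum(self.fractions.get(k, 0.0) for k in SOMATIC_CLASSES)
        if abs(total - 1.0) > 1e-9:
            raise ValueError("somatic class fractions must sum to 1")
        if self.gain_fold < 2.0:
            raise ValueError("gain fold must be >= 2 to exceed the classification threshold")


@dataclass
class SimulationDesign:
    """Knobs of the synthetic cohort.  Defaults give a 2 x 10 Mb genome,
    6 cell lines and 8 tumor/normal pairs."""

    n_cell_lines: int = 6
    n_pairs: int = 8
    chrom_names: tuple[str, ...] = ("chr1", "chr2")
    chrom_lengths: tuple[int, ...] = (10_000_000, 10_000_000)
    bin_size: int = 50
    n_genes: int = 300
    expressed_gene_fraction: float = 0.45
    n_enhancer_clusters: int = 120
    super_fraction: float = 0.2
    # typical clusters: sparse, moderate fold.  Kept bimodal against the
    # super clusters so the rank-signal curve has a clean elbow, and the
    # total planted footprint stays small enough that the empirical p99
    # background threshold (which does not exclude enhancer territory)
    # remains below every planted signal.
    constituents_per_cluster: tuple[int, int] = (2, 3)
    constituent_width: tuple[int, int] = (600, 1_000)
    intra_cluster_gap: tuple[int, int] = (4_000, 12_000)
    peak_fold: tuple[float, float] = (12.0, 18.0)
    # super clusters: dense, strong
    super_constituents: tuple[int, int] = (3, 6)
    super_constituent_width: tuple[int, int] = (1_200, 1_500)
    super_gap: tuple[int, int] = (800, 1_600)
    super_fold: tuple[float, float] = (30.0, 45.0)
    promoter_fold: tuple[float, float] = (70.0, 100.0)
    promoter_width: int = 600
    background_mean: float = 0.2
    dispersion: float = 20.0  # NB size; var = mu + mu^2 / dispersion
    somatic_design: SomaticDesign = field(default_factory=SomaticDesign)
    expression_coupling: float = 1.0
    methylation_coupling: float = 0.2
    tf_summit_rate: float = 1.0       # summits per kb of gain-SE constituent
    tf_background_rate: float = 0.02  # summits per kb genome-wide
    snp_enrichment_fold: float = 3.0
    n_background_snps: int = 20_000
    n_trait_snps: int = 800
    probes_per_cluster: int = 5
    n_background_probes: int = 400
    tss_margin: int = 3_500           # min cluster-span distance to any TSS
    cluster_separation: int = 13_000  # min gap between distinct cluster spans
    max_retries: int = 10_000
    seed: int = 0

    def __post_init__(self):
        for lo, hi in (self.constituent_width, self.intra_cluster_gap,
                       self.super_constituent_width, self.super_gap):
            if lo <= 0 or hi < lo:
                raise ValueError("widths/gaps must be positive ranges")
        if not (0 < self.super_fraction < 1):
            raise ValueError("super_fraction must be in (0,1)")
        if self.intra_cluster_gap[1] > 12_000 or self.super_gap[1] > 12_000:
            raise ValueError("intra-cluster gaps must stay stitchable (<= 12 kb)")
        if self.cluster_separation <= 12_500:
            raise ValueError("cluster separation must exceed the 12.5 kb stitch gap")

    @property
    def genome(self) -> GenomeModel:
        return GenomeModel(self.chrom_names, self.chrom_lengths, self.bin_size)


@dataclass
class ClusterTruth:
    cluster_id: str
    constituents: list[Region]
    span: Region
    is_super: bool
    somatic_class: str
    peak_fold: float
    active_lines: list[str]
    linked_gene: str
    expression_fold: float
    delta_beta: float
    tf_summits: list[int] = field(default_factory=list)


@dataclass
class GroundTruth:
    design: SimulationDesign
    clusters: list[ClusterTruth]
    tss: list[TssAnnotation]
    expressed_genes: set[str]

    @property
    def super_spans(self) -> list[Region]:
        return [c.span for c in self.clusters if c.is_super]

    @property
    def constituent_regions(self) -> list[Region]:
        return [r for c in self.clusters for r in c.constituents]


# ---------------------------------------------------------------------------
# placement
# ---------------------------------------------------------------------------

def _snap(value: int, bs: int) -> int:
    return max((int(value) // bs) * bs, bs)


def _place_genes(design: SimulationDesign, rng: np.random.Generator) -> list[TssAnnotation]:
    genome = design.genome
    min_sep = 4_000
    tss: list[TssAnnotation] = []
    placed: dict[str, list[int]] = {c: [] for c in design.chrom_names}
    lengths = np.array(design.chrom_lengths, dtype=float)
    probs = lengths / lengths.sum()
    i = 0
    attempts = 0
    while i < design.n_genes:
        attempts += 1
        if attempts > design.max_retries * design.n_genes:
            raise PlacementError("could not place genes")
        chrom = design.chrom_names[rng.choice(len(design.chrom_names), p=probs)]
        pos = int(rng.integers(10_000, genome.lengths[chrom] - 10_000))
        if any(abs(pos - q) < min_sep for q in placed[chrom][-50:]) or \
           any(abs(pos - q) < min_sep for q in placed[chrom]):
            continue
        placed[chrom].append(pos)
        strand = "+" if rng.random() < 0.5 else "-"
        tss.append(TssAnnotation(f"gene_{i:04d}", chrom, pos, strand))
        i += 1
    return tss


def _cluster_layout(design: SimulationDesign, rng: np.random.Generator,
                    is_super: bool) -> list[tuple[int, int]]:
    """Constituent (offset, width) pairs relative to the cluster start."""
    bs = design.bin_size
    if is_super:
        k = int(rng.integers(design.super_constituents[0], design.super_constituents[1] + 1))
        wlo, whi = design.super_constituent_width
        glo, ghi = design.super_gap
    else:
        k = int(rng.integers(design.constituents_per_cluster[0],
                             design.constituents_per_cluster[1] + 1))
        wlo, whi = design.constituent_width
        glo, ghi = design.intra_cluster_gap
    offsets = []
    pos = 0
    for j in range(k):
        w = _snap(int(rng.integers(wlo, whi + 1)), bs)
        offsets.append((pos, w))
        pos += w + _snap(int(rng.integers(glo, ghi + 1)), bs)
    return offsets


def _place_clusters(design: SimulationDesign, rng: np.random.Generator,
                    tss: list[TssAnnotation], expressed_pos: dict[str, np.ndarray],
                    ) -> list[tuple[str, int, list[tuple[int, int]], bool]]:
    """Rejection-sample cluster placements.

    A placement is accepted when the whole cluster span keeps
    ``tss_margin`` distance from every TSS, distinct spans stay more than
    ``cluster_separation`` apart, and the nearest expressed TSS (the
    cluster's linked gene by construction) is not already claimed by
    another cluster — so every planted expression effect targets a
    distinct gene.
    """
    genome = design.genome
    tss_pos = {c: np.sort(np.array([t.tss_pos for t in tss if t.chrom == c]))
               for c in design.chrom_names}
    spans: dict[str, list[tuple[int, int]]] = {c: [] for c in design.chrom_names}
    claimed: set[tuple[str, int]] = set()
    lengths = np.array(design.chrom_lengths, dtype=float)
    probs = lengths / lengths.sum()
    n_super = max(int(round(design.super_fraction * design.n_enhancer_clusters)), 1)
    placements = []
    for ci in range(design.n_enhancer_clusters):
        is_super = ci < n_super
        layout = _cluster_layout(design, rng, is_super)
        span_len = layout[-1][0] + layout[-1][1]
        ok = False
        for _ in range(design.max_retries):
            chrom = design.chrom_names[rng.choice(len(design.chrom_names), p=probs)]
            clen = genome.lengths[chrom]
            if clen - span_len - 20_000 <= 20_000:
                continue
            start = int(rng.integers(20_000, clen - span_len - 20_000))
            end = start + span_len
            pos = tss_pos[chrom]
            i = int(np.searchsorted(pos, start))
            near = [pos[j] for j in (i - 1, i) if 0 <= j < len(pos)]
            if any(start - design.tss_margin < p < end + design.tss_margin for p in near):
                continue
            if any(not (end + design.cluster_separation <= s
                        or e + design.cluster_separation <= start)
                   for s, e in spans[chrom]):
                continue
            linked = _nearest_expressed(expressed_pos, chrom, (start + end) // 2)
            if linked is None or (chrom, linked) in claimed:
                continue
            claimed.add((chrom, linked))
            spans[chrom].append((start, end))
            placements.append((chrom, start, layout, is_super))
            ok = True
            break
        if not ok:
            raise PlacementError(f"cluster {ci} placement failed after retries")
    return placements


def _nearest_expressed(expressed_pos: dict[str, np.ndarray], chrom: str,
                       center: int) -> int | None:
    pos = expressed_pos[chrom]
    if len(pos) == 0:
        return None
    i = int(np.searchsorted(pos, center))
    near = [int(pos[j]) for j in (i - 1, i) if 0 <= j < len(pos)]
    return min(near, key=lambda p: (abs(p - center), p))


# ---------------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------------

def _nb_counts(mean: np.ndarray, dispersion: float, rng: np.random.Generator) -> np.ndarray:
    """Negative-binomial bin counts with var = mu + mu^2/dispersion."""
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p).astype(np.float64)


def _class_scales(cls: str, sd: SomaticDesign) -> tuple[float, float]:
    """(normal, tumor) multipliers of the planted enhancer excess."""
    if cls == "gain":
        return 1.0, sd.gain_fold
    if cls == "loss":
        return 1.0, sd.loss_fold
    if cls == "unaltered":
        return 1.0, 1.0
    return 0.0, 0.0  # inactive: background only in primaries


def generate_dataset(design: SimulationDesign,
                     write_dir: str | Path | None = None) -> tuple[Dataset, GroundTruth]:
    """Generate the full synthetic dataset and its ground truth.

    With ``write_dir`` set, the dataset is also written in the exact file
    layout :func:`somase.io_formats.load_dataset` consumes (plus
    ``truth/*.tsv``).
    """
    rng = np.random.default_rng(design.seed)
    genome = design.genome
    sd = design.somatic_design

    tss = _place_genes(design, rng)
    n_expressed = int(round(design.expressed_gene_fraction * design.n_genes))
    expressed_idx = rng.choice(design.n_genes, size=n_expressed, replace=False)
    expressed = {tss[i].gene_id for i in expressed_idx}
    expressed_tss = [t for t in tss if t.gene_id in expressed]

    exp_pos_early = {c: np.sort(np.array([t.tss_pos for t in expressed_tss
                                          if t.chrom == c], dtype=np.int64))
                     for c in design.chrom_names}
    placements = _place_clusters(design, rng, tss, exp_pos_early)

    lines = [f"L{i + 1:02d}" for i in range(design.n_cell_lines)]
    patients = [f"P{i + 1:02d}" for i in range(design.n_pairs)]
    tumor_ids = [f"{p}T" for p in patients]
    normal_ids = [f"{p}N" for p in patients]

    class_names = list(SOMATIC_CLASSES)
    class_probs = np.array([sd.fractions[c] for c in class_names])

    clusters: list[ClusterTruth] = []
    exp_pos = {c: np.sort(np.array([t.tss_pos for t in expressed_tss if t.chrom == c]))
               for c in design.chrom_names}
    exp_by_pos = {(t.chrom, t.tss_pos): t.gene_id for t in expressed_tss}
    for ci, (chrom, start, layout, is_super) in enumerate(placements):
        constituents = [Region(chrom, start + off, start + off + w, f"cluster_{ci:03d}_c{j}")
                        for j, (off, w) in enumerate(layout)]
        span = Region(chrom, constituents[0].start, constituents[-1].end, f"cluster_{ci:03d}")
        cls = class_names[rng.choice(len(class_names), p=class_probs)]
        if is_super:
            fold = float(rng.uniform(*design.super_fold))
        else:
            fold = float(rng.uniform(*design.peak_fold))
        # active in a random subset of lines, biased toward recurrence
        n_active = int(rng.integers(2, design.n_cell_lines + 1)) \
            if rng.random() > 0.15 else 1
        active = sorted(rng.choice(lines, size=min(n_active, len(lines)), replace=False))
        # linked gene: nearest expressed TSS to the cluster center, by construction
        pos = exp_pos[chrom]
        i = int(np.searchsorted(pos, span.center))
        near = [int(pos[j]) for j in (i - 1, i) if 0 <= j < len(pos)]
        best = min(near, key=lambda p: (abs(p - span.center), p))
        linked = exp_by_pos[(chrom, best)]
        if cls == "gain":
            efold = sd.gain_fold ** design.expression_coupling
            dbeta = -design.methylation_coupling
        elif cls == "loss":
            efold = sd.loss_fold ** design.expression_coupling
            dbeta = design.methylation_coupling
        else:
            efold, dbeta = 1.0, 0.0
        clusters.append(ClusterTruth(
            cluster_id=f"cluster_{ci:03d}", constituents=constituents, span=span,
            is_super=is_super, somatic_class=cls, peak_fold=fold,
            active_lines=list(active), linked_gene=linked,
            expression_fold=efold, delta_beta=dbeta,
        ))

    # ---- signal tracks -----------------------------------------------------
    bs = design.bin_size
    bg = design.background_mean

    def _base_mult() -> dict[str, np.ndarray]:
        return {c: np.ones(genome.n_bins(c)) for c in design.chrom_names}

    def _add_regions(mult: dict[str, np.ndarray], regions: list[Region], factor: float):
        for r in regions:
            mult[r.chrom][r.start // bs: r.end // bs] += factor - 1.0

    half_pw = design.promoter_width // 2
    promoter_windows = [Region(t.chrom, max(t.tss_pos - half_pw, 0),
                               min(t.tss_pos + half_pw, genome.lengths[t.chrom]))
                        for t in expressed_tss]
    promoter_folds = rng.uniform(*design.promoter_fold, size=len(promoter_windows))

    tracks: dict[tuple[str, str], SignalTrack] = {}
    samples: list[SampleInfo] = []

    def _make_track(sample_id: str, role: str, mark: str,
                    mult: dict[str, np.ndarray], patient: str | None = None):
        lib = int(rng.lognormal(np.log(1e7), 0.1))
        depth = lib / 1e7  # coverage scales with sequencing depth, as in real data,
        # so RPKM normalization recovers the planted folds exactly
        bins = {c: _nb_counts(bg * depth * mult[c], design.dispersion, rng)
                for c in design.chrom_names}
        tracks[(sample_id, mark)] = SignalTrack(sample_id=sample_id, mark=mark,
                                                library_size=lib, bins=bins, genome=genome)
        samples.append(SampleInfo(sample_id=sample_id, role=role, mark=mark,
                                  path=f"tracks/{sample_id}_{mark}.bedgraph",
                                  library_size=lib, patient=patient))

    def _promoter_mult(mult: dict[str, np.ndarray]):
        for w, f in zip(promoter_windows, promoter_folds):
            mult[w.chrom][w.start // bs: w.end // bs] += f - 1.0

    for line in lines:
        active_clusters = [c for c in clusters if line in c.active_lines]
        m27 = _base_mult()
        m1 = _base_mult()
        m3 = _base_mult()
        for c in active_clusters:
            _add_regions(m27, c.constituents, c.peak_fold)
        for c in clusters:  # H3K4me1 marks enhancer chromatin in every line
            _add_regions(m1, c.constituents, c.peak_fold)
        _promoter_mult(m27)
        _promoter_mult(m3)
        _make_track(line, "cell_line", "H3K27ac", m27)
        _make_track(line, "cell_line", "H3K4me1", m1)
        _make_track(line, "cell_line", "H3K4me3", m3)
        _make_track(line, "cell_line", "input", _base_mult())

    pair_jitter = rng.lognormal(0.0, 0.05, size=(len(clusters), design.n_pairs))
    for pi, patient in enumerate(patients):
        for role, sid in (("tumor", tumor_ids[pi]), ("normal", normal_ids[pi])):
            m27 = _base_mult()
            for cj, c in enumerate(clusters):
                n_scale, t_scale = _class_scales(c.somatic_class, sd)
                scale = t_scale * pair_jitter[cj, pi] if role == "tumor" else n_scale
                if scale > 0:
                    _add_regions(m27, c.constituents, 1.0 + (c.peak_fold - 1.0) * scale)
            _promoter_mult(m27)
            _make_track(sid, role, "H3K27ac", m27, patient=patient)
            _make_track(sid, role, "input", _base_mult(), patient=patient)

    # ---- expression --------------------------------------------------------
    gene_ids = [t.gene_id for t in tss]
    base = np.where(np.isin(gene_ids, list(expressed)),
                    rng.lognormal(np.log(10.0), 0.5, size=len(gene_ids)), 0.02)
    fold_by_gene = {c.linked_gene: c.expression_fold for c in clusters}
    fpkm = {"gene_id": gene_ids}
    for pi in range(design.n_pairs):
        noise_t = rng.lognormal(0.0, 0.1, size=len(gene_ids))
        noise_n = rng.lognormal(0.0, 0.1, size=len(gene_ids))
        folds = np.array([fold_by_gene.get(g, 1.0) for g in gene_ids])
        fpkm[tumor_ids[pi]] = np.round(base * folds * noise_t, 4)
        fpkm[normal_ids[pi]] = np.round(base * noise_n, 4)
    fpkm_df = pd.DataFrame(fpkm)

    # ---- methylation -------------------------------------------------------
    rows = []
    for c in clusters:
        pos = np.sort(rng.integers(c.span.start, c.span.end, size=design.probes_per_cluster))
        for p in pos:
            rows.append((c.span.chrom, int(p), c.delta_beta))
    for _ in range(design.n_background_probes):
        chrom = design.chrom_names[int(rng.integers(len(design.chrom_names)))]
        rows.append((chrom, int(rng.integers(0, genome.lengths[chrom])), 0.0))
    beta = {"chrom": [r[0] for r in rows], "pos": [r[1] for r in rows]}
    deltas = np.array([r[2] for r in rows])
    for pi in range(design.n_pairs):
        normal_beta = np.clip(rng.normal(0.5, 0.05, size=len(rows)), 0.0, 1.0)
        tumor_beta = np.clip(normal_beta + deltas + rng.normal(0.0, 0.03, size=len(rows)),
                             0.0, 1.0)
        beta[tumor_ids[pi]] = np.round(tumor_beta, 4)
        beta[normal_ids[pi]] = np.round(normal_beta, 4)
    beta_df = pd.DataFrame(beta)

    # ---- TF summits --------------------------------------------------------
    tfa: list[Region] = []
    tfb: list[Region] = []
    for c in clusters:
        if c.somatic_class != "gain" or not c.is_super:
            continue
        for r in c.constituents:
            n_summits = rng.poisson(design.tf_summit_rate * len(r) / 1_000)
            for _ in range(n_summits):
                p = int(rng.integers(r.start, r.end))
                tfa.append(Region(r.chrom, p, p + 1))
                c.tf_summits.append(p)
                if rng.random() < 0.76:
                    q = int(np.clip(p + rng.integers(-400, 401), 0,
                                    genome.lengths[r.chrom] - 1))
                    tfb.append(Region(r.chrom, q, q + 1))
    for tf_list in (tfa, tfb):
        n_bgs = rng.poisson(design.tf_background_rate * genome.total_length / 1_000)
        for _ in range(n_bgs):
            chrom = design.chrom_names[int(rng.integers(len(design.chrom_names)))]
            p = int(rng.integers(0, genome.lengths[chrom]))
            tf_list.append(Region(chrom, p, p + 1))
    tfa.sort(key=lambda r: (r.chrom, r.start))
    tfb.sort(key=lambda r: (r.chrom, r.start))

    # ---- SNPs --------------------------------------------------------------
    somatic_spans = [c.span for c in clusters if c.somatic_class in ("gain", "loss")]
    a_in = sum(len(s) for s in somatic_spans)
    a_out = genome.total_length - a_in
    span_weights = np.array([len(s) for s in somatic_spans], dtype=float)
    span_weights /= span_weights.sum()

    def _uniform_pos() -> tuple[str, int]:
        chrom = design.chrom_names[int(rng.choice(
            len(design.chrom_names),
            p=np.array(design.chrom_lengths) / genome.total_length))]
        return chrom, int(rng.integers(0, genome.lengths[chrom]))

    def _inside_somatic(chrom: str, pos: int) -> bool:
        return any(s.chrom == chrom and s.start <= pos < s.end for s in somatic_spans)

    bg_rows = []
    for i in range(design.n_background_snps):
        chrom, pos = _uniform_pos()
        bg_rows.append((chrom, pos, f"bg_snp_{i:06d}", "background"))
    background_snps = pd.DataFrame(bg_rows, columns=["chrom", "pos", "id", "trait"])

    p_in = design.snp_enrichment_fold * a_in / (design.snp_enrichment_fold * a_in + a_out)
    trait_rows = []
    for i in range(design.n_trait_snps):
        if rng.random() < p_in:
            s = somatic_spans[int(rng.choice(len(somatic_spans), p=span_weights))]
            chrom, pos = s.chrom, int(rng.integers(s.start, s.end))
        else:
            chrom, pos = _uniform_pos()
            while _inside_somatic(chrom, pos):
                chrom, pos = _uniform_pos()
        trait_rows.append((chrom, pos, f"trait_snp_{i:06d}", "planted_trait"))
    trait_snps = pd.DataFrame(trait_rows, columns=["chrom", "pos", "id", "trait"])

    # ---- CNV ---------------------------------------------------------------
    cnv_rows = []
    for chrom in design.chrom_names:
        breaks = np.sort(rng.integers(0, genome.lengths[chrom], size=14))
        edges = np.concatenate([[0], breaks, [genome.lengths[chrom]]])
        for s, e in zip(edges[:-1], edges[1:]):
            if e <= s:
                continue
            u = rng.random()
            if u < 0.8:
                lr = float(rng.normal(0.0, 0.2))
            elif u < 0.9:
                lr = float(rng.uniform(0.7, 1.5))
            else:
                lr = float(rng.uniform(-2.0, -1.1))
            cnv_rows.append((chrom, int(s), int(e), round(lr, 4)))
    cnv_df = pd.DataFrame(cnv_rows, columns=["chrom", "start", "end", "log_ratio"])

    # ---- gene sets ---------------------------------------------------------
    gain_genes = sorted({c.linked_gene for c in clusters if c.somatic_class == "gain"})
    set_rows = []
    planted = set(rng.choice(gain_genes, size=max(len(gain_genes) * 3 // 5, 1),
                             replace=False))
    planted |= set(rng.choice(gene_ids, size=20, replace=False))
    for g in sorted(planted):
        set_rows.append(("planted_hallmark", g))
    for k in range(9):
        for g in sorted(rng.choice(gene_ids, size=30, replace=False)):
            set_rows.append((f"random_set_{k}", g))
    gene_sets_df = pd.DataFrame(set_rows, columns=["set_name", "gene_id"])

    dataset = Dataset(
        genome=genome, tracks=tracks, samples=samples, tss=tss,
        pairs=list(zip(tumor_ids, normal_ids)), cell_lines=lines,
        fpkm=fpkm_df, beta=beta_df, snps=trait_snps, background_snps=background_snps,
        cnv=cnv_df, summits={"TFA": tfa, "TFB": tfb},
        gene_sets={name: set(sub["gene_id"]) for name, sub in
                   gene_sets_df.groupby("set_name")},
    )
    truth = GroundTruth(design=design, clusters=clusters, tss=tss,
                        expressed_genes=expressed)
    if write_dir is not None:
        write_dataset(dataset, truth, write_dir, gene_sets_df)
    return dataset, truth


def write_dataset(dataset: Dataset, truth: GroundTruth, out_dir: str | Path,
                  gene_sets_df: pd.DataFrame | None = None) -> Path:
    """Write the dataset in the layout ``load_dataset`` consumes."""
    out = Path(out_dir)
    (out / "tracks").mkdir(parents=True, exist_ok=True)
    (out / "truth").mkdir(exist_ok=True)
    for info in dataset.samples:
        track = dataset.tracks[(info.sample_id, info.mark)]
        write_bedgraph(out / info.path, track.bins, dataset.genome)
    write_tss_table(out / "tss.tsv", dataset.tss)
    dataset.fpkm.to_csv(out / "fpkm.tsv", sep="\t", index=False)
    dataset.beta.to_csv(out / "beta.tsv", sep="\t", index=False)
    write_snp_table(out / "snps.tsv", dataset.snps)
    write_snp_table(out / "background_snps.tsv", dataset.background_snps)
    dataset.cnv.to_csv(out / "cnv.tsv", sep="\t", index=False)
    for tf, summits in dataset.summits.items():
        write_bed(out / f"summits_{tf}.bed", summits)
    if gene_sets_df is None:
        gene_sets_df = pd.DataFrame(
            [(name, g) for name in sorted(dataset.gene_sets)
             for g in sorted(dataset.gene_sets[name])],
            columns=["set_name", "gene_id"])
    gene_sets_df.to_csv(out / "gene_sets.tsv", sep="\t", index=False)

    manifest = {
        "genome": {
            "chrom_names": list(dataset.genome.chrom_names),
            "chrom_lengths": list(dataset.genome.chrom_lengths),
            "bin_size": dataset.genome.bin_size,
        },
        "samples": [
            {"id": s.sample_id, "role": s.role, "mark": s.mark, "path": s.path,
             "library_size": s.library_size,
             **({"patient": s.patient} if s.patient else {})}
            for s in dataset.samples
        ],
        "tss": "tss.tsv", "fpkm": "fpkm.tsv", "beta": "beta.tsv",
        "snps": "snps.tsv", "background_snps": "background_snps.tsv",
        "cnv": "cnv.tsv", "gene_sets": "gene_sets.tsv",
        "summits": {tf: f"summits_{tf}.bed" for tf in sorted(dataset.summits)},
    }
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)

    pd.DataFrame({
        "cluster_id": [c.cluster_id for c in truth.clusters],
        "chrom": [c.span.chrom for c in truth.clusters],
        "start": [c.span.start for c in truth.clusters],
        "end": [c.span.end for c in truth.clusters],
        "n_constituents": [len(c.constituents) for c in truth.clusters],
        "is_super": [c.is_super for c in truth.clusters],
        "somatic_class": [c.somatic_class for c in truth.clusters],
        "peak_fold": [c.peak_fold for c in truth.clusters],
        "active_lines": [",".join(c.active_lines) for c in truth.clusters],
        "linked_gene": [c.linked_gene for c in truth.clusters],
        "expression_fold": [c.expression_fold for c in truth.clusters],
        "delta_beta": [c.delta_beta for c in truth.clusters],
    }).to_csv(out / "truth" / "clusters.tsv", sep="\t", index=False)
    write_bed(out / "truth" / "constituents.bed", truth.constituent_regions)
    pd.DataFrame({"gene_id": sorted(truth.expressed_genes)}).to_csv(
        out / "truth" / "expressed_genes.tsv", sep="\t", index=False)
    return out


# ---------------------------------------------------------------------------
# recovery report
# ---------------------------------------------------------------------------

def _reciprocal_match(truth_regions: list[Region], call_regions: list[Region],
                      min_frac: float = 0.5) -> dict[int, int]:
    """truth index -> call index with >= min_frac reciprocal overlap."""
    matches: dict[int, int] = {}
    for ti, t in enumerate(truth_regions):
        best, best_ov = None, 0
        for ci, c in enumerate(call_regions):
            ov = t.overlap(c)
            if ov > best_ov and ov >= min_frac * len(t) and ov >= min_frac * len(c):
                best, best_ov = ci, ov
        if best is not None:
            matches[ti] = best
    return matches


def _jaccard(a: Region, b: Region) -> float:
    ov = a.overlap(b)
    union = len(a) + len(b) - ov
    return ov / union if union else 0.0


def truth_report(truth: GroundTruth, calls: dict) -> dict:
    """Confusion matrices and recovery metrics for pipeline calls.

    ``calls`` keys (all optional): ``enhancers`` (regions),
    ``super_enhancers`` (regions), ``somatic_classes`` (region -> class,
    aligned list of (Region, str)), ``gene_links`` (region -> gene_id,
    aligned list of (Region, str)).  Matching is >= 50% reciprocal overlap.
    """
    report: dict = {}

    def _pr(truth_regions, call_regions):
        matches = _reciprocal_match(truth_regions, call_regions)
        recall = len(matches) / len(truth_regions) if truth_regions else float("nan")
        matched_calls = len(set(matches.values()))
        precision = matched_calls / len(call_regions) if call_regions else float("nan")
        return matches, precision, recall

    if "enhancers" in calls:
        _, p, r = _pr(truth.constituent_regions, calls["enhancers"])
        report["enhancers"] = {"precision": p, "recall": r}

    se_matches: dict[int, int] = {}
    if "super_enhancers" in calls:
        se_truth = truth.super_spans
        se_matches, p, r = _pr(se_truth, calls["super_enhancers"])
        jac = [_jaccard(se_truth[ti], calls["super_enhancers"][ci])
               for ti, ci in se_matches.items()]
        report["super_enhancers"] = {
            "precision": p, "recall": r,
            "mean_jaccard": float(np.mean(jac)) if jac else float("nan"),
        }

    if "somatic_classes" in calls:
        regions = [r for r, _ in calls["somatic_classes"]]
        classes = [k for _, k in calls["somatic_classes"]]
        supers = [c for c in truth.clusters if c.is_super]
        matches = _reciprocal_match([c.span for c in supers], regions)
        confusion: dict[tuple[str, str], int] = {}
        correct = 0
        for ti, ci in matches.items():
            key = (supers[ti].somatic_class, classes[ci])
            confusion[key] = confusion.get(key, 0) + 1
            correct += key[0] == key[1]
        report["somatic"] = {
            "confusion": confusion,
            "accuracy": correct / len(matches) if matches else float("nan"),
            "n_matched": len(matches),
        }

    if "gene_links" in calls:
        regions = [r for r, _ in calls["gene_links"]]
        genes = [g for _, g in calls["gene_links"]]
        supers = [c for c in truth.clusters if c.is_super]
        matches = _reciprocal_match([c.span for c in supers], regions)
        correct = sum(genes[ci] == supers[ti].linked_gene for ti, ci in matches.items())
        report["gene_links"] = {
            "recovery": correct / len(matches) if matches else float("nan"),
            "n_matched": len(matches),
        }
    return report
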