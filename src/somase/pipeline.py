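"""End-to-end orchestration: candidate calling through somatic
classification and gene assignment on a loaded or generated dataset."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io_formats import Dataset, Region
from . import signal_processing as sp
from . import enhancer_calling as ec
from . import super_enhancers as se
from . import somatic_classification as sc
from . import gene_assignment as ga

log = logging.getLogger("somase")


@dataclass
class PipelineParams:
    """Thresholds default to the printed analysis values; caller internals
    (smoothing, width floor) belong to the built-in threshold caller only."""

    background_n: int = 100_000
    background_width: int = 500
    # The built-in run-length caller thresholds against a robust estimate of
    # the background noise level (p90 of the sampled background, scaled)
    # rather than the p99 presence threshold: random background regions are
    # not excluded from enhancer territory, so with realistic enhancer
    # footprints (>1% of the genome) the p99 sits inside enhancer-level
    # signal and is unusable for bin-level calling.  p99 remains the
    # presence/promoter-activity criterion.
    caller_noise_quantile: float = 0.90
    caller_threshold_factor: float = 3.0
    smooth_bins: int = 6
    min_candidate_width: int = 400
    min_distal_bp: int = ec.DISTAL_MIN_BP
    k4_ratio_max: float = ec.K4_RATIO_MAX
    k4_pseudocount: float = ec.K4_PSEUDOCOUNT
    stitch_gap: int = se.STITCH_GAP_BP
    n_perm: int = 10_000
    min_recurrent_pairs: int = 2
    promoter_rule: str = "any"
    seed: int = 0


@dataclass
class PipelineResult:
    enhancers_by_line: dict[str, list[Region]] = field(default_factory=dict)
    se_by_line: dict[str, list[Region]] = field(default_factory=dict)
    enhancer_catalog: list = field(default_factory=list)   # EnhancerCall
    se_catalog: list = field(default_factory=list)         # EnhancerCall
    typical_catalog: list[Region] = field(default_factory=list)
    recurrence: list = field(default_factory=list)
    somatic_calls: list = field(default_factory=list)
    gene_links: list = field(default_factory=list)
    active_tss: list = field(default_factory=list)

    def calls_for_truth_report(self) -> dict:
        links_by_se = {l.se_id: l.gene_id for l in self.gene_links}
        se_regions = [c.region for c in self.se_catalog]
        return {
            "enhancers": [c.region for c in self.enhancer_catalog],
            "super_enhancers": se_regions,
            "somatic_classes": [
                (next(c.region for c in self.se_catalog if c.region.id == s.se_id), s.klass)
                for s in self.somatic_calls
            ],
            "gene_links": [
                (r, links_by_se[r.id]) for r in se_regions if r.id in links_by_se
            ],
        }


def smooth_bins(vec: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average used by the built-in threshold caller."""
    if window <= 1:
        return vec
    kernel = np.ones(window) / window
    return np.convolve(vec, kernel, mode="same")


def run_pipeline(dataset: Dataset, params: PipelineParams | None = None) -> PipelineResult:
    params = params or PipelineParams()
    genome = dataset.genome
    result = PipelineResult()

    k4me3_tracks = [dataset.tracks[k] for k in dataset.tracks if k[1] == "H3K4me3"]
    k4me1_tracks = [dataset.tracks[k] for k in dataset.tracks if k[1] == "H3K4me1"]
    k4me3_agg = sp.aggregate_tracks(k4me3_tracks, "H3K4me3")
    k4me1_agg = sp.aggregate_tracks(k4me1_tracks, "H3K4me1")

    # ---- per-line enhancer calling and SE stitching ------------------------
    for line in dataset.cell_lines:
        chip = dataset.track(line, "H3K27ac")
        inp = dataset.tracks.get((line, "input"))
        background = sp.build_background(chip, params.background_width,
                                         n=params.background_n, seed=params.seed,
                                         input_track=inp)
        threshold = params.caller_threshold_factor * sp.empirical_quantile(
            background.values, params.caller_noise_quantile)
        corrected = {c: smooth_bins(sp.corrected_bin_rpkm(chip, inp, c), params.smooth_bins)
                     for c in genome.chrom_names}
        candidates = ec.call_candidate_regions(corrected, genome, threshold,
                                               min_width=params.min_candidate_width)
        calls = ec.filter_to_predicted_enhancers(
            candidates, dataset.tss, k4me3_agg, k4me1_agg,
            pseudocount=params.k4_pseudocount, min_distal_bp=params.min_distal_bp,
            max_ratio=params.k4_ratio_max)
        enhancers = [c.region for c in calls]
        result.enhancers_by_line[line] = enhancers
        stitched = se.stitch(enhancers, gap=params.stitch_gap) if enhancers else []
        if len(stitched) >= 3:
            se.call_super_enhancers(stitched, chip, inp)
            result.se_by_line[line] = [s.region for s in stitched if s.is_super]
        else:
            result.se_by_line[line] = []
        log.info("line %s: %d enhancers, %d super-enhancers", line,
                 len(enhancers), len(result.se_by_line[line]))

    # ---- merged catalogs ---------------------------------------------------
    result.enhancer_catalog = ec.merge_catalog(result.enhancers_by_line, id_prefix="ENH")
    result.se_catalog = se.merge_se_across_lines(result.se_by_line)
    result.typical_catalog = se.typical_enhancers(
        [c.region for c in result.enhancer_catalog],
        [c.region for c in result.se_catalog])

    # ---- rank-product recurrence over the merged enhancer catalog ----------
    if result.enhancer_catalog and len(dataset.cell_lines) >= 2:
        matrix = np.empty((len(result.enhancer_catalog), len(dataset.cell_lines)))
        for j, line in enumerate(dataset.cell_lines):
            chip = dataset.track(line, "H3K27ac")
            inp = dataset.tracks.get((line, "input"))
            for i, call in enumerate(result.enhancer_catalog):
                matrix[i, j] = sp.corrected_rpkm(chip, inp, call.region)
        present = np.array([[line in c.present_in for line in dataset.cell_lines]
                            for c in result.enhancer_catalog])
        result.recurrence = ec.rank_product_recurrence(
            matrix, n_perm=params.n_perm, seed=params.seed,
            region_ids=[c.region.id for c in result.enhancer_catalog],
            present_matrix=present)

    # ---- somatic classification against matched normals --------------------
    if dataset.pairs:
        for call in result.se_catalog:
            t_vals, n_vals = [], []
            for tumor_id, normal_id in dataset.pairs:
                t_vals.append(sp.corrected_rpkm(
                    dataset.track(tumor_id, "H3K27ac"),
                    dataset.tracks.get((tumor_id, "input")), call.region))
                n_vals.append(sp.corrected_rpkm(
                    dataset.track(normal_id, "H3K27ac"),
                    dataset.tracks.get((normal_id, "input")), call.region))
            result.somatic_calls.append(sc.classify_somatic(
                call.region.id, t_vals, n_vals,
                min_recurrent_pairs=params.min_recurrent_pairs))

    # ---- gene assignment ---------------------------------------------------
    if dataset.tss:
        chip_all = [dataset.tracks[k] for k in dataset.tracks if k[1] == "H3K27ac"]
        inp_by_sample = {k[0]: dataset.tracks.get((k[0], "input")) for k in dataset.tracks}
        k27_agg = sp.aggregate_tracks(chip_all, "H3K27ac")
        inputs = [t for t in (inp_by_sample.get(t.sample_id) for t in chip_all)
                  if t is not None]
        inp_agg = sp.aggregate_tracks(inputs, "input") if inputs else None
        promoter_bg = sp.build_background(k27_agg, 1_000, n=max(params.background_n, 10_000),
                                          seed=params.seed, input_track=inp_agg)
        result.active_tss = ga.active_promoters(
            dataset.tss, [(k27_agg, inp_agg)], promoter_bg, rule=params.promoter_rule)
        for call in result.se_catalog:
            link = ga.assign_nearest_active(call.region, result.active_tss, dataset.tss)
            if link is not None:
                result.gene_links.append(link)

    return result
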