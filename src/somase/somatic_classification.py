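"""Tumor/matched-normal classification of cell-line-derived super-enhancers
into somatic gain / somatic loss / unaltered / inactive, with methylation,
expression and copy-number evidence overlays.

A pair supports gain when tumor/normal fold >= 2 (pseudocount 0.1 on both
terms) AND the absolute difference exceeds 0.5 RPKM; loss is the mirror
condition.  A super-enhancer is inactive when its maximum input-corrected
RPKM over all primary samples (tumors and normals) is below 0.5.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import Region

log = logging.getLogger("somase")

FOLD_THRESHOLD = 2.0
DIFF_THRESHOLD = 0.5
INACTIVE_MAX_RPKM = 0.5
FOLD_PSEUDOCOUNT = 0.1
CNV_GAIN_LOG_RATIO = 0.6
CNV_LOSS_LOG_RATIO = -1.0


@dataclass
class SomaticCall:
    se_id: str
    tumor_rpkm: np.ndarray
    normal_rpkm: np.ndarray
    fold: np.ndarray
    diff: np.ndarray
    n_gain_pairs: int
    n_loss_pairs: int
    max_primary_rpkm: float
    klass: str  # gain | loss | unaltered | inactive


def classify_somatic(se_id: str, tumor_rpkm, normal_rpkm,
                     min_recurrent_pairs: int = 2,
                     fold_threshold: float = FOLD_THRESHOLD,
                     diff_threshold: float = DIFF_THRESHOLD,
                     inactive_max: float = INACTIVE_MAX_RPKM,
                     pseudocount: float = FOLD_PSEUDOCOUNT) -> SomaticCall:
    """Classify one super-enhancer from per-pair corrected RPKM values.

    Evaluation order: (1) inactive if max RPKM over all primaries < 0.5;
    (2) gain if >= ``min_recurrent_pairs`` gain pairs and gain pairs >= loss
    pairs; (3) loss if >= ``min_recurrent_pairs`` loss pairs; (4) unaltered.
    """
    t = np.asarray(tumor_rpkm, dtype=float)
    n = np.asarray(normal_rpkm, dtype=float)
    if t.shape != n.shape:
        raise ValueError("tumor and normal vectors must align (missing pair member?)")
    if len(t) < 2:
        raise ValueError("need at least 2 tumor/normal pairs")
    fold = (t + pseudocount) / (n + pseudocount)
    diff = t - n
    gain_pairs = (fold >= fold_threshold) & (diff > diff_threshold)
    loss_pairs = (fold <= 1.0 / fold_threshold) & (diff < -diff_threshold)
    n_gain = int(gain_pairs.sum())
    n_loss = int(loss_pairs.sum())
    max_primary = float(max(t.max(), n.max()))

    if max_primary < inactive_max:
        klass = "inactive"
    elif n_gain >= min_recurrent_pairs and n_gain >= n_loss:
        klass = "gain"
        if n_loss >= min_recurrent_pairs:
            log.info("SE %s has both recurrent gain (%d) and loss (%d); labeled gain",
                     se_id, n_gain, n_loss)
    elif n_loss >= min_recurrent_pairs:
        klass = "loss"
    else:
        klass = "unaltered"

    return SomaticCall(se_id=se_id, tumor_rpkm=t, normal_rpkm=n, fold=fold, diff=diff,
                       n_gain_pairs=n_gain, n_loss_pairs=n_loss,
                       max_primary_rpkm=max_primary, klass=klass)


def somatic_call_table(calls: list[SomaticCall]) -> pd.DataFrame:
    return pd.DataFrame({
        "se_id": [c.se_id for c in calls],
        "class": [c.klass for c in calls],
        "n_gain_pairs": [c.n_gain_pairs for c in calls],
        "n_loss_pairs": [c.n_loss_pairs for c in calls],
        "max_primary_rpkm": [c.max_primary_rpkm for c in calls],
    })


# ---------------------------------------------------------------------------
# Methylation
# ---------------------------------------------------------------------------

def methylation_delta(se: Region, probes: pd.DataFrame,
                      pairs: list[tuple[str, str]]) -> np.ndarray:
    """Per-pair delta-beta (tumor - normal), averaged over probes in the SE.

    ``probes`` columns: chrom, pos, then one beta column per sample.
    Returns an array of NaN when no probe falls inside the SE span.
    """
    inside = probes[(probes["chrom"] == se.chrom)
                    & (probes["pos"] >= se.start) & (probes["pos"] < se.end)]
    if inside.empty:
        return np.full(len(pairs), np.nan)
    out = np.empty(len(pairs))
    for i, (t, n) in enumerate(pairs):
        out[i] = float(inside[t].mean() - inside[n].mean())
    return out


def methylation_class_test(gain_deltas, loss_deltas) -> float:
    """One-sided Welch test that gain-class delta-beta < loss-class."""
    g = np.asarray(gain_deltas, dtype=float)
    l = np.asarray(loss_deltas, dtype=float)
    g, l = g[~np.isnan(g)], l[~np.isnan(l)]
    if len(g) < 2 or len(l) < 2:
        return float("nan")
    return float(stats.ttest_ind(g, l, equal_var=False, alternative="less").pvalue)


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

@dataclass
class ExpressionAssociation:
    se_id: str
    gene_id: str
    lfc: np.ndarray            # per-pair log2 fold change
    differential: np.ndarray   # per-pair two-fold + 0.5 FPKM flag
    mean_lfc: float = field(init=False)

    def __post_init__(self):
        self.mean_lfc = float(np.nanmean(self.lfc)) if len(self.lfc) else float("nan")


def expression_association(se_id: str, gene_id: str, fpkm: pd.DataFrame,
                           pairs: list[tuple[str, str]],
                           pseudocount: float = FOLD_PSEUDOCOUNT,
                           ) -> ExpressionAssociation | None:
    """Per-pair expression fold change for a linked gene.

    lfc = log2((T + 0.1)/(N + 0.1)); a pair is differential iff the
    (pseudocounted) fold is two-fold in either direction and the absolute
    FPKM difference is at least 0.5.
    """
    if gene_id not in set(fpkm["gene_id"]):
        log.info("SE %s: linked gene %s has no expression data; skipped", se_id, gene_id)
        return None
    row = fpkm.set_index("gene_id").loc[gene_id]
    lfc = np.empty(len(pairs))
    differential = np.zeros(len(pairs), dtype=bool)
    for i, (t, n) in enumerate(pairs):
        tv, nv = float(row[t]), float(row[n])
        fold = (tv + pseudocount) / (nv + pseudocount)
        lfc[i] = np.log2(fold)
        differential[i] = (fold >= 2.0 or fold <= 0.5) and abs(tv - nv) >= 0.5
    return ExpressionAssociation(se_id=se_id, gene_id=gene_id, lfc=lfc,
                                 differential=differential)


def expression_class_test(gain_lfc, other_lfc) -> float:
    """One-sided Welch test that gain-class lfc > comparison-class lfc."""
    g = np.asarray(gain_lfc, dtype=float)
    o = np.asarray(other_lfc, dtype=float)
    g, o = g[~np.isnan(g)], o[~np.isnan(o)]
    if len(g) < 2 or len(o) < 2:
        return float("nan")
    return float(stats.ttest_ind(g, o, equal_var=False, alternative="greater").pvalue)


# ---------------------------------------------------------------------------
# Copy number
# ---------------------------------------------------------------------------

def cnv_status(log_ratio: float) -> str:
    if log_ratio > CNV_GAIN_LOG_RATIO:
        return "gain"
    if log_ratio < CNV_LOSS_LOG_RATIO:
        return "loss"
    return "neutral"


def cnv_overlay(se: Region, segments: pd.DataFrame) -> tuple[float, str]:
    """Length-weighted mean log-ratio of CNV segments overlapping the SE.

    ``segments`` columns: chrom, start, end, log_ratio; must be
    non-overlapping.  No overlapping segment -> neutral (logged).
    """
    seg = segments[segments["chrom"] == se.chrom].sort_values("start")
    if (seg["start"].values[1:] < seg["end"].values[:-1]).any():
        raise ValueError("CNV segments overlap")
    ov_start = np.maximum(seg["start"].values, se.start)
    ov_end = np.minimum(seg["end"].values, se.end)
    w = np.maximum(ov_end - ov_start, 0).astype(float)
    if w.sum() == 0:
        log.info("SE %s: no overlapping CNV segment; status neutral", se.id or se)
        return float("nan"), "neutral"
    mean_lr = float(np.average(seg["log_ratio"].values, weights=w))
    return mean_lr, cnv_status(mean_lr)
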