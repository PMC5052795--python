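"""Domain types and readers/writers for the external formats the pipeline touches.

All internal coordinates are 0-based, half-open (BED convention).  Formats
that are 1-based on disk (SNP catalogs) are converted at the boundary and
converted back on write.  Signal lives in dense per-chromosome bin vectors
(fixed ``bin_size``); bedGraph is the on-disk representation, with
zero-count bins omitted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

log = logging.getLogger("somase")

VALID_MARKS = ("H3K27ac", "H3K4me1", "H3K4me3", "input")
VALID_ROLES = ("cell_line", "tumor", "normal")


class FormatError(ValueError):
    """Malformed input file (bad coordinates, off-grid bins, ...)."""


class PairingError(ValueError):
    """Tumor/normal manifest entries that cannot be paired by patient."""


class CoordinateError(ValueError):
    """Region coordinates outside chromosome bounds."""


@dataclass(frozen=True)
class GenomeModel:
    """Chromosome names/lengths plus the fixed signal bin size (default 50 bp)."""

    chrom_names: tuple[str, ...]
    chrom_lengths: tuple[int, ...]
    bin_size: int = 50

    def __post_init__(self):
        if len(self.chrom_names) != len(self.chrom_lengths):
            raise ValueError("chrom_names and chrom_lengths length mismatch")
        if any(l <= 0 for l in self.chrom_lengths):
            raise ValueError("chromosome lengths must be positive")
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")

    @property
    def lengths(self) -> dict[str, int]:
        return dict(zip(self.chrom_names, self.chrom_lengths))

    def n_bins(self, chrom: str) -> int:
        return -(-self.lengths[chrom] // self.bin_size)

    @property
    def total_length(self) -> int:
        return int(sum(self.chrom_lengths))

    def validate_region(self, region: "Region") -> None:
        if region.chrom not in self.lengths:
            raise CoordinateError(f"unknown chromosome {region.chrom!r}")
        if not (0 <= region.start < region.end <= self.lengths[region.chrom]):
            raise CoordinateError(
                f"region {region} outside bounds of {region.chrom} "
                f"(length {self.lengths[region.chrom]})"
            )


@dataclass(frozen=True, order=True)
class Region:
    """Genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    id: str | None = field(default=None, compare=False)

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    def overlap(self, other: "Region") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class TssAnnotation:
    """One gene TSS.  Strand is carried but ignored in distance computations."""

    gene_id: str
    chrom: str
    tss_pos: int
    strand: str = "+"


# ---------------------------------------------------------------------------
# bedGraph
# ---------------------------------------------------------------------------

def read_bedgraph(path: str | Path, genome: GenomeModel) -> dict[str, np.ndarray]:
    """Read a fixed-bin bedGraph into dense per-chromosome vectors.

    Bins absent from the file are zero.  Every interval must start on the
    ``genome.bin_size`` grid and span whole bins, otherwise a
    :class:`FormatError` is raised.
    """
    bs = genome.bin_size
    bins = {c: np.zeros(genome.n_bins(c), dtype=np.float64) for c in genome.chrom_names}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "#")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FormatError(f"{path}:{ln}: expected 4 columns")
            chrom, start, end, value = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
            if chrom not in bins:
                raise FormatError(f"{path}:{ln}: unknown chromosome {chrom!r}")
            if start % bs != 0 or (end % bs != 0 and end != genome.lengths[chrom]):
                raise FormatError(
                    f"{path}:{ln}: interval [{start},{end}) not aligned to {bs} bp bins"
                )
            if not (0 <= start < end <= genome.lengths[chrom]):
                raise CoordinateError(f"{path}:{ln}: interval out of bounds")
            bins[chrom][start // bs : -(-end // bs)] = value
    return bins


def write_bedgraph(path: str | Path, bins: Mapping[str, np.ndarray], genome: GenomeModel) -> None:
    """Write dense bin vectors as bedGraph, omitting zero bins.

    Integer-valued signals are printed without a decimal point so that a
    read→write→read cycle is the identity.
    """
    bs = genome.bin_size
    with open(path, "w") as fh:
        for chrom in genome.chrom_names:
            vec = np.asarray(bins[chrom])
            clen = genome.lengths[chrom]
            (nz,) = np.nonzero(vec)
            if len(nz) == 0:
                continue
            starts = nz.astype(np.int64) * bs
            ends = np.minimum(starts + bs, clen)
            vals = vec[nz]
            if np.all(vals == np.floor(vals)):
                vcol = vals.astype(np.int64)
            else:
                vcol = vals.astype(float)
            df = pd.DataFrame({"c": chrom, "s": starts, "e": ends, "v": vcol})
            df.to_csv(fh, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path: str | Path, genome: GenomeModel | None = None) -> list[Region]:
    regions: list[Region] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "#")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{ln}: expected >=3 BED columns")
            name = parts[3] if len(parts) > 3 else None
            region = Region(parts[0], int(parts[1]), int(parts[2]), name)
            if genome is not None:
                genome.validate_region(region)
            regions.append(region)
    return regions


def write_bed(path: str | Path, regions: Iterable[Region]) -> None:
    with open(path, "w") as fh:
        for r in regions:
            if r.id is not None:
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.id}\n")
            else:
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\n")


# ---------------------------------------------------------------------------
# Tab-separated tables
# ---------------------------------------------------------------------------

def read_tss_table(path: str | Path, genome: GenomeModel | None = None) -> list[TssAnnotation]:
    """TSS annotation table: gene_id, chrom, pos, strand (0-based position)."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "chrom", "pos", "strand"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: TSS table needs columns {sorted(required)}")
    if df["gene_id"].duplicated().any():
        raise FormatError(f"{path}: duplicate gene_id entries")
    out = []
    for row in df.itertuples(index=False):
        if genome is not None and not (0 <= row.pos < genome.lengths[row.chrom]):
            raise CoordinateError(f"TSS {row.gene_id} at {row.chrom}:{row.pos} out of bounds")
        out.append(TssAnnotation(str(row.gene_id), str(row.chrom), int(row.pos), str(row.strand)))
    return out


def write_tss_table(path: str | Path, tss: Sequence[TssAnnotation]) -> None:
    pd.DataFrame(
        {
            "gene_id": [t.gene_id for t in tss],
            "chrom": [t.chrom for t in tss],
            "pos": [t.tss_pos for t in tss],
            "strand": [t.strand for t in tss],
        }
    ).to_csv(path, sep="\t", index=False)


def read_snp_table(path: str | Path) -> pd.DataFrame:
    """SNP catalog: chrom, pos (1-based on disk), id, trait -> 0-based in memory."""
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "pos", "id", "trait"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: SNP table needs columns {sorted(required)}")
    df = df.copy()
    df["pos"] = df["pos"].astype(int) - 1
    return df


def write_snp_table(path: str | Path, df: pd.DataFrame) -> None:
    out = df.copy()
    out["pos"] = out["pos"].astype(int) + 1
    out.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Dataset
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SampleInfo:
    sample_id: str
    role: str  # cell_line | tumor | normal
    mark: str  # H3K27ac | H3K4me1 | H3K4me3 | input
    path: str
    library_size: int
    patient: str | None = None


@dataclass
class Dataset:
    """Validated in-memory dataset: tracks, annotations, and side tables."""

    genome: GenomeModel
    tracks: dict  # (sample_id, mark) -> SignalTrack
    samples: list[SampleInfo]
    tss: list[TssAnnotation]
    pairs: list[tuple[str, str]] = field(default_factory=list)  # (tumor, normal) sample ids
    cell_lines: list[str] = field(default_factory=list)
    fpkm: pd.DataFrame | None = None
    beta: pd.DataFrame | None = None
    snps: pd.DataFrame | None = None
    background_snps: pd.DataFrame | None = None
    cnv: pd.DataFrame | None = None
    summits: dict[str, list[Region]] = field(default_factory=dict)
    gene_sets: dict[str, set[str]] = field(default_factory=dict)
    regions: dict[str, list[Region]] = field(default_factory=dict)

    def track(self, sample_id: str, mark: str):
        return self.tracks[(sample_id, mark)]

    def marks_of(self, sample_id: str) -> list[str]:
        return [m for (s, m) in self.tracks if s == sample_id]


def _build_pairs(samples: Sequence[SampleInfo]) -> list[tuple[str, str]]:
    tumors: dict[str, str] = {}
    normals: dict[str, str] = {}
    for s in samples:
        if s.mark != "H3K27ac":
            continue
        if s.role == "tumor":
            tumors[s.patient] = s.sample_id
        elif s.role == "normal":
            normals[s.patient] = s.sample_id
    unpaired = set(tumors) ^ set(normals)
    if unpaired:
        raise PairingError(f"patients missing a pair member: {sorted(unpaired)}")
    return [(tumors[p], normals[p]) for p in sorted(tumors)]


def load_dataset(config_path: str | Path) -> Dataset:
    """Load the full file set declared in a dataset manifest (YAML).

    Validates bin alignment, coordinates, manifest roles/marks, and
    tumor/normal pairing; logs a dataset summary.
    """
    from .signal_processing import SignalTrack  # deferred to avoid import cycle

    config_path = Path(config_path)
    base = config_path.parent
    with open(config_path) as fh:
        cfg = yaml.safe_load(fh)

    g = cfg["genome"]
    genome = GenomeModel(
        tuple(g["chrom_names"]), tuple(int(x) for x in g["chrom_lengths"]),
        int(g.get("bin_size", 50)),
    )

    samples: list[SampleInfo] = []
    tracks: dict[tuple[str, str], SignalTrack] = {}
    for entry in cfg["samples"]:
        info = SampleInfo(
            sample_id=str(entry["id"]),
            role=str(entry["role"]),
            mark=str(entry["mark"]),
            path=str(entry["path"]),
            library_size=int(entry["library_size"]),
            patient=str(entry["patient"]) if entry.get("patient") is not None else None,
        )
        if info.role not in VALID_ROLES:
            raise FormatError(f"sample {info.sample_id}: unknown role {info.role!r}")
        if info.mark not in VALID_MARKS:
            raise FormatError(f"sample {info.sample_id}: unknown mark {info.mark!r}")
        bins = read_bedgraph(base / info.path, genome)
        tracks[(info.sample_id, info.mark)] = SignalTrack(
            sample_id=info.sample_id, mark=info.mark,
            library_size=info.library_size, bins=bins, genome=genome,
        )
        samples.append(info)

    pairs = _build_pairs(samples)
    cell_lines = sorted({s.sample_id for s in samples if s.role == "cell_line"})

    tss = read_tss_table(base / cfg["tss"], genome) if "tss" in cfg else []

    def _opt_table(key, reader):
        return reader(base / cfg[key]) if key in cfg else None

    ds = Dataset(
        genome=genome, tracks=tracks, samples=samples, tss=tss,
        pairs=pairs, cell_lines=cell_lines,
        fpkm=_opt_table("fpkm", read_table),
        beta=_opt_table("beta", read_table),
        snps=_opt_table("snps", read_snp_table),
        background_snps=_opt_table("background_snps", read_snp_table),
        cnv=_opt_table("cnv", read_table),
    )
    for tf, path in cfg.get("summits", {}).items():
        ds.summits[tf] = read_bed(base / path, genome)
    if "gene_sets" in cfg:
        gs = read_table(base / cfg["gene_sets"])
        for name, sub in gs.groupby("set_name"):
            ds.gene_sets[str(name)] = set(sub["gene_id"].astype(str))
    for name, path in cfg.get("regions", {}).items():
        ds.regions[name] = read_bed(base / path, genome)

    log.info(
        "loaded dataset: %d tracks, %d samples, %d TSS, %d tumor/normal pairs, %d lines",
        len(tracks), len({s.sample_id for s in samples}), len(tss), len(pairs), len(cell_lines),
    )
    return ds


SOMATIC_CALL_COLUMNS = ["se_id", "class", "n_gain_pairs", "n_loss_pairs", "max_primary_rpkm"]


def write_results(out_dir: str | Path, regions: Mapping[str, Sequence[Region]] = (),
                  tables: Mapping[str, pd.DataFrame] = ()) -> dict[str, Path]:
    """Write region sets as BED and per-stage tables as TSV under ``out_dir``.

    Somatic-call tables are coerced to the fixed documented column order.
    Returns the mapping of logical names to written paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for name, regs in dict(regions).items():
        path = out_dir / f"{name}.bed"
        write_bed(path, regs)
        written[name] = path
    for name, df in dict(tables).items():
        path = out_dir / f"{name}.tsv"
        if set(SOMATIC_CALL_COLUMNS).issubset(df.columns):
            rest = [c for c in df.columns if c not in SOMATIC_CALL_COLUMNS]
            df = df[SOMATIC_CALL_COLUMNS + rest]
        df.to_csv(path, sep="\t", index=False)
        written[name] = path
    return written
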