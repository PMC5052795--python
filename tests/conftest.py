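import numpy as np
import pytest

from somase.io_formats import GenomeModel, Region
from somase.signal_processing import SignalTrack
from somase.synthetic_data import SimulationDesign, generate_dataset
from somase.pipeline import PipelineParams, run_pipeline


@pytest.fixture(scope="session")
def genome():
    return GenomeModel(("chr1", "chr2"), (1_000_000, 500_000), 50)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_track(genome, rng, mean=2.0, sample_id="S1", mark="H3K27ac", library_size=10_000_000):
    bins = {c: rng.poisson(mean, size=genome.n_bins(c)).astype(float)
            for c in genome.chrom_names}
    return SignalTrack(sample_id=sample_id, mark=mark, library_size=library_size,
                       bins=bins, genome=genome)


@pytest.fixture()
def track(genome, rng):
    return make_track(genome, rng)


@pytest.fixture(scope="session")
def small_dataset():
    """Small synthetic cohort shared by generator-backed unit tests."""
    design = SimulationDesign(
        n_cell_lines=3, n_pairs=4, chrom_lengths=(3_000_000, 3_000_000),
        n_genes=90, n_enhancer_clusters=36, seed=7,
    )
    return generate_dataset(design)


@pytest.fixture(scope="session")
def default_run():
    """Full default-design end-to-end run shared by the acceptance tests."""
    design = SimulationDesign(seed=0)
    dataset, truth = generate_dataset(design)
    result = run_pipeline(dataset, PipelineParams(seed=0))
    return design, dataset, truth, result


def random_regions(rng, n, chrom="chr1", span=100_000, max_len=2_000):
    regions = []
    for _ in range(n):
        start = int(rng.integers(0, span - max_len))
        length = int(rng.integers(1, max_len))
        regions.append(Region(chrom, start, start + length))
    return regions
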