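# somase

Super-enhancer landscapes from binned histone-mark signal tracks: predicted
enhancer calling, ROSE-style stitching with the hockey-stick cutoff,
rank-product recurrence, tumor/matched-normal somatic classification
(gain / loss / unaltered / inactive), nearest-active-TSS gene assignment,
and downstream enrichment statistics (GWAS SNPs, gene sets, TF occupancy,
knockdown H3K27ac depletion, conservation) — together with a seeded
synthetic-cohort generator that plants ground truth for every stage.

## What it does

Starting from fixed 50-bp binned signal tracks (bedGraph) for H3K27ac,
H3K4me1, H3K4me3 and input libraries across cell lines and tumor/normal
pairs, the pipeline:

1. **Quantifies** interval signal as RPKM (`reads × 10⁹ / (library × bp)`),
   corrects ChIP against matched input (subtraction, floored at 0), and
   derives empirical background thresholds from 100,000 random regions
   (presence = corrected RPKM above the 99th percentile).
2. **Calls predicted enhancers**: threshold-run candidate regions, kept when
   ≥ 2.5 kb from every TSS and with aggregate H3K4me3/H3K4me1 log2 ratio
   ≤ 2.4 (pseudocount 0.1).
3. **Stitches** enhancers within 12.5 kb and separates super-enhancers from
   typical enhancers at the slope-1 tangent of the unit-scaled rank–signal
   curve; per-line catalogs are merged at one-base overlap.
4. **Scores recurrence** by per-line rank products against a 10,000-fold
   permutation null.
5. **Classifies** each super-enhancer against matched normals: a pair
   supports gain at fold ≥ 2 (pseudocount 0.1) and difference > 0.5 RPKM
   (loss mirrored); ≥ 2 recurrent pairs call the class; max corrected RPKM
   < 0.5 across all primaries marks the region inactive.
6. **Assigns genes** by the nearest active TSS (500-bp-flanked promoter above
   background), and computes the expression / methylation / copy-number /
   SNP / gene-set / TF-occupancy / knockdown-depletion statistics.

## CLI

```bash
# generate a synthetic cohort (2 × 10 Mb genome, 6 lines, 8 pairs by default)
soma-se simulate --seed 1 --out data/

# full pipeline: catalogs, somatic calls, recurrence, gene links
soma-se run --config data/manifest.yaml --seed 1 --out results/

# individual stages
soma-se qc         --config data/manifest.yaml --out qc.tsv
soma-se quantify   --config data/manifest.yaml --regions results/se_catalog.bed --out rpkm.tsv
soma-se call-enhancers --config data/manifest.yaml --seed 1 --out out/
soma-se stitch     --config data/manifest.yaml --seed 1 --out out/
soma-se classify   --config data/manifest.yaml --seed 1 --out out/
soma-se assign     --config data/manifest.yaml --seed 1 --out out/
soma-se snp-enrich --config data/manifest.yaml --seed 1 --out out/
soma-se tf         --config data/manifest.yaml --seed 1 --out out/
```

`simulate --config design.yaml` accepts YAML overrides for any
`SimulationDesign` field. Knockdown-depletion and conservation scoring are
available through the Python API (`somase.integration_stats`), which is also
the route for custom analyses:

```python
from somase import SimulationDesign, generate_dataset, run_pipeline, PipelineParams
from somase.synthetic_data import truth_report

dataset, truth = generate_dataset(SimulationDesign(seed=1))
result = run_pipeline(dataset, PipelineParams(seed=1))
print(truth_report(truth, result.calls_for_truth_report()))
```

## Layout

```
src/somase/
  io_formats.py            formats (bedGraph/BED/TSV), genome model, dataset manifest
  synthetic_data.py        seeded generator + ground truth + recovery report
  signal_processing.py     RPKM, input correction, empirical background, QC
  enhancer_calling.py      candidate calling, distal/ratio filters, merging, rank product
  super_enhancers.py       stitching, hockey-stick cutoff, cross-line SE catalog
  somatic_classification.py  gain/loss/unaltered/inactive + methylation/expression/CNV
  gene_assignment.py       active promoters, nearest-active-TSS links, Fisher enrichment
  integration_stats.py     SNP/gene-set/TF/profile/knockdown/conservation statistics
  pipeline.py              end-to-end orchestration
  cli.py                   soma-se entry point
```

Coordinates are 0-based half-open throughout; 1-based sources (SNP catalogs)
are converted at the I/O boundary. All stochastic stages take explicit seeds
and are reproducible bit-for-bit.
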