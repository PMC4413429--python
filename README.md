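# deprof

Two-group array-style differential-expression calling feeding TSS-anchored
ChIP coverage composite profiling, plus a synthetic-data generator so every
stage is verifiable against known ground truth without downloads.

The pipeline has four analysis stages:

1. **Expression DE** — variance-stabilizing transform (fitted generalized
   log, with a plain `log2` fallback), robust spline normalization onto the
   quantiles of the per-gene mean pseudo-sample, empirical-Bayes moderated
   t-test (method-of-moments variance prior, BH FDR control), and twofold /
   P<0.05 filtering into down / up / unchanged calls. Hypergeometric
   over-representation of GMT gene sets is available for the resulting
   lists.
2. **Coverage profiling** — per-sample depth normalization to the mean
   total signal, per-base mean densities in 100-bp windows sliding by 20 bp
   across a 6-kb interval centred on each TSS (296 windows), and per-window
   median composite profiles per gene set, with minus-strand profiles
   flipped to gene orientation.
3. **Stratified comparison** — TSS sets stratified by DE call; per-gene
   TSS-proximal (±500 bp) mean densities compared between genotypes with a
   paired Wilcoxon signed-rank test (exact for ≤25 informative pairs), BH
   adjustment across the comparison family.
4. **Synthetic data** — annotations with spaced TSSs, intensity matrices
   with a scaled-inverse-chi-square variance prior and planted twofold DE
   genes, and Poisson coverage tracks with Gaussian TSS peaks whose
   knockout amplitude is attenuated for down-class genes, over matched
   input tracks. A gene-free "bulk" chromosome carries the rest-of-genome
   signal mass so planted peaks are a realistically negligible share of
   each sample's total.

Supported formats: bedGraph and WIG (fixedStep/variableStep with span) for
coverage, BED6 and GFF3 for annotations, TSV for matrices and metadata, GMT
for gene sets. Internal coordinates are 0-based half-open.

## CLI

```sh
# generate a synthetic dataset with known truth
deprof simulate --out data/ --seed 1

# DE chain on an expression TSV + sample metadata
deprof de --expression data/expression.tsv --metadata data/samples.tsv \
          --out de/ --fc-threshold 2 --p-threshold 0.05 --p-mode raw

# gene-set over-representation
deprof enrich --genes de/genes_down.txt --universe universe.txt \
              --gmt sets.gmt --out enrichment.tsv

# composite profiles around TSS anchors
deprof profile --coverage data/H3ac_WT_1.bedgraph --coverage data/H3ac_KO_1.bedgraph \
               --anchors data/annotation.bed --genes de/genes_down.txt --out profiles/

# browser-style slice around one gene
deprof locus --coverage data/H3ac_WT_1.bedgraph --anchors data/annotation.bed \
             --gene g00001 --flank 3000 --out g00001.bedgraph

# full pipeline from a YAML config (synthetic or real inputs)
deprof pipeline --config config.yaml --out report/ --seed 3
```

A minimal self-generating pipeline config:

```yaml
simulate: {}          # default synthetic design; any SimConfig field overrides
de: {fc_threshold: 2, p_threshold: 0.05, p_mode: raw, transform: vst}
profile: {span: 6000, window: 100, slide: 20, proximal_halfwidth: 500}
```

Real-data runs replace `simulate:` with an `inputs:` block pointing at an
expression TSV, sample metadata, a BED6/GFF3 annotation, and coverage files
with assay/genotype labels. The report directory contains the DE table,
gene lists, optional enrichment tables, per-stratum composite TSVs,
comparison statistics, a deterministic `run.log`, and a `manifest.json`
echoing every effective parameter; a fixed config + seed reproduces the
report byte for byte.

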