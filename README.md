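# ctcmut

Comparison of somatic mutation profiles between matched lesion pairs — a
primary tumor callset and a circulating-tumor-cell (CTC) callset per case.
The package provides:

- **`ctcmut.variant_io`** — mutation records and keys, a MAF-like TSV dialect,
  a minimal single-sample VCF 4.x reader/writer (via cyvcf2), pyrimidine-strand
  collapse of substitutions, and a clinical cohort-metadata table parser and
  summarizer (a transcription of the study cohort table ships as a fixture in
  `ctcmut/data/table1_cohort.tsv`).
- **`ctcmut.synthetic_cohort`** — a trunk-branch generative model for matched
  callsets: per-case trunk and lesion-private branch mutation counts,
  signature-mixture trinucleotide contexts, Beta-distributed cell fractions,
  and a Poisson-depth / binomial-reads / alt-read-threshold detection model,
  together with per-mutation ground truth and a closed-form expected
  concordance oracle.
- **`ctcmut.concordance`** — regional classification (common /
  primary-specific / CTC-specific), concordance fractions under union and
  per-lesion denominators, and the cohort abundance correlation (Pearson,
  two-sided t-transform p).
- **`ctcmut.spectra_signatures`** — functional-consequence proportions and
  NS/S ratios, 6- and 96-class mutation spectra, non-negative least-squares
  signature refitting against a catalog TSV (a 5-signature toy catalog is
  packaged), and average-linkage hierarchical clustering of exposure profiles
  with Newick export.
- **`ctcmut.clonality_genes`** — variant allele frequency summaries with
  two-sided Mann–Whitney comparisons of region-specific vs common mutations
  per lesion, and per-category cancer-gene recurrence tables.
- **`ctcmut.cli`** — a `ctcmut` command with `simulate`, `analyze`, and
  `full` subcommands producing a deterministic TSV report bundle plus a
  machine-readable manifest.

## CLI

Simulate a 20-case cohort and analyze it in one run:

```sh
ctcmut full --seed 42 --n-cases 20 --out out/
```

Analyze existing callsets (MAF-like TSV; see `ctcmut.variant_io` for the
column contract):

```sh
ctcmut analyze --maf calls.maf.tsv --catalog signatures.tsv \
    --genes genes.txt --metadata cohort.tsv --out out/
```

Only generate callsets, truth table, and metadata (optionally per-case VCFs):

```sh
ctcmut simulate --seed 7 --n-cases 5 --out sim/ --write-vcfs
```

Simulation parameters can be supplied as a flat YAML file via `--config`;
keys mirror `ctcmut.synthetic_cohort.SimulationConfig` fields. Identical
config and seed produce byte-identical bundles.

The bundle contains per-case abundance, regional-proportion, and concordance
tables (all three denominators), cohort correlation, consequence/NS-S table,
6- and 96-class spectra, exposure matrix with a Newick dendrogram, VAF
summaries, the gene recurrence table, a cohort-metadata summary, and
`manifest.json` with the seed, versions, dropped-record counts, and SHA-256
of every table.

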