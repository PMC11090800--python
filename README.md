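# mtsoma

Somatic mitochondrial mutation analysis for duplex-sequencing call tables.
The package ingests per-site duplex variant calls (VCF or TSV) against a
circular mt-genome reference, and provides:

- **genome model** (`mtsoma.genome`) — circular genome + typed features
  (protein / tRNA / rRNA / D-loop / OriL), vertebrate mitochondrial
  translation, synonymous/non-synonymous site and substitution
  classification, and frameshift premature-stop scanning.
- **variant I/O** (`mtsoma.variants`) — call reading/validation, indel
  normalization, haplotype-site and high-frequency (>1e-3) filters, the
  de novo proxy filter (alt depth < 100, frequency < 0.01), replicate
  aggregation into condition tables, and optional hypergeometric
  depth normalization across conditions.
- **burden** (`mtsoma.burden`) — per-position frequency tracks, exact
  (chi-square quantile) Poisson intervals, region mutation probabilities,
  pooled homopolymer-span frequencies, circular 150-bp sliding-window
  hotspot scans, and log-link (Poisson GLM) age/strain rate tests.
- **spectra** (`mtsoma.spectra`) — strand-collapsed 8-class mutation
  typing (G>A/C>T, ..., INS, DEL), per-class frequencies normalized by
  compatible reference-base depth, collapsed trinucleotide spectra of
  de novo calls, Fisher/BH age-association tests, and export of the
  condition x class count matrix for external signature extraction.
- **selection** (`mtsoma.selection`) — per-gene hN/hS with a multinomial
  simulated null (mutations re-drawn with observed type proportions,
  placed uniformly over class-compatible positions; 10,000 simulations by
  default), doubled one-sided empirical p-values with BH correction,
  frequency-binned scans, non-synonymous/synonymous frequency spectra and
  their null expectation.
- **reversion / NUMT** (`mtsoma.reversion`) — junction-based NUMT
  contamination estimation (max junction fraction, validated against SNV
  cluster medians), reversion-count correction inside the NUMT-homologous
  span, and reversion enrichment / identity / age-delta tests.
- **synthetic data** (`mtsoma.simulate`) — fully seeded generator for
  annotated circular genomes, haplotype tables and per-sample call/depth
  tables with negative-binomial depth, region- and hotspot-scaled rates,
  age fold-changes, frequency-dependent non-synonymous thinning,
  reversion enrichment and NUMT leakage.

## CLI

The pipeline runs from a single YAML config (see `tests/test_cli.py` for
a complete example, including an embedded `simulate:` block):

```sh
mtsoma simulate config.yaml    # generate the configured synthetic dataset
mtsoma burden config.yaml      # frequency summaries + window scans
mtsoma spectra config.yaml     # class frequencies + signature matrix
mtsoma selection config.yaml   # aggregate + binned hN/hS tests
mtsoma reversion config.yaml   # reversion enrichment tests
mtsoma all config.yaml         # everything, with a run manifest
```

Outputs are TSV files under the configured `out_dir`, plus a
`manifest.json` recording input digests and seeds; reruns with the same
config and seed are bit-identical. Logs are line-delimited JSON on
stderr. A single master seed fans out to per-stage seeds by stable
hashing.

For real data, chr1-read counting for NUMT estimation is performed
externally (e.g. `samtools depth in.bam -b regions.bed`, with mapping
quality filters as appropriate); this package consumes the resulting
junction/cluster count summaries.

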