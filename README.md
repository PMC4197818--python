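# capmeth

Analysis toolkit for genome-wide differential 5-methylcytosine (5mC) and
5-hydroxymethylcytosine (5hmC) affinity-capture sequencing. From aligned
short reads it produces:

- **Enrichment islands** per library under a Poisson window background
  (window 200 bp, gap 600 bp, fragment 300 bp, effective genome fraction
  0.854, E-value 1000, FDR 0.01 by default) and **differential regions**
  between two libraries via an exact conditional binomial test with
  Benjamini–Hochberg FDR control.
- **Feature annotation**: promoters (TSS ± 1 kb), 5'UTR / exon / coding
  exon / 3'UTR / intron, the 1-kb TTS flank, CpG islands, 2-kb CGI shores,
  CGI location classes (promoter / gene body / intergenic), HCP/ICP/LCP
  promoter CpG-density classes, and enhancers.
- **Per-gene change tables** stratified by two-fold (2–4×) and four-fold
  (≥4×) magnitude, plus promoter-shore hypermethylation summaries.
- **Composite tag-density profiles** (FPKM-scaled): TSS ±5 kb, 25–75 %
  relative gene body, TTS ±5 kb, and scaled interval profiles for CGIs
  with shores and enhancers with flanks.
- **Gene-set overlap statistics**: exact two-tailed Fisher tests with the
  conservative EASE variant, expression tertile classes, and
  enhancer→nearest-gene (≤ 20 kb) repression linkage.
- A **synthetic-data module** that generates toy genomes, capture
  libraries with planted fold-enrichment, and expression tables with
  planted repression, so the whole pipeline is testable offline.

## CLI

```sh
capmeth demo --outdir demo_out --seed 1      # synthetic end-to-end run
capmeth simulate --outdir sim --seed 1       # inputs + pipeline.yaml only
capmeth run-all --config sim/pipeline.yaml   # full pipeline from config
capmeth call-islands --reads a.bed --chrom-sizes chrom.sizes --out islands.bed
capmeth call-diff --reads-a kd.bed --reads-b ctrl.bed \
    --chrom-sizes chrom.sizes --out diff.bed
capmeth annotate --regions diff.bed --annotation genes.refFlat \
    --chrom-sizes chrom.sizes --cgi cgi.bed --out annotated.tsv
capmeth profile --reads a.bed --annotation genes.refFlat \
    --chrom-sizes chrom.sizes --out profile.tsv
capmeth enrich --set-a a.txt --set-b b.txt --universe universe.txt
```

Reads are consumed as aligned BED6 (SAM/BAM also supported through
`capmeth.tag_processing.read_sam_reads`); annotation as refFlat or GTF;
CGIs and enhancers as BED; chromosome sizes as a two-column TSV;
expression as TSV with a `gene_id` column and one column per condition.
All coordinates are 0-based half-open internally.

## Layout

| module | contents |
| --- | --- |
| `capmeth.genome_model` | interval/gene types, refFlat/GTF/BED readers, region derivation, shores, CpG-density classes |
| `capmeth.synthetic_data` | toy genomes, capture-library and expression simulators, planted truth |
| `capmeth.tag_processing` | dedup, 3'-extension to fragment midpoints, window counts, FPKM |
| `capmeth.island_caller` | window scoring, island linking, E-value threshold, differential regions |
| `capmeth.feature_annotation` | region→feature assignment, gene/shore change tables |
| `capmeth.profiles` | composite and scaled-interval density profiles |
| `capmeth.set_enrichment` | Fisher/EASE, Venn counts, expression tiers, enhancer linkage |
| `capmeth.pipeline`, `capmeth.cli`, `capmeth.demo` | orchestration, CLI, synthetic demo |
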