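# gcrmap

Split-read mapping, classification, and quantification of gross
chromosomal rearrangements (GCRs) near interstitial telomere-like
sites in yeast-style assay genomes.

The pipeline analyses pooled short-read sequencing of clones that
survived an induced double-strand break by losing a distal `URA3`
marker. All viable breakpoints fall in the **repair region** — the
interval from the integrated HO cut site to the most distal essential
gene. `gcrmap`:

* detects **GCR split reads** (reads anchored in the repair region with
  a soft-clipped tail from the rearrangement partner), either from an
  externally produced SAM or with a built-in seed-and-extend aligner
  suitable for toy genomes;
* calls the **breakpoint coordinate** (the position at which the read
  diverges from the reference) and places the clipped tail genome-wide;
* classifies each read as **telomere addition** (TG₁₋₃ / C₁₋₃A clip),
  **deletion** (unique placement telomere-proximal to the marker), or
  **translocation** (everything else, including multi-mapping clips),
  and assigns translocation classes **A** (internal X/Y′ target with
  junction microhomology), **B** (Y′-element start marked by the
  `ATATATAT` motif), and **C** (telomeric-tract-mediated);
* quantifies event frequencies per feature / 1 kb / 100 bp bin /
  nucleotide, applies the >200-read singleton filter with a Poisson
  read-support diagnostic, computes plate-count GCR frequencies, and
  calls hotspot functionality at the 6.6% threshold;
* scans sequences for telomere-likeness with a sliding T+G / G:T-ratio
  window (`tg_scan`);
* ships a **seeded simulator** (`synthetic_pool`) that builds a toy
  genome with the relevant repeat architecture (Y′ elements, ITS
  tracts, `ATATATAT` motifs, an X element, a bipartite TG-rich
  hotspot), samples pools of 30 single-event clones, and emits FASTQ,
  truth tables, and truth SAM — so the entire pipeline is testable
  offline.

## CLI

Every stage is a subcommand and reads the previous stage's plain-text
outputs, so the pipeline is resumable and each stage can be driven by
hand-crafted fixtures:

```bash
# simulate a pool of 30 clones over a toy genome
gcrmap simulate --out sim --seed 7 --depth 30 \
    --mixture "telomere_addition=0.6,deletion=0.2,translocation_B=0.2"

# detect split reads (from FASTQ via the built-in aligner, or --sam)
gcrmap detect --reference sim/reference.fa --annotations sim/annotations.tsv \
    --fastq sim/reads.fastq --out splitreads.tsv

# classify each split read
gcrmap classify --reference sim/reference.fa --annotations sim/annotations.tsv \
    --splitreads splitreads.tsv --out events.tsv

# collapse, filter, and quantify into frequency tables + JSON report
gcrmap quantify --reference sim/reference.fa --annotations sim/annotations.tsv \
    --events events.tsv --out report/ --histogram

# or run detect -> classify -> quantify end to end
gcrmap run --reference sim/reference.fa --annotations sim/annotations.tsv \
    --fastq sim/reads.fastq --out run/ --seed 7

# sliding-window telomere-likeness scan (3'->5' strand of a left arm)
gcrmap scan --fasta sim/reference.fa --chrom chrR --reverse-complement \
    --out windows.tsv --peaks peaks.tsv
```

Exit codes: 0 success, 1 usage error, 2 data error, 3 internal error.
Outputs embed the configuration hash and seed; re-running the same
configuration reproduces byte-identical tables.

## File formats

* reference: FASTA; annotations: 4–6 column tab-separated BED-like
  (chrom, start, end, kind[, strand, label]), 0-based half-open.
* split reads / events / frequencies: tab-separated tables with
  1-based coordinates in all user-facing columns.
* plate counts: 4-line `key = value` text
  (`galr_colonies`, `cells_plated_gal`, `galr_assayed`, `foar_colonies`).

## Layout

```
src/gcrmap/
  genome_model.py    reference, annotations, repair-region geometry
  synthetic_pool.py  toy genome + pooled-clone read simulator
  splitread.py       split-read detection, breakpoints, clip realignment
  classify.py        event types, translocation classes, microhomology
  quantify.py        filters, Poisson model, frequency tables, reports
  tg_scan.py         sliding-window T+G composition scan
  pipeline.py        orchestration and run configuration
  cli.py             click-based subcommand interface
tests/               unit, property (hypothesis), and acceptance suites
scripts/acceptance.py
```
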