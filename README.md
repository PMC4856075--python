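# srnakit

A small-RNA sequencing analysis toolkit for *C. elegans*-style libraries,
with a built-in simulator so every stage can be verified against known
ground truth without external downloads.

The pipeline stages, each available as a library module and a CLI
subcommand:

| stage | module | what it does |
|---|---|---|
| simulate | `srnakit.simulate` | toy annotated genome (miRNA hairpins with guide/passenger arms, 21U piRNA loci, tRNA/rRNA, transposons, genes with 5'UTR/exon/3'UTR, pathway gene lists) plus barcoded, 3'-adapter-ligated libraries in two replicate groups with per-read ground truth and spiked fold changes |
| preprocess | `srnakit.preprocess` | adapter trimming (substitutions + indels, floor(error-rate x match-length) errors allowed), exact-barcode demultiplexing, >= 16 nt length filter, collapsing identical reads into counted unique sequences |
| align | `srnakit.align` | ungapped best-stratum alignment (all placements at the minimum achievable mismatch count, up to 3 mismatches, both strands) and the length-dependent mismatch filter (16-17 nt: 0, 18-19: 1, 20-24: 2, >= 25: 3) |
| classify | `srnakit.classify` | miRNA assignment by the +/-5 nt 5'-end window against annotated mature 5' ends (sense only), sense/antisense feature counting by full containment, endo-siRNAs as reads antisense to gene sub-regions, pathway partitioning (CSR-1 / WAGO / ALG-3/4 / ERGO-1), per-class and per-feature count tables |
| diffexpr | `srnakit.diffexpr` | TMM normalization, qCML common negative-binomial dispersion, two-sided conditional exact test (doubled smaller tail), Benjamini-Hochberg FDR |
| phenostats | `srnakit.phenostats` | Pearson chi-square on penetrance tables (no continuity correction) and two-tailed Welch t-test on seam cell counts |

## CLI

```sh
srnakit simulate --config config.yaml --seed 1 --outdir sim/
srnakit preprocess --fastq sim/wt_1.fastq.gz ... --barcodes sim/barcodes.tsv --outdir pp/
srnakit align --genome sim/genome.fa --reads pp/wt_1.collapsed.fa --library wt_1 \
    --out-tsv aln/wt_1.tsv --out-sam aln/wt_1.sam
srnakit classify --gff sim/annotations.gff3 --mature sim/mature_mirnas.tsv \
    --pathways sim/pathways --alignments wt_1 aln/wt_1.tsv ... --outdir cls/
srnakit de --counts cls/counts_mirna_arm.tsv --out de.tsv --out-ma ma.tsv
srnakit phenostats --chisq-table penetrance.tsv --ttest-a a.txt --ttest-b b.txt --out stats.tsv
```

The simulate YAML config has two sections, `genome` and `library`,
whose keys mirror `GenomeSpec` and `LibrarySpec` fields.

## Notes on conventions

* Coordinates are 0-based half-open in memory; GFF3 and SAM output use
  their standards' 1-based conventions.
* Untrimmed reads are retained by default (`--discard-untrimmed` to
  drop); demultiplexing requires an exact barcode match; `N` never
  matches adapters or barcodes and counts as a mismatch in alignment.
* Multi-mapping reads contribute `count/n` per placement by default
  (`--count-mode all` for integer counting).
* Simulated outputs are byte-identical for identical specs and seeds
  (gzip streams are written with a fixed mtime).
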