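# trmc

Toolkit for calling N4-acetylcytidine (ac⁴C) sites on tRNA and rRNA at
single-nucleotide resolution from reduction–misincorporation sequencing,
with downstream tRNA-abundance and translation readouts.

The assay chemistry splits each sample into three groups: **reduced**
(NaCNBH₃ treatment converts ac⁴C into a base that reverse transcriptase
misreads as T), **deacetylated** (mild alkali strips the acetyl group
first, so reduction leaves no mark — the matched negative control) and
**mock** (untreated). A modified C therefore shows a dominant C→T
misincorporation only in the reduced library. This package implements
the analysis side of that design end to end, plus a seeded simulator so
every stage is testable without external data.

## Modules

| module | what it does |
| --- | --- |
| `trmc.refset` | Load/normalize mature tRNA/rRNA FASTA (U→T, CCA completion), collapse identical isodecoders, anticodon→codon mapping |
| `trmc.simreads` | Seeded simulator: three-condition libraries with embedded C→T signatures, knockdown pairs, ribosome footprints, count tables; built-in synthetic reference sets |
| `trmc.alnpile` | Built-in ungapped aligner (≤2 mismatches, fractional multi-group weights) or SAM/BAM ingestion; base-count pileups; misincorporation/stop rate tracks |
| `trmc.sitecall` | Three-condition site caller (one-sided exact test reduced vs deacetylated, BH FDR, effect-size gates), differential modification, summaries, TSV/BED export |
| `trmc.abundance` | Weighted tRNA counts, CPM normalization, the P ≤ 0.05 & fold-change ≥ 1.5 differential-expression rule, modified-vs-unmodified class comparison |
| `trmc.riboccupancy` | RPF filtering (26–32 nt, frame 0), P/A-site assignment, codon occupancy with basal (+1/+2/+3) normalization, TE/TR, codon-frequency-by-class (Kruskal–Wallis) |
| `trmc.cli` | `trmc` command-line interface and end-to-end pipeline orchestration |

Coordinates are 1-based on the normalized mature sequence (including the
appended CCA); site labels are linear sequence positions.

## CLI

```sh
# end-to-end on the built-in synthetic reference set
trmc run --mode trmc --seed 1 --outdir out/

# or stage by stage
trmc simulate --refs refs.fasta --sites sites.tsv --condition reduced --out reduced.fastq
trmc align    --refs refs.fasta --reads reduced.fastq --out reduced.hits.tsv
trmc pileup   --refs refs.fasta --reads reduced.fastq --hits reduced.hits.tsv --out reduced.pileup.tsv
trmc callsites --refs refs.fasta \
    --pileup-reduced reduced.pileup.tsv \
    --pileup-deacetylated deac.pileup.tsv \
    --pileup-mock mock.pileup.tsv --out sites.tsv
```

Other subcommands: `diffmod` (control vs knockdown at known sites),
`quant` (tRNA abundance + DE rule), `occupancy` (codon occupancy from
footprint placements), `te` (translation efficiency / ratio). Thresholds
can be supplied via a YAML config (`--config`); all tables are TSV with
a single `#`-prefixed header line.

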