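# replikit

Toolkit for replication-origin analyses around scored genomic peak sets:

- **Colocalization** — fraction of anchor peaks within a distance cutoff of
  event peaks (edge-to-edge, overlap = 0; center-to-center optional), signed
  distance-to-center profiles, and stratification of origins into
  binder-bound / unbound subsets.
- **Motif null model** — selection of short, isolated, high-scoring peaks
  for motif discovery input; generation of randomized genomic region sets
  matched to a template in length and GC content; exact IUPAC motif
  containment scanning on both strands; and an observed-vs-null enrichment
  table stratified by origin proximity.
- **DNA-combing fiber statistics** — µm→kb conversion (2 kb/µm), fork speed
  from second-pulse elongating tracks, inter-origin distances, the
  >33%-longer fork-asymmetry rule, fraction of fibers with signal, and
  two-sided Mann–Whitney comparison between conditions.
- **Coexpression screen** — row z-scores and ranking of candidate genes by
  mean Pearson correlation with a replication gene set.
- **Synthetic data** — deterministic generators for genomes (controllable
  GC), planted motifs, anchor/event peak pairs with an exact colocalization
  fraction, and fiber populations with known spacing/speed/stall truth, so
  every stage is testable offline.

## CLI

All stages are subcommands of `replikit` (see `replikit --help`):

```sh
replikit simulate genome --chroms chr1:1000000 --gc 0.5 --seed 1 --out genome.fa
replikit simulate peaks --chroms chr1:16000000 --n-anchors 1000 \
    --colocal-fraction 0.8 --seed 2 --out-prefix pp
replikit colocalize --anchors pp.anchors.bed --events pp.events.bed --cutoff 2000
replikit profile --anchors A.bed --events B.bed --half-window 10000 --bin 500 --out profile.tsv
replikit stratify --origins O.bed --binder R.bed --cutoff 2000 --out-prefix origins
replikit select-peaks --peaks R.bed --max-len 400 --min-iso 1000 --min-score 150 --out subset.bed
replikit randomize --template subset.bed --genome genome.fa --n 3 --gc-tol 0.02 --seed 5 \
    --out-prefix subset
replikit motif-enrich --regions subset.bed --nulls subset.null1.bed --nulls subset.null2.bed \
    --nulls subset.null3.bed --origins O.bed --genome genome.fa --motif GGAGGRGGVGGW \
    --cutoff 2000 --out report.tsv
replikit simulate fibers --n 1000 --median-iod 102.6 --speed-mean 1.570 --seed 3 --out fibers.tsv
replikit fibers --table fibers.tsv --condition-a WT --condition-b KO --out summary.tsv
replikit coexpress --matrix expr.tsv --candidates cand.txt --repl-genes repl.txt --top 10
replikit run --config config.yaml --out-dir out   # combined pipeline + JSON manifest
```

Fiber input is a per-segment TSV: `fiber_id condition ssdna_length_um
segment_index label length_um kind origin_id side start_um`, with label
`none` marking fibers without replication signal.

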