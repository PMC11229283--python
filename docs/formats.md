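# File formats

All coordinates are 0-based, half-open, on the forward strand of the master
circle, unless stated otherwise.  TSV files carry a header row with exactly
the column names below, in this order.

## Genome

- `genome.fasta` — single FASTA record, the circular master sequence.
- `contigs.tsv` — `contig_id  start  end  depth`.  The contigs must tile
  `[0, genome length)` contiguously; repeat copies are their own contig
  entries (the simulator names them `<repeat>.1` / `<repeat>.2`), so repeat
  loci coincide with contig boundaries.  `depth` (mean coverage, ×) is
  optional and may be empty.

## Repeat annotations

`repeats.tsv` — `repeat_id  orientation  locus1_start  locus1_end
locus2_start  locus2_end  composite`.

- `orientation`: `+` direct, `-` inverted (locus2 carries the reverse
  complement), `?` unknown (treated as direct with a warning).
- `composite`: `0`/`1`; `1` marks a multi-contig complex repeat (CR).
- BED6 export: two lines per repeat, `name` = repeat id, strand column `+`
  for locus1 and the pair orientation for locus2.

## Assembly graph

GFA 1.0.  `S` lines may carry sequence or `*` with `LN:i:` length; coverage
depth is read from a `DP:f:` or `dp:f:` tag.  `L` lines define links
(`from  from_orient  to  to_orient  overlap`); the overlap field is ignored.

## Alignments (PAF)

Standard 12+ column PAF (minimap2 dialect).  Target names must be
`<repeat_id>|<path>` with path one of `m1 m2 s1 s2` (this is how
`mitorecomb quartets` names its FASTA records, so mapping reads against that
FASTA with minimap2 yields compatible PAF directly).  Mapping quality is
ignored; a record is primary when it has `tp:A:P` or no `tp` tag at all.

## Reads

FASTA or FASTQ, optionally gzipped.  Simulated reads are written as FASTQ
with a constant placeholder quality (the pipeline never consumes qualities).

## Labels and counts

- `labels.tsv` — `read_id  repeat_id  label` with label in
  `m1 m2 s1 s2 ambiguous none`.
- `counts.tsv` — `repeat_id  m1  m2  s1  s2`.

## Report

`report.tsv` — `repeat_id  length  orientation  size_class  m1  m2  s1  s2
F_m  F_s  rate_percent  activity` plus, when quartets are available, one
`*_path` column per junction path with its contig composition (reverse-
complemented flank contigs carry a trailing apostrophe).  `rate_percent` is
rounded half-up to 2 decimals; an undefined rate (no spanning reads) is NA.

## Simulation truth

`truth.tsv` — `read_id  molecule  state  start  length  strand
focal_repeat`.  `state` is one bit per repeat (1 = secondary conformation in
the molecule of origin), `start`/`length` locate the read on its origin
molecule (forward strand), and `focal_repeat` is set for junction-mode reads.

## Simulation config (JSON)

Keys of `SimulationConfig`: `genome_length`, `repeat_specs` (list of
`[length, orientation, f]`), `contig_min`, `read_count`,
`read_length_median`, `read_length_sigma`, `read_length_min`, `error_rate`,
`mode` (`molecule` or `junction`), `seed`.  The pipeline echoes the resolved
config next to its outputs.
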