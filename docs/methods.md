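# Methods

## The measurement problem

Plant mitochondrial genomes are usually *assembled* as a single circle (the
"master circle"), but in vivo they are a population of molecules
interconverted by homologous recombination (HR) between pairs of
near-identical repeats.  Each repeat pair admits two arrangements of its
flanking sequence.  Writing the two repeat copies with their flanks as
`up1-R-down1` and `up2-R-down2`, the master arrangement exhibits the two
junctions

    m1 = up1-R-down1        m2 = up2-R-down2

and the recombined (secondary) arrangement the two crossover junctions

    s1 = up1-R-down2'       s2 = up2'-R-down1

where the primed flanks are taken in the frame that keeps R forward: for a
direct repeat (copies co-oriented) `down2' = down2` and `up2' = up2`; for an
inverted repeat the master segment around locus 2 reads `up2-rc(R)-down2`,
so in the R-forward frame its upstream flank is `rc(down2)` and its
downstream flank is `rc(up2)`, giving

    s1 = up1-R-rc(up2)      s2 = rc(down2)-R-down1.

This follows from segment-inversion algebra: recombination between inverted
copies on `A-R-b-rc(R)-C` inverts the intervening segment, producing
`A-R-rc(b)-rc(R)-C`, and the two junctions of that product are exactly the
s1/s2 above.  The package verifies this construction against an independent
molecule-level simulation (`toggle_conformation`) by exact substring search,
in both orientations.

## Spanning-read evidence

Long reads are aligned to the four junction path sequences.  Each path is
the repeat plus its neighboring contigs; a flank shorter than 1 kb (default
`min_flank_contig`) is extended with further contigs so that every path has
enough unique anchor sequence.  A read supports a path only when a single
primary alignment covers the entire repeat plus at least `min_flank` = 100 bp
on both sides at identity >= `min_identity` = 0.7.  A read satisfying two or
more paths is ambiguous; ambiguous and non-spanning reads are excluded.
These thresholds are exposed as parameters; 100 bp and 1 kb are the
published operating point, and 0.7 is a permissive identity floor for noisy
long reads (it is vacuous for error-free simulated reads).

Alignments can come from minimap2 as PAF (map reads against the quartet
FASTA written by `mitorecomb quartets`), or from the built-in matcher.  The
matcher is deliberately simple and exact for the substitution-only error
model of the simulator: 15-mers sampled along the read vote for an offset
(diagonal) per path and strand; the winning diagonal defines a gap-free
alignment, which is then clipped to its maximum-scoring contiguous segment
(+1 per match, -2 per mismatch) so that, like a local aligner, it breaks at
a junction instead of running through a mismatching flank.  It handles
substitutions (0-10%) but not indels, which is why the simulator's default
error model is substitution-only; use an external aligner for indel-rich
data.

## The rate statistic

For one repeat with support counts (m1, m2, s1, s2):

    F_m = max(m1, m2),  F_s = max(s1, s2),
    rate = 100 * min(F_m, F_s) / (F_m + F_s)   [%]

Only the better-supported junction of each arrangement is acknowledged,
which makes the statistic robust to one junction being harder to span than
the other.  The rate lies in [0, 50] for every input, reaching 50 exactly at
parity (F_m = F_s); it is undefined (reported NA) when no spanning read
supports either arrangement.  Activity calls: `active` when both
arrangements have support; `inactive_no_secondary` when only one does (the
repeat is then a false positive of graph-based repeat detection, or
genuinely silent); `no_data` otherwise.  Zero rates are genuine
observations and enter the length-rate correlation; NA rates do not.

The repeat length vs rate relationship is summarised by the Pearson
correlation on raw lengths (no log transform) with a two-sided t-test on
n - 2 degrees of freedom.  On the published floating-bamboo table of 25
repeats this reproduces r = 0.74, p < 0.01.  A species column is accepted
for pooled multi-species tables.

## Repeat discovery support

Two helpers mirror how repeat pairs are found in practice.
`detect_candidate_repeats` flags assembly-graph nodes whose coverage depth
is at least `depth_ratio` (default 1.75, tolerant of noise around a nominal
2x) times the median depth of non-candidate nodes *and* which branch into
>= 2 neighbors on each end; the multiplicity estimate is depth over the
single-copy baseline, rounded, floored at 2.  `find_complex_repeats`
enumerates maximal exactly-repeated substring pairs of the circular master
(both orientations, seeded by 31-mer diagonal runs), suppresses pairs
contained in longer ones, and annotates each with the elementary repeats
and contigs it spans — this is how multi-contig complex repeats (CRs) arise
as compositions like `contig7-LR1-contig8`.  Matching is exact by design;
mismatch-tolerant repeat scanning is out of scope.

## The simulator

`generate_master_circle` builds a circular master from unique random
contigs (>= `contig_min` = 1.5 kb) with planted repeat pairs.  Copy 1 of
every repeat is planted in the first half of the circle and copy 2 in the
second half in *reverse* order (a palindromic layout), so the arc between
any pair's copies contains other pairs' copies either both or neither —
conformation toggles then compose without interacting.  Unique regions are
rejection-sampled so that no exact match of >= 30 bp (either strand) occurs
between them or against a repeat, keeping junction evidence unambiguous.

Molecules are circular lists of oriented segments, so recombination is
exact: a direct pair fissions one circle into two (carrying the s1 and s2
junctions); an inverted pair reverse-complements the inter-copy segment run
(one circle carrying both).  Total bases are conserved and inverted toggling
is an involution — both are tested.

`simulate_reads` offers two sampling modes:

- **molecule mode** draws one conformation state per molecule (each repeat
  secondary independently with probability `f`), materialises it and samples
  a read uniformly from the resulting circle(s), length-weighted across
  fission products.  At most one *direct* repeat may switch in this mode
  (a second fission could strand other copies on separate circles).
- **junction mode** allocates reads round-robin over repeats and centres
  each read on one junction of its focal repeat (secondary with probability
  `f`, junction 1 or 2 uniform).  This yields spanning evidence for
  arbitrary `f` combinations at a fixed read budget; the classifier then
  evaluates each read only against its focal repeat, since only those pairs
  are sampled representatively.

Read lengths are lognormal (median 12 kb, sigma 0.35, minimum 1 kb — an
N50 in the 10-30 kb range typical of Nanopore organelle datasets); errors
are uniform substitutions at `error_rate` in [0, 0.1].  Because a read
spans a repeat only when its length draw covers repeat + 200 bp, the number
of *informative* reads per repeat is roughly `(1 - W/L)` times the
allocation, and simulations pad accordingly.

`truth_classify` is the oracle twin of the alignment classifier: it labels a
read purely from its recorded origin coordinates (does the true span cover a
repeat copy ± 100 bp, and which junction does that copy form on its
molecule, read off the copy's neighboring segments).  On error-free reads
the alignment classifier agrees with it to >= 99.9%; the residual
disagreement channel is reads long enough to span *both* copies of a repeat
(legitimately ambiguous either way).

What the simulator does not model: indels and homopolymer artefacts,
chimeric reads, coverage bias, substoichiometric shifting dynamics, or the
molecular topology of multi-event intermediates beyond single-event algebra
composed per molecule.  Passing tests therefore demonstrate correctness of
the counting and statistics under a clean substitution-only regime, not
robustness to every real-data pathology — for real data, use an external
aligner and the PAF route.

## Codon-usage statistics

For CDS collections the package computes positional GC (GC, GC1, GC2, GC3,
GC12 = mean of GC1/GC2, and GC3s over third positions of synonymous codons,
excluding Met, Trp and stops), Wright's effective number of codons, RSCU,
PR2 coordinates and neutrality-plot points.  Conventions, where tools
differ: the standard genetic code by default (any NCBI table selectable);
six-codon families (Leu, Ser, Arg) kept whole rather than split 2+4; ENC
per-family homozygosity F = (n·Σp² − 1)/(n − 1) with families below two
observations dropped, a missing 3-fold class imputed as the mean of the 2-
and 4-fold class averages (CodonW-compatible), and the composite
2 + 9/F̄2 + 1/F̄3 + 5/F̄4 + 3/F̄6 capped at 61; the ENC-plot expected curve
is 2 + s + 29/(s² + (1−s)²), whose value at s = 0.5 is 60.5 (the exact
no-bias ceiling of 61 is approached only by the estimator on uniform
usage, not by the curve).  PR2 uses third positions of the eight fourfold-
degenerate codon boxes, x = G3/(G3+C3) and y = A3/(A3+T3).

## Numerical and reporting choices

- Size classes: SR < 500 <= MR < 1000 <= LR (half-open bins; the published
  table leaves the boundaries unassigned), CR for multi-contig composites
  regardless of length.
- Rates are kept at full precision internally and rounded half-up to 2
  decimals in reports.
- All randomness flows through one seeded NumPy generator; identical
  config + seed reproduces outputs byte-for-byte.
- Unknown-orientation repeats are processed as direct with a warning (their
  published junction labels follow the direct-crossover pattern).
- Degenerate quartets (both loci sharing identical flank sequence) are
  flagged; every spanning read is then ambiguous and the repeat yields no
  usable counts, which is the honest outcome.

## Problem sizes used in the test suite

The expensive fixture simulates a 100 kb circle with five repeats switching
at f = 0, 0.05, 0.2, 0.35 and 0.5 and 3,200 junction reads per repeat
(>= 2,000 spanning each); recovered rates are required to fall within three
binomial standard errors of 100·min(f, 1−f), and the f = 0 repeat must be
called `inactive_no_secondary`.  Oracle cross-checks (brute-force substring
scans, direct-formula ENC/RSCU/Pearson, truth-label agreement) run on toys
up to ~30 kb.  These sizes were chosen as the smallest at which the
binomial tolerances are meaningful.
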