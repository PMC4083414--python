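# Methods

## Scope and model

`miredit` treats a microRNA precursor as a *stem-loop*: a sequence, a
secondary structure given as a Vienna dot-bracket string (structures are
inputs, e.g. from a hairpin annotation database; the package does not fold
RNA), optional annotated 5P/3P mature intervals and optional genomic
segments. All user-facing coordinates are 1-based inclusive; internal
arrays may be 0-based but nothing 0-based is serialized or displayed.

### Structure classification

The dot-bracket string is parsed with a bracket stack into a symmetric,
nested pairing table (pseudoknot alphabets are rejected; malformed strings
fail naming the first offending index). Positions are partitioned into
maximal runs of five kinds:

- **duplex** — consecutive paired positions;
- **bulge** — an unpaired run between two pairs whose partners are
  adjacent on the opposite strand (opposite run length 0);
- **internal loop** — an unpaired run whose flanking pairs enclose a
  non-empty unpaired run on the opposite strand; each run is annotated
  with the other's length (`opposite_bulge_len`);
- **hairpin loop** — the run closed directly by the innermost pair;
- **flank** — unpaired runs outside the outermost pair.

Only single-hairpin structures are supported; a second terminal loop (a
`(` reopening after some `)`) raises an unsupported-structure error. The
classification is an exact partition, which the tests verify directly
against the pairing table with an independent per-element checker.

### Single- vs double-stranded counting

N_ds is the number of duplex nucleotides; N_ss by default counts only stem
interruptions — bulges and internal loops. The terminal loop and flanks
are excluded because the statistic's contrast is between the duplex and
its interruptions, and contiguous single-stranded stretches are a
different structural regime (editing enzymes that act on double-stranded
RNA are not expected to engage them at all); `include_hairpin_loop` /
`include_flanks` flags provide the inclusive variant, and sites falling in
excluded classes are reported as *unclassified* rather than silently
dropped. Internal loops are counted as single-stranded even though only
one-sided interruptions are colloquially "bulges": any unpaired stem
position is single-stranded, with the element kind preserved for
reporting.

## Read preprocessing

Adaptor clipping removes the read tail at the leftmost position where
either the full 3' adaptor occurs or a prefix of the adaptor of at least
`min_overlap` nt (default 6) runs to the read's 3' end. Matching is exact:
no tolerance is specified for the protocol, and exactness keeps the filter
deterministic. Reads that clip to nothing are discarded. The length filter
keeps reads of length ≥ 16 ("shorter than 16" is read strictly, so 16
survives), and any read containing `N` is removed. Collapsed-FASTA counts
are parsed from `_xN` and `-N` header suffixes; anything else counts 1.

## Mapping

Alignment is ungapped, end-to-end, sense-strand against stem-loops, with
at most `max_mm` substitutions (default 1) and *all* qualifying placements
reported — a read matching two stem-loops contributes to both profiles and
is flagged. Correctness is defined by the exhaustive offset scan; the
implementation accelerates it with a pigeonhole prefilter (with ≤ 1
substitution, one half of the read must match exactly, so candidate
offsets come from exact occurrences of either half), and the test suite
checks the two against each other on hundreds of random instances.

The cross-genome filter re-maps every mismatched read against the genome
on both strands; one placement (≤ `max_mm` substitutions) outside the
read's own stem-loop locus — 1-based interval overlap — removes it.
0-mismatch reads always pass. The first disqualifying placement
short-circuits the scan; whether further placements exist does not change
the decision.

## Editing candidates

Coverage at a position is the summed multiplicity of collapsed reads
overlapping it; substitutions are tallied per (ref, alt) pair weighted by
multiplicity. The editing level is computed in exact integer arithmetic as
`(200·m + t) // (2·t)`, i.e. round-half-up of the percentage — pinned by a
published row where 6/48 (12.5%) prints as 13. The candidate row's type is
the dominant alternative base by count, ties broken to the
lexicographically smallest base and flagged. Both thresholds are strict
(coverage > 20, level > 10) by default, with a non-strict switch, and the
mismatch-frequency display track can use either position coverage
(default) or the whole library as denominator. The per-site library
support table flags sites seen in ≥ 2 libraries as high-confidence.

## Observed vs expected context

For S unique (stem-loop, position) sites, E_ds = S·N_ds/(N_ds+N_ss) and
E_ss = S·N_ss/(N_ds+N_ss); E_ss + E_ds = S exactly, which is asserted to
1e-9 under property sweeps. The nucleotide universe defaults to stem-loops
carrying at least one candidate (the natural conditioning when candidate
discovery and the universe come from the same run), with an `all`
alternative. Ratios are reported to 2 decimals. Zero candidates raise an
error unless an empty report is explicitly allowed (ratios then NaN).

## Display

The SVG display is static but machine-readable: every read-group bar,
mismatch segment, coverage bar, structure run and bulge box carries
`data-*` attributes, replacing pixel assertions with DOM assertions and
interactive clicking with flags (`--highlight-pair` draws the magenta
pairing connector; `--libraries` selects libraries; a chosen library is
tinted pink; libraries are separated by a dotted divider). The group
display threshold is strict — `min_group_count=30` shows groups with more
than 30 identical reads — matching the published display convention; the
default of 1 shows everything. The green bulge-length box is drawn on the
strand opposite the bulge, spanning the interval between the partners of
the bulge's flanking pairs, and carries the bulge's own length as its
label. Coverage bars are scaled so the maximum fills the track height. The
mismatch-frequency track is a stripe whose opacity encodes the percentage;
a polyline variant is available via `freq_style=line`. Mismatch colors per
alternative base are fixed in the default style (distinct colors for
A/C/G/T); no published palette exists for them.

## Synthetic data

Structures are constructed, not folded: `make_stemloop` lays down
`stem_len` complementary pairs, a terminal loop, and bulges at requested
arm offsets, so element classification has an exact ground truth and no
folding dependency or nondeterminism enters the tests. Simulated libraries
draw each read from an annotated mature interval with both ends jittered
inward by geometric(0.7) offsets — read 5' ends pile up at the annotated
start, as real isomiR distributions concentrate at the dominant cleavage
site — plant each overlapping configured substitution independently with
its per-read rate, add uniform sequencing errors (rate < 0.05), and append
the adaptor. The mini-genome embeds each stem-loop in random spacer
sequence at recorded loci and can plant *decoys* — single-substitution
near-copies of read-length windows — to exercise the cross-genome filter.
All generators are deterministic given their seed.

What the generator does *not* emulate: realistic base composition or
folding energetics, expression-level differences between libraries,
quality-score structure, indels, or multi-hairpin loci. Passing recovery
tests therefore demonstrate the pipeline's arithmetic and filtering logic
under clean, known truth — not performance on real libraries, where
adaptor variants, PCR duplicates and paralogous hairpins add noise the
truth table cannot represent.

## Problem sizes and numerical choices

The recovery experiment uses four hairpins (28-bp stems, one bulge), one
library per planted rate {0.15, 0.3, 0.5, 0.99}, depth 100 over the
edited arm, thresholds at their defaults; with no sequencing error all
planted sites are recovered with zero false positives, and at 1% error
false positives remain zero (expected error level ≈ 1% sits far below the
10% threshold). The mapper sweep uses 500 random read/reference instances
(reads 16–30 nt, references 30–200 nt), half with planted 0–2-error reads.
The uniform-null experiment plants 1000 unique sites over the ~1280 stem
nucleotides of a 20-hairpin panel; both observed/expected ratios fall
within 1.0 ± 0.1 (sampling standard deviation ≈ 0.04 for the
single-stranded ratio at these sizes). These sizes keep the whole suite
in seconds while leaving each check statistically meaningful.

## Known limitations

- One mismatch per read end-to-end; no gaps, no quality awareness. Users
  needing a production aligner can import its SAM via `read_sam`.
- Strict thresholds reproduce the published filter's letter; published
  tables show occasional rows suggesting a different denominator or
  non-strict boundary, so both are configurable, and a handful of printed
  levels 1–2 points above any consistent rounding of their printed counts
  are not chased.
- Multiloop (branched) structures are rejected rather than partially
  classified.
- The display spells out read sequences for every shown group; for deep
  libraries raise `min_group_count` or disable the track.
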