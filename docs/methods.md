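# Methods

This note records how `telarray` detects and classifies telomere-derived
repeat arrays, what the synthetic-read generator does and does not
emulate, and the design choices taken where the procedure was genuinely
open.

## Motif scanning

Seeding follows the strict query logic used on the original nanopore
libraries: three tandem copies of a motif, matched with **zero
mismatches**, on both strands. Only the three primary motifs are queries —
the canonical heptamer TTTAGGG, the terminal derivative TTTAAAA, and the
interstitial derivative CCTGGG. The family variants (CCCTGGG, CCTAGG,
CCCAGG) and the degenerate canonical forms (TTTAGG, TTAGGG) are *not*
queries: CCTGGG read on the minus strand is the same string as CCCAGG read
on plus, so treating the variants as independent queries would destroy the
orientation signal that junction detection depends on. Variants instead
participate in array extension and monomer decomposition.

Seeds merge into an array when they share strand and motif group and lie
within `max_intra_array_gap` (default 14 bp = two monomers; the merge rule
is ours — the original procedure never states one). Two groups exist:
{TTTAGGG, TTTAAAA}, which co-occur in combined terminal arrays, and the
CCTGGG family. Keeping the groups separate is what lets a junction be
represented as DTR / canonical core / DTR rather than one fused array.

Array boundaries are then extended monomer by monomer while the next
6–8 bp window lies within edit distance `max_monomer_edit_distance`
(default 2) of a group monomer — real arrays carry a few percent of
monomers deviating by one or two nucleotides, and at nanopore error rates
roughly a third of all monomers acquire at least one error. When extension
stalls, a bounded *exact jump* is allowed: up to `max_intra_array_gap`
bases may be skipped if the landing point is an exact copy of a group
monomer. This crosses heavily corrupted monomers and the spacers of
elongated units while re-anchoring the tiling phase on an exact match;
landing on anything less than an exact copy is not allowed, which keeps
run-off into non-repeat sequence negligible. The same jump logic fuses
seed islands across stretches in which sequencing errors have destroyed
every exact 21-bp seed (at ~5.5% total error, only ~30% of seed windows
survive).

Monomer decomposition is greedy left-to-right tiling: at each offset the
catalog monomer and window length (6/7/8 bp) with the smallest edit
distance wins; ties prefer a primary motif over a variant, then the longer
monomer, then lexicographic order. Primary-first (a slight generalization
of canonical-first) matters: in a CCTGGG tract preceded by a chance C,
CCTGGG and CCCTGGG both match exactly, and preferring the family's
dominant monomer keeps the tiling phase anchored. Windows matching nothing
within the tolerance become `unassigned` calls; concatenating the observed
call sequences always reconstructs the array sequence exactly. Arrays are
reported on the G-rich strand: minus-strand hits keep forward-read
coordinates, but their decomposition is computed on the reverse
complement. A dynamic-programming tiling oracle (minimal total edit cost
over all window boundaries) backs the greedy tiler in the tests.

## Classification

Position: TERMINAL iff the array starts within `edge_tol` of the read
start or ends within `edge_tol` of the read end (default 100 bp — the
original analysis shows arrays "at the edge" of reads without defining a
distance; 100 bp absorbs adapter remnants and ragged ends). The boundary
is inclusive, and growing `edge_tol` can only move arrays toward TERMINAL.

Blocks are maximal runs of one monomer class, where canonical variants
count as canonical (deviant monomers are array-internal noise, never block
founders) and unassigned calls ride along with the preceding run without
contributing evidence. A run with fewer than `min_block_copies` (default
3, the seed length) *assigned* calls is absorbed into the flanking run
with more calls (tie → left). Counting only assigned calls prevents a
single error-flipped monomer plus a stretch of unassignable neighbours
from fabricating a TTTAAAA block inside a pure array — with naive
counting that artifact alone pushed the combined-class false-positive rate
above 5% at default error rates.

Composition: PURE_TEL (all blocks canonical), COMBINED_TEL_TTTAAAA
(canonical and TTTAAAA blocks, nothing else), DTR (all blocks in the
CCTGGG family), MIXED_OTHER (anything else). Junctions are triples
DTR — short pure-canonical core (≤ `core_max_copies`, default 10; the
observed cores are "a few" copies) — DTR with opposite flank orientations
and gaps ≤ `max_flank_gap` (default 50 bp); detection is equivalent to a
brute-force scan over array triples, which the tests verify. Colocations
pair interstitial telomeric and DTR arrays within `max_coloc_gap`
(default 1 kb) by greedy nearest-gap assignment, each array used once;
arrays already in a junction are excluded, since a junction core is by
construction an interstitial canonical array next to a DTR and would
otherwise always double-report.

The forbidden-combination statistic counts derivative-only arrays that
join TTTAAAA with the CCTGGG family and contain no canonical block —
a pattern never seen in the studied libraries. Because the scanner keeps
the two seed groups in separate arrays, the pattern can also surface as a
TTTAAAA-only array directly abutting a DTR array (gap ≤ 14 bp); both
forms are counted. It is a reported statistic, never a filter.

## Tandem consensus

Candidate periods come from the histogram of distances between successive
identical k-words (default word 8, `max_period` 210 bp, minimum support
5) — the same signal as the diagonal spacing in a self dot plot. Ranking
is by support, ties to the smaller period; the estimate is invariant under
reverse complementation.

The consensus engine is a simplified stand-in for the usual
tandem-repeat-finder role: wraparound dynamic programming of the whole
array against a cyclic template (match +2, mismatch −3, indel −5 by
default; the weights the original analysis used are unstated, so the
195-bp checks carry a ±5 bp weight-sensitivity tolerance). The template
starts as the first period-length window and is refined by column-majority
vote — majority-gap columns are dropped and majority insertions become new
columns, so the period can drift to the true unit length — until stable
(≤5 rounds). The in-row cyclic dependency of the DP is resolved exactly
with prefix-max scans over a doubled column axis, valid because gap
penalties are negative. Reported statistics: identity = matches / aligned
columns, indel rate = indels / sequence length, copy number = sequence
length / period. The consensus is reported in its lexicographically
smallest rotation (a tandem tract has no distinguished phase).

Elongated monomers: for an interstitial array, every supported period of
at least twice the base motif length is consensus-built, and units that
still contain a copy of the base motif within edit distance 2 (checked
cyclically) are reported; `distinct_consensus_count` is the number of
distinct unit sequences found. A pure heptamer array supports only the
7-bp period and therefore reports nothing. With `max_period` = 210 bp the
engine covers units up to the 195-bp maximum seen in the source libraries
with headroom, while excluding trivial doublings of such units.

## Strand-exchange model

A monomer is a valid recombinant if it splits into a nonempty substring of
the cyclic G-strand monomer followed by a nonempty substring of the cyclic
C-strand monomer, or the same with roles swapped (the exchange scheme has
no fixed polarity). Segments are substrings of the *cyclic* monomers
because telomeric tracts have no phase; segment length is capped at two
monomer lengths to bound the enumeration (the cap and the ≥1-base rule are
ours). Both observed derivatives decompose: TTTAAAA = TTTA(G) + AAA(C);
CCTGGG = CCT(C) + GGG(G). Exhaustive enumeration over all length-6 and
length-7 monomers (backed by an independent brute-force oracle in the
tests) shows only ~6.7% of random length-6 monomers are valid recombinants,
so validity is informative. The generative events — replace one monomer
with a uniformly drawn recombinant product; insert tandem copies of one
monomer (t-loop / rolling-circle style block growth) — reproduce the
combined-array class from a pure array, which the tests assert. The model
deliberately does not adjudicate between the strand-exchange and
rolling-circle mechanisms.

## Synthetic libraries

Reads are lognormal in length (median 12 kb, σ=0.30, clipped to 5–25 kb,
matching the ~10–25 kb reads the analysis worked with). Each read draws
one architecture: pure terminal array, combined terminal array, ITR, DTR,
ITR+DTR colocation, junction cassette, elongated-unit (HOR) array, or no
array (default frequencies 0.16/0.10/0.16/0.12/0.06/0.04/0.04/0.32 —
chosen to exercise every class; the real per-class abundances are unknown
and nothing downstream depends on these defaults). Terminal arrays sit
flush at a read end, left-end arrays written as the C-rich strand;
interstitial arrays keep ≥2 kb from both ends. ITRs plant deviant
monomers at 3% by default (the observed range is 2–5%), drawn from the
degenerate forms plus single substitutions that provably decompose back
as single variant calls; never three adjacent (three adjacent 6-bp
variants would open a gap wider than the merge tolerance and split the
array, making exact truth ill-posed). Combined arrays alternate 2–6
blocks of geometric length (mean 8, minimum 3 so no planted block can be
absorbed; the real block-length distribution is unpublished). DTR arrays
mix CCTGGG/CCTAGG/CCCTGGG at 85/10/5. Junction cassettes are
DTR(±) – 10–40 bp – TTTAGGG×3–8 – 10–40 bp – DTR(∓). HOR arrays tile
(TTTAGGG)×3 + a screened 7-bp spacer, ending on a motif triple — a unit a
zero-mismatch triple seed can still find; truth block counts include the
spacer calls the classifier absorbs.

Array edges are planted crisp (three exact primary monomers at each end)
and all spacer/backbone bases near a boundary are resampled until no
window crossing the boundary could seed, extend, or exact-jump a scan; the
backbone is likewise screened free of chance seed queries. Consequently a
zero-error library round-trips exactly: scan → classify reproduces every
interval, strand, class, block count and event. This is a property of the
*generator's screening discipline*, not of the scanner alone — on real
data boundaries are only exact up to the ±1–2 monomer ambiguity inherent
in prefix-related catalogs.

The error model is i.i.d. per base: deletion 2.1%, mismatch 1.7%,
insertion 1.7% by default (midpoints of the rates reported for the R9.4
chemistry: deletions 1.6–2.7%, mismatches 1.2–2.2%, insertions 1.1–2.4%).
Each rate is a per-truth-base *marginal*: the mismatch draw is conditioned
on surviving deletion and insertions are independent of deletion, so
planted event counts are exactly binomial at the stated rates. Truth
coordinates are carried through the edits, not re-discovered.
`measure_error_rates` re-estimates the three rates by global (edlib)
alignment; with only deletions active this is provably exact, while with
all channels on, adjacent deletion+insertion pairs are
alignment-degenerate with substitutions, so alignment-based rates agree
with planted counts only to a few percent relative — the tests check the
exact planted counts against the binomial oracle and the alignment
re-estimate at that looser tolerance. The model has no homopolymer or
sequence-context bias and no quality strings; passing tests therefore
demonstrate robustness to aggregate indel/mismatch load, not to
context-dependent nanopore artifacts, chimeras, or adapter sequence.

## Problem sizes and determinism

The test suite and acceptance script size their simulations so the whole
battery completes in well under a minute of compute per property: 1,000
reads for the zero-error round trip and the forbidden-combination scan,
700 reads for the recall/precision property (recall and precision ≥0.95
per composition class for arrays of ≥30 monomers at default error rates),
1,000 × 10 kb reads for the deletion-rate calibration, ≥10⁴ monomers for
the variant-fraction recovery, and exhaustive enumeration over all 4⁶+4⁷
monomers for the recombinant model. Every stochastic step takes an
explicit seed; the analysis path itself contains no randomness, so a rerun
with the same configuration is byte-identical.

## Known limitations

* Boundaries on real (errored) data are accurate to about two monomers;
  the 95th percentile of boundary error at default rates is ≤14 bp.
* The consensus engine is not a scoring-compatible reimplementation of
  TRF or YASS; periods and unit counts can shift slightly under different
  alignment weights.
* Monomer classes are assigned per best-matching catalog entry; a monomer
  equidistant from two families goes to the tie-break winner rather than
  being flagged ambiguous.
* Table-level comparisons against the deposited libraries are provided as
  an optional scripted experiment (`telarray fetch-zenodo` + `telarray
  run`), not as part of the test battery: the inputs are multi-GB and the
  published per-library counts are sensitive to scan parameters.
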