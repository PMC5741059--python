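# Methods

`svbreakend` calls structural variant (SV) breakpoints from coordinate-sorted
short-read alignments by combining three evidence classes — split reads (SR),
discordant read pairs (DP) and break-end assemblies — under a single
probabilistic score, and reporting junctions as VCFv4.2 break-end (BND)
records.  This note documents the model, the tunable parameters, the
synthetic-data generator, and the numerical and design choices.

## Evidence model

**Library metrics.** A first pass over each input file collects the empirical
fragment-size distribution (outermost-base span of forward–reverse
inward-facing same-contig pairs, recomputed from the alignments rather than
TLEN), the soft-clip length distribution, the CIGAR insertion/deletion length
distributions, and read/pair counts.  Concordant fragment-size bounds are the
order statistics of the central `concordance_percentile` mass (default 0.995,
i.e. the 0.25 % and 99.75 % order statistics), so at most `1 − 0.995` of
training pairs fall outside them.  Two background rates are estimated:
`p_d`, the chimeric-fragment rate, is the fraction of both-mapped pairs whose
inferred fragment size deviates from the median by more than 10 median
absolute deviations (pairs with wrong orientation or split across contigs are
counted as chimeric); `p_u` is the fraction of pairs with exactly one read
unmapped.  Duplicate, secondary and supplementary alignments are excluded
from all metrics.

**Extraction.** Reads are classified, non-exclusively, as soft-clipped
(CIGAR S), indel-containing (CIGAR I/D), discordant pair (both mapped, but
fragment size outside the concordant bounds, wrong orientation, or different
contigs), or one-end anchor (exactly one read of the pair mapped).  Pairs
with both reads unmapped are unused.  Soft clips shorter than 4 bp or whose
clipped bases average base quality below 5 are dropped as adapter/quality
artifacts.  Mate-pair (outward-facing) libraries are not supported.

**Split-read identification.** Clipped bases are realigned to the reference;
a unique placement with mapping quality ≥ `min_realign_mapq` (default 10)
turns the soft clip into a split read.  The default realigner is internal:
an exact 12-mer index over the reference proposes candidate windows, each
window is scored with Smith–Waterman, and the mapq-equivalent is
`min(60, 4·(best − second best))`, with 60 when no competing placement
explains the same query bases.  Any aligner exposing `align(query) -> hit`
can be substituted.  Indel-containing reads are treated as split reads
joining the two sides of the indel.

## Scoring

Every piece of evidence is scored as the Phred-scaled probability
`Q = −10·log10 Pr(r)` of arising from its mapped locations *without* an SV.
With `M` the event that the mapping is correct,

    Pr(r) = Pr(M)·Pr(r|M) + (1 − Pr(M))·1,
    Pr(M) = (1 − 10^(−mapq_a/10)) · (1 − 10^(−mapq_b/10)),

single-locus evidence using only `mapq_a`.  `Pr(r|M)` is the library's own
capacity to produce the observation without an SV: for split reads the upper
tail mass of the soft-clip length distribution at the clip length observed
before split-read identification; for indel reads the same with the matching
I/D length distribution; for read pairs
`p_d + (1 − p_d)·P_rp(ifs)`, where `P_rp` is the two-sided tail mass of the
fragment-size distribution about its median (a density would make common
fragment sizes look like SV support, so tail mass is used — the same
convention as the clip/indel distributions).  Pairs with no defined fragment
size (different contigs, wrong orientation) keep only the `p_d` term;
one-end anchors substitute `p_u` for `p_d` and have no fragment term.
Empirical masses are floored at `1/(2n)` (half a pseudo-count) so unseen
values cannot produce infinite scores, and all scores are capped at
`q_max = 100` because the formulas diverge for perfect qualities.

Assemblies are scored through their constituent reads: soft clips are
promoted to split reads and one-end anchors to discordant pairs, each is
rescored with the assembly's anchored mapping quality (the maximum
constituent mapq) and unanchored mapping quality (the contig realignment
mapq), and the assembly score is the maximum promoted constituent score — a
deliberate approximation that avoids multiplying hundreds of correlated
per-read terms.

## Positional de Bruijn graph assembly

Graph nodes are `(position, k-mer)` pairs; nodes connect iff positions differ
by one and the k-mers overlap by k−1, so the graph is acyclic and
maximal-weight paths are computable in polynomial time by position-ordered
dynamic programming.  Node weight is the (integer-rounded) sum of supporting
k-mer weights,

    w(r,i) = −10·log10(1 − (1 − 10^(−mapq/10)) · Π_j (1 − 10^(−baseq_j/10))),

rounding making aggregation order-independent and tests exact.  A node is
*anchored* when all k bases are reference-aligned in some supporting read.
k-mers containing N are skipped rather than expanded.

Placement rules: clipped reads are placed once, at the positions implied by
full ungapped mapping projected from the clip-side alignment boundary;
split/indel reads act as two independent clipped reads; a discordant read is
placed, unanchored, at every start position at which the pair would be
concordant given the mate's anchor and the concordant bounds (closed-interval
arithmetic: mate first base `a`, fragment `f ∈ [lo, hi]`, read length `L` ⇒
starts `a+lo−L … a+hi−L`); a one-end anchor contributes its mapped read once
(anchored) and its unmapped mate across the analogous interval.  Break-ends
opening rightwards assemble on a forward graph; leftward break-ends on a
backward graph built by coordinate reflection (`pos → −pos`, sequence
reverse-complemented) so one path-calling core serves both directions.

**Error correction** collapses a path into a parallel path when it weighs
less, differs by fewer than `max_base_diff = 2` bases, and is either a simple
bubble (same length, same start and end node) or a terminal leaf sharing one
endpoint, considering only paths shorter than twice the read length.
Candidate alternates are found breadth-first with per-node memoization of the
best partial path (node positions make the search depth unambiguous, keeping
traversal polynomial); leaf collapse runs before bubble popping and nodes are
visited in deterministic `(position, k-mer)` order.  Merging transfers weight
and support node-by-node, so total graph weight is conserved.

**Contig calling** repeats: find the maximal-weight path of supported
unanchored nodes (paths with an anchored flank are preferred to unflanked
ones; ties break to the lexicographically smallest end node), extend into
flanking anchored nodes until the anchored length exceeds both the maximum
read length and the unanchored length, truncate by k-mer chaining, emit, and
remove every supporting read from the whole graph — each read (strictly,
each evidence piece; a read clipped at both ends contributes one independent
piece per direction) supports at most one contig.  Iteration ends when no
supported unanchored k-mer remains.  Contigs with fewer than
`min_support = 3` reads, unflanked contigs shorter than the read length, and
contigs longer than `max_contig_len = 2·(concordant_hi + max_read_length)`
are filtered; their reads are still consumed.

**Truncation.** A read placed over a position window with a repeated k-mer
lets the maximal path loop through the repeat (a 6 bp read placeable at five
starts can spell a 10 bp contig).  Each supporting read is therefore aligned
to the contig placement with the greatest number of matching k-mers (ties
toward the truncation-start side), the graph transitions its k-mer chain
spells there are marked, and the contig is re-called as the maximal-weight
path over marked transitions only — operationally, the path is cut at the
first transition no constituent read supports, and the cut tail is replaced
by the read-supported continuation when one exists.  Truncation is attempted
from both contig ends; the heavier result is kept, preferring paths that
retain anchored nodes.  This supported-transition formulation is what makes
the repeated-k-mer case collapse back to the read itself rather than merely
to its longest prefix.

**Streaming.** Because a read only influences node positions within its own
placement span, any position gap wider than the widest span plus one k-mer
separates subgraphs sharing no nodes or edges.  The streaming assembler makes
a single in-order pass over placements, assembling and flushing each
completed subgraph before loading the next, so memory is bounded by the
densest subgraph and output is exactly equal to whole-graph assembly (this
equivalence is tested on randomized fixtures).  The default execution path
at desk scale is this chunked streaming; whole-graph assembly of a region is
the reference implementation it is tested against.

## Realignment and calling

Assembled contigs are realigned in junction orientation.  A contig whose
full length aligns to the reference is indel-spanning evidence if the
alignment contains I/D operations and is discarded as a false positive
otherwise.  Otherwise the anchored flank is realigned by Smith–Waterman in a
tight window around the expected anchor (the whole-contig alignment can latch
onto the partner segment when the junction partner is nearby), fixing the
break-end position, and the residue is placed by the realigner; soft clip
left by that placement is realigned recursively up to depth 4, emitting one
piece of breakpoint evidence per junction the contig spans (compound
rearrangements).  Unplaceable residue becomes a single break-end record.
Contigs with no anchored bases (pure read-pair assemblies) take the
breakpoint interval covered by the greatest number of supporting pair
rectangles, the widest such interval on ties.

Breakpoint evidence is the tuple `(s_l, e_l, s_h, e_h, d_l, d_h, w)`.
Split-read and assembly junction intervals are widened by the exact
microhomology so evidence aligned to either edge of a homologous junction
coalesces.  A discordant pair contributes the bounding rectangle of its
fragment-size constraint: for a '+' break-end from a read spanning
`[r1, r2]` with mate length `m`, the interval `[r2, r1 + hi − 1 − m]`
(mirrored for '−'); the lower fragment bound is ignored in the rectangle
(it rarely binds and keeps the region axis-aligned).

Within each directional subset (`d_l`, `d_h`, contig pair), evidence
rectangles have the Helly property, so maximal cliques are maximal
point-stabbing sets; they are enumerated by an in-order sweep over interval
start events, each clique recognised at its core corner
`(max s_l, max s_h)`, with an explicit maximality check against outside
rectangles (the exhaustive subset enumerator is kept as a test oracle).
A variant's provisional score is its clique's summed evidence; a second
greedy pass assigns each evidence item to the highest-scoring clique it
supports (ties to the genomically first variant), quality is recomputed from
assigned evidence only, and empty variants are dropped — total assigned
weight is conserved.

**Annotation.** Calls holding an exact junction (from assembly, preferred,
or a split read) get exact microhomology by sliding the junction while both
sides match the reference; the nominal position is the homology centre
(floored toward the lower coordinate for even lengths), CIPOS spans the
homology interval, and untemplated inserted bases go into the BND ALT allele
and an `SVINS` INFO field.  Inexact homology (`IHOMPOS`) extends each
break-end across the junction by gapless scored extension (match +1,
mismatch −4, best-prefix score, X-drop 40) within a ±300 bp window, computed
per break-end and reported as the merged interval; it always contains the
exact interval.  DP-only calls keep their clique core as CIPOS and omit the
homology fields.

**Confidence.** A call is HIGH iff its quality is at least
`high_qual_threshold` (default 500) *and* it has assembly support at both
break-ends; all other calls are retained as LOW (FILTER `LOW_QUAL`) for
analyses needing sensitivity.  Multi-sample inputs share evidence for
assembly and clique formation; support is reported per category
(`CAT_SUPPORT`), with no somatic test applied.

## Parameters

| parameter | default | units | why |
| --- | --- | --- | --- |
| `k` | 25 | bp | long enough to be unique in desk-scale genomes, short enough for 36 bp reads; configurable 4–32 |
| `min_support` | 3 | reads | single- and two-read contigs are dominated by artifacts |
| `concordance_percentile` | 0.995 | mass | central fragment-size mass considered concordant |
| `min_realign_mapq` | 10 | Phred | unique-realignment threshold for split reads and contig residues |
| `q_max` | 100 | Phred | score cap; the model diverges at perfect qualities |
| mass floor | 1/(2n) | prob. | half pseudo-count for unseen lengths/sizes |
| SW scores | +1/−4, gap −6 −1/bp | — | bwa-like; gap of length L costs open + L·extend |
| `max_base_diff` | 2 | bases | error-correction merge tolerance (strictly fewer) |
| `max_realign_depth` | 4 | junctions | compound realignment recursion limit |
| `high_qual_threshold` | 500 | Phred | HIGH-confidence quality floor |
| `ihom_window` | 300 | bp | inexact-homology search window per side |
| clip filters | ≥ 4 bp, mean baseq ≥ 5 | — | suppress adapter/quality artifacts |
| MAPQ 255 | treated as 60 | Phred | the model needs a finite mapping probability |

## Synthetic data

The generator emulates a small, repeat-free genome study: uniform random
reference at a target GC; non-overlapping planted events
(DEL/INS/INV/DUP and an unbalanced translocation, each with truth junctions
and homology derived from the reference); paired-end reads with normal
fragment sizes (default 2×100 bp, 300 ± 30 bp), uniform per-base substitution
error (default 1 %), and base qualities at the Phred equivalent of the error
rate with ±5 jitter — enough variation to exercise the weight formula without
a full quality model.  Alignments are derived from the truth segment map
rather than a real aligner: junction-spanning reads are emitted soft-clipped
at the reference position a correct aligner would choose (reference-colinear
segment boundaries, e.g. the second copy of a tandem duplication flowing into
downstream sequence, are merged so no artifact clips arise), reads inside
novel insertions are emitted unmapped with a mapped mate, and MAPQ is a
constant 60.

What this does *not* emulate — and hence what passing tests do not show about
real data: aligner-specific clip placement and MAPQ behaviour, repeats and
low-complexity regions (so realignment ambiguity is rare), indel
sequencing errors, GC and coverage bias, duplicates, and multi-library
fragment-size mixtures.  The end-to-end tests use a 100 kb two-contig genome
(60 kb + 40 kb) with a heterozygous 500 bp deletion, 1 kb tandem duplication,
2 kb inversion and one translocation at 60× coverage; the streaming
equivalence suite uses twenty 100 kb fixtures at 6× (subgraph structure, not
depth, is what that contract exercises).  These sizes are the package's
chosen desk-scale study conditions.

## Numerical choices and degenerate inputs

Coordinates are 1-based, fully closed, matching SAM/VCF; break-end
direction '+' means the retained sequence ends at the position, '−' that it
starts there.  Node weights are integers (rounded per k-mer contribution) so
aggregation is order-independent.  All tie-breaks are deterministic:
maximal-path ends and anchored extensions prefer the lexicographically
smallest `(position, k-mer)`; greedy assignment prefers the genomically
first variant; read placements in truncation break ties toward the
truncation-start side.  Degenerate cases: an empty alignment file is an
error; a paired library with no mapped pairs disables pair-based evidence
rather than failing; a constant fragment-size library has MAD 0, making any
deviating pair chimeric; reads shorter than k are skipped with a warning;
an empty graph assembles to an empty contig list; zero calls still produce a
valid header-only VCF.

## Limitations

Calling stops at breakpoints: no genotyping, copy-number integration or
somatic statistics.  DP-only variants are interval-resolved and never reach
HIGH confidence.  The assembly score is a maximum, not a sum, over
constituents, so deep assemblies are conservatively scored.  The internal
realigner assumes the reference fits in memory and indexes exact seeds, so
it is not tolerant of highly diverged or heavily repetitive targets; for
such data an external aligner adapter should replace it.  Only one
translocation per simulated genome is supported by the generator, and it is
unbalanced.  Execution is single-threaded.
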