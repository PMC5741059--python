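# svbreakend

Desk-scale structural variant (SV) break-end calling from short-read
alignments.  `svbreakend` detects genomic rearrangements — deletions,
duplications, inversions, translocations and compound events — by combining
three evidence classes from coordinate-sorted SAM/BAM input:

* **split reads** (soft-clipped reads whose clipped bases realign uniquely
  elsewhere),
* **discordant read pairs** (unexpected fragment size, orientation, or
  contig), and
* **break-end assemblies** from a *positional de Bruijn graph* — a de Bruijn
  graph whose nodes are `(position, k-mer)` pairs, which makes the graph
  acyclic and lets maximal-weight contigs be called in polynomial time.

Evidence is scored by the Phred-scaled probability of arising without an SV,

    Q = −10·log10 Pr(r),   Pr(r) = Pr(M)·Pr(r|M) + (1 − Pr(M)),

where `Pr(M)` comes from the mapping qualities and `Pr(r|M)` from the
library's own empirical distributions (soft-clip lengths, indel-operation
lengths, fragment sizes, chimera rate `p_d`, one-end-unmapped rate `p_u`).
Assembly graph nodes are weighted by the joint base-call/mapping probability

    w(r,i) = −10·log10(1 − (1 − 10^(−mapq/10)) · Π_j (1 − 10^(−baseq_j/10))).

Breakpoints are called as maximal cliques of evidence rectangles
`[s_l,e_l] × [s_h,e_h]` per break-end direction pair, each evidence item is
greedily assigned to the best variant it supports, and calls are annotated
with breakpoint microhomology (HOMSEQ/HOMLEN/CIPOS), inexact homology
(IHOMPOS) and untemplated insertions, then written as VCFv4.2 break-end
(BND) record pairs.  High-confidence calls require assembly support from
both break-ends.

The package is aimed at method development, teaching and simulation studies
at desk scale (kilobase–megabase genomes, in-memory references); it is a
library first, with a thin CLI.  A built-in generator produces random
references, planted SVs with exact truth (junctions, homology), and
simulated paired-end reads, so everything is testable without downloads.

See `docs/methods.md` for the full model description and parameter table.

## Worked example

`examples/01_simulate_and_call.py` plants a heterozygous 400 bp deletion in a
20 kb random genome, simulates 36× 2×100 bp reads (fragment 300 ± 30, 1 %
error), and runs the caller:

```
planted DEL: chr1:9999(+) -> chr1:10400(-)
simulated 3564 read pairs -> .../reads.sam

11 breakpoints called (.../calls.vcf); strongest first:
  chr1:9998(+) -> chr1:10399(-)  QUAL=275 LOW assembly_sides=2 {'DP': 8, 'SR': 13, 'ASSEMBLY': 2}
  chr1:485(-) -> chr1:1005(+)  QUAL=19 LOW assembly_sides=0 {'DP': 1}
  chr1:14615(-) -> chr1:15129(+)  QUAL=19 LOW assembly_sides=0 {'DP': 1}
```

The top call is the planted junction: 13 split reads, 8 discordant pairs and
a break-end contig assembled on *each* side (`assembly_sides=2`) sum to
QUAL 275, and the nominal position sits one base left of the planted one
because the junction has one base of microhomology and the call is centred
on the homology interval.  The remaining single-pair calls are the expected
background of fragment-size outliers; they are retained (FILTER `LOW_QUAL`)
for high-sensitivity uses and are trivially separable by QUAL.

The other examples are one capability each: `02` builds the positional graph
for a repeated-k-mer read by hand and shows k-mer-chaining truncation
rescuing the misassembled loop; `03` walks the scoring model on a toy
library; `04` shows clique enumeration and greedy assignment on four
evidence rectangles.

## Command line

```sh
svbreakend simulate -o sim                      # genome + reads + truth BEDPE
svbreakend metrics sim.sam                      # library metrics as JSON
svbreakend call sim.sam -r sim.fasta -o out.vcf # the full caller
svbreakend assemble sim.sam -r sim.fasta        # break-end contigs only
```

`call` exposes `--k`, `--min-support`, `--concordance-percentile`,
`--min-realign-mapq`, `--high-qual-threshold`, `--ihom-window` and per-input
`--category` labels for multi-sample calling.

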