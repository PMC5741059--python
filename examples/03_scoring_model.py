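"""Scoring evidence: the Phred-scaled probability of 'no SV here'.

Each piece of evidence is scored as Q = -10 log10 Pr(r), the probability of
observing it from the mapped locations without any structural variant:
mapping errors (from MAPQ) and the library's own background of soft clips
and fragment-size outliers both explain evidence away.
"""

from svbreakend.evidence import EvidenceKind, Locus, ReadEvidence
from svbreakend.metrics import EmpiricalDistribution, LibraryMetrics
from svbreakend.scoring import kmer_weight, score_read_pair, score_split_read

# a toy library: soft clips are short and rare, fragments ~300 bp
lib = LibraryMetrics(library_id="toy")
for length, count in [(1, 500), (2, 300), (5, 100), (10, 40), (30, 8), (50, 2)]:
    lib.softclip_len_dist.add(length, count)
lib.fragment_size_dist = EmpiricalDistribution()
for size, count in [(280, 100), (290, 250), (300, 400), (310, 250), (320, 100)]:
    lib.fragment_size_dist.add(size, count)
lib.p_d = 0.002  # chimeric fragment rate
lib.p_u = 0.01

sr = ReadEvidence(
    kind=EvidenceKind.SPLIT_READ, read_id="r1", library_id="toy",
    category="default", locus_a=Locus("chr1", 10_000, "+"),
    locus_b=Locus("chr1", 14_000, "-"), l_sc=50, mapq_a=60, mapq_b=60,
)
s = score_split_read(sr, lib)
print(f"50 bp split read, both MAPQ 60:    Q = {s.q:6.2f}"
      f"  (Pr(M)={s.pr_mapping:.4f}, Pr(r|M)={s.pr_given_mapped:.2e})")

sr.mapq_b = 3  # clipped bases realign ambiguously
print(f"same split read, partner MAPQ 3:   Q = {score_split_read(sr, lib).q:6.2f}")

dp = ReadEvidence(
    kind=EvidenceKind.DISCORDANT_PAIR, read_id="r2", library_id="toy",
    category="default", locus_a=Locus("chr1", 10_000, "+"),
    ifs=900, mapq_a=60, mapq_b=60,
)
print(f"discordant pair, fragment 900 bp:  Q = {score_read_pair(dp, lib).q:6.2f}")
dp.ifs = 310
print(f"same pair at fragment 310 bp:      Q = {score_read_pair(dp, lib).q:6.2f}")

w = kmer_weight(mapq=60, base_quals=[30] * 25, start=0, k=25)
print(f"\nassembly k-mer weight (k=25, MAPQ 60, baseq 30): w = {w:.2f}")
print("low-MAPQ or low-quality bases shrink a k-mer's contribution to the")
print("assembly graph; a MAPQ 0 read contributes nothing at all:",
      kmer_weight(0, [30] * 25, 0, 25))
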