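"""Breakpoint calling as maximal cliques of evidence rectangles.

Each piece of breakpoint evidence supports an interval on the lower and on
the higher break-end — a rectangle.  Evidence items mutually support the
same breakpoint when their rectangles pairwise overlap (and directions
match), so candidate variants are maximal cliques of the rectangle overlap
graph; shared evidence is then greedily assigned to the highest-scoring
variant it supports.
"""

from svbreakend.breakpoints import BreakpointEvidence
from svbreakend.calling import enumerate_maximal_cliques, greedy_assign


def make(s_l, e_l, s_h, e_h, w):
    return BreakpointEvidence(
        contig_l="chr1", s_l=s_l, e_l=e_l, d_l="+",
        contig_h="chr1", s_h=s_h, e_h=e_h, d_h="-",
        w=w, origin="DP",
    )


evidence = [
    make(100, 150, 900, 950, w=30),   # variant A
    make(120, 160, 920, 960, w=25),   # variant A
    make(140, 210, 940, 1010, w=10),  # ambiguous: overlaps A and B
    make(200, 250, 1000, 1050, w=20), # variant B
]

cliques = enumerate_maximal_cliques(evidence)
print("maximal cliques (before assignment):")
for c in cliques:
    print(f"  members={list(c.members)} core={c.core} provisional weight={c.weight:.0f}")

calls = greedy_assign(cliques, evidence)
print("\ncalls after greedy assignment (each item counted once):")
for call in calls:
    print(
        f"  {call.contig_l}:{call.pos_l}({call.d_l}) -> "
        f"{call.contig_h}:{call.pos_h}({call.d_h})  QUAL={call.qual:.0f}"
        f"  n_evidence={len(call.evidence)}"
    )
print("\nthe ambiguous item joined the heavier clique; total assigned weight")
print("equals the total evidence weight:", sum(c.qual for c in calls))
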