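"""Variant calling by maximal-clique enumeration over breakpoint evidence.

Evidence items mutually support a breakpoint when their directional subsets
match and their (lower, higher) break-end rectangles pairwise overlap.
Axis-parallel rectangles have the Helly property, so every clique has a
common intersection point and maximal cliques are exactly the maximal
point-stabbing sets; they are enumerated in a single in-order sweep over
interval start events per directional subset (each maximal clique is
recognised at its core corner ``(max s_l, max s_h)``).  A variant's score is
the sum of its supporting evidence scores; because evidence can fall in
several cliques, a second greedy pass assigns each item to the highest-
scoring variant it supports and variant quality is recomputed from assigned
evidence only.

Calls with an exact junction are annotated with breakpoint microhomology
(HOMSEQ/HOMLEN/CIPOS; the nominal position is the centre of the homology),
inexact homology (IHOMPOS), and untemplated inserted sequence.  High
confidence requires assembly support at both break-ends plus a quality
threshold; low-confidence calls are retained for high-sensitivity analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .breakpoints import BreakpointEvidence
from .homology import Junction, exact_homology, homology_intervals, inexact_homology

HIGH_QUAL_THRESHOLD = 500.0


@dataclass
class Clique:
    members: tuple[int, ...]  # indices into the evidence list
    core: tuple[int, int, int, int]  # (max s_l, min e_l, max s_h, min e_h)
    subset: tuple[str, str, str, str]
    weight: float


@dataclass
class VariantCall:
    contig_l: str
    pos_l: int
    d_l: str
    contig_h: str
    pos_h: int
    d_h: str
    qual: float
    cipos_l: tuple[int, int] = (0, 0)
    cipos_h: tuple[int, int] = (0, 0)
    evidence: list[BreakpointEvidence] = field(default_factory=list)
    support_breakdown: dict = field(default_factory=dict)
    category_breakdown: dict = field(default_factory=dict)
    assembly_sides: int = 0
    homseq: str = ""
    homlen: int = 0
    ihompos: tuple[int, int] | None = None
    untemplated_seq: str = ""
    exact: bool = False
    confidence: str = "LOW"

    @property
    def key(self) -> tuple:
        return (self.contig_l, self.pos_l, self.contig_h, self.pos_h, self.d_l, self.d_h)


def _stab(group, x0: int, y0: int) -> tuple[int, ...]:
    return tuple(
        i
        for i, bp in group
        if bp.s_l <= x0 <= bp.e_l and bp.s_h <= y0 <= bp.e_h
    )


def enumerate_maximal_cliques(
    evidence: list[BreakpointEvidence],
) -> list[Clique]:
    """All maximal cliques of mutually overlapping evidence rectangles."""
    by_subset: dict[tuple, list[tuple[int, BreakpointEvidence]]] = {}
    for i, bp in enumerate(evidence):
        by_subset.setdefault(bp.subset, []).append((i, bp))
    out: list[Clique] = []
    for subset, group in sorted(by_subset.items()):
        seen: set[tuple[int, ...]] = set()
        xs = sorted({bp.s_l for _, bp in group})
        for x0 in xs:
            active = [(i, bp) for i, bp in group if bp.s_l <= x0 <= bp.e_l]
            if not active:
                continue
            for y0 in sorted({bp.s_h for _, bp in active}):
                members = _stab(active, x0, y0)
                if not members:
                    continue
                ms = [evidence[i] for i in members]
                if max(bp.s_l for bp in ms) != x0 or max(bp.s_h for bp in ms) != y0:
                    continue  # not this clique's core corner; found elsewhere
                if members in seen:
                    continue
                seen.add(members)
                core = (
                    x0,
                    min(bp.e_l for bp in ms),
                    y0,
                    min(bp.e_h for bp in ms),
                )
                # maximality: no outside rectangle overlaps the core both ways
                maximal = True
                mset = set(members)
                for i, bp in group:
                    if i in mset:
                        continue
                    if (
                        bp.s_l <= core[1]
                        and bp.e_l >= core[0]
                        and bp.s_h <= core[3]
                        and bp.e_h >= core[2]
                    ):
                        maximal = False
                        break
                if maximal:
                    out.append(
                        Clique(
                            members=members,
                            core=core,
                            subset=subset,
                            weight=sum(bp.w for bp in ms),
                        )
                    )
    return out


def greedy_assign(
    cliques: list[Clique], evidence: list[BreakpointEvidence]
) -> list[VariantCall]:
    """Assign each evidence item to the highest-scoring clique it supports.

    Ties break toward the genomically first variant (lower break-end, then
    higher).  Variants left without assigned evidence are dropped; total
    assigned weight is conserved.
    """
    supporting: dict[int, list[Clique]] = {}
    for cl in cliques:
        for i in cl.members:
            supporting.setdefault(i, []).append(cl)
    assigned: dict[tuple, list[int]] = {}
    for i, cls in supporting.items():
        best = min(cls, key=lambda c: (-c.weight, _order_key(c)))
        assigned.setdefault(id(best), []).append(i)
    by_id = {id(c): c for c in cliques}
    calls: list[VariantCall] = []
    for cid, idxs in assigned.items():
        cl = by_id[cid]
        members = [evidence[i] for i in idxs]
        qual = sum(bp.w for bp in members)
        if qual <= 0 and not members:
            continue
        contig_l, contig_h, d_l, d_h = cl.subset
        breakdown: dict[str, dict] = {}
        cats: dict[str, dict] = {}
        for bp in members:
            o = breakdown.setdefault(bp.origin, {"count": 0, "qual": 0.0})
            o["count"] += 1
            o["qual"] += bp.w
            c = cats.setdefault(bp.category, {"count": 0, "qual": 0.0})
            c["count"] += 1
            c["qual"] += bp.w
        sides = {bp.assembly_side for bp in members if bp.origin == "ASSEMBLY"}
        sides.discard(None)
        call = VariantCall(
            contig_l=contig_l,
            pos_l=(cl.core[0] + cl.core[1]) // 2,
            d_l=d_l,
            contig_h=contig_h,
            pos_h=(cl.core[2] + cl.core[3]) // 2,
            d_h=d_h,
            qual=qual,
            cipos_l=(cl.core[0], cl.core[1]),
            cipos_h=(cl.core[2], cl.core[3]),
            evidence=members,
            support_breakdown=breakdown,
            category_breakdown=cats,
            assembly_sides=len(sides),
        )
        calls.append(call)
    calls.sort(key=lambda c: c.key)
    return calls


def _order_key(cl: Clique) -> tuple:
    return (cl.subset[0], cl.core[0], cl.subset[1], cl.core[2])


def _slide(pos: int, direction: str, low_side: bool, steps: int) -> int:
    """Genome position after sliding the junction ``steps`` rightward."""
    if low_side:
        return pos + steps if direction == "+" else pos - steps
    return pos + steps if direction == "-" else pos - steps


def annotate_homology(
    call: VariantCall, reference: dict, max_ihom_window: int = 300
) -> VariantCall:
    """Fill homology fields; requires an exact-junction evidence item.

    The best exact evidence (assembly preferred over split reads, then
    weight) provides the junction; the nominal position moves to the centre
    of the exact homology (floor toward the lower coordinate when even).
    Calls with no exact junction keep their clique-interval CIPOS.
    """
    exact = [bp for bp in call.evidence if bp.exact and bp.nominal_l is not None]
    if not exact:
        call.exact = False
        return call
    best = max(exact, key=lambda bp: ((bp.origin == "ASSEMBLY"), bp.w))
    j = Junction(
        contig_l=call.contig_l,
        pos_l=best.nominal_l,
        dir_l=call.d_l,
        contig_h=call.contig_h,
        pos_h=best.nominal_h,
        dir_h=call.d_h,
        untemplated_seq=best.untemplated_seq,
    )
    left, right, homseq = exact_homology(reference, j, max_ihom_window)
    shift = (right - left) // 2
    pos_l = _slide(j.pos_l, call.d_l, True, shift)
    pos_h = _slide(j.pos_h, call.d_h, False, shift)
    low_iv, high_iv = homology_intervals(reference, j, max_ihom_window)
    ileft, iright = inexact_homology(reference, j, max_ihom_window)
    if call.d_l == "+":
        ihom_low = (j.pos_l - ileft, j.pos_l + iright)
    else:
        ihom_low = (j.pos_l - iright, j.pos_l + ileft)
    if call.d_h == "-":
        ihom_high = (j.pos_h - ileft, j.pos_h + iright)
    else:
        ihom_high = (j.pos_h - iright, j.pos_h + ileft)
    call.pos_l, call.pos_h = pos_l, pos_h
    call.homlen = left + right
    call.homseq = homseq
    call.cipos_l = (low_iv[0] - pos_l, low_iv[1] - pos_l)
    call.cipos_h = (high_iv[0] - pos_h, high_iv[1] - pos_h)
    # per-break-end inexact homology, reported merged relative to the call
    rel_low = (ihom_low[0] - pos_l, ihom_low[1] - pos_l)
    rel_high = (ihom_high[0] - pos_h, ihom_high[1] - pos_h)
    call.ihompos = (min(rel_low[0], rel_high[0]), max(rel_low[1], rel_high[1]))
    call.untemplated_seq = best.untemplated_seq
    call.exact = True
    return call


def classify_confidence(
    call: VariantCall, qual_threshold: float = HIGH_QUAL_THRESHOLD
) -> str:
    """HIGH requires assembly support from both break-ends and high quality."""
    call.confidence = (
        "HIGH" if call.qual >= qual_threshold and call.assembly_sides == 2 else "LOW"
    )
    return call.confidence
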