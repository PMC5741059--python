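"""Breakpoint microhomology and inexact homology detection.

Sequence homology between the two sides of a breakpoint makes the junction
position ambiguous: the breakpoint can be slid across the homologous bases
without changing the derivative sequence.  The exact microhomology interval
is found by sliding the junction while both sides keep matching the
reference; the nominal call position is the centre of the homology (floored
toward the lower coordinate for even lengths).  Inexact homology additionally
tolerates mismatches: each side is extended across the break by gapless
scored extension (match/mismatch, best-prefix score), bounded by a window
(default 300 bp per side).  The inexact interval always contains the exact
one, since a perfect-match extension scores maximally.
"""

from __future__ import annotations

from dataclasses import dataclass

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


@dataclass(frozen=True)
class Junction:
    """A single-base-resolution breakpoint: low side (contig_l, pos_l, dir_l)
    joined to high side (contig_h, pos_h, dir_h), read low -> high."""

    contig_l: str
    pos_l: int
    dir_l: str
    contig_h: str
    pos_h: int
    dir_h: str
    untemplated_seq: str = ""


def _base(ref: dict, contig: str, pos: int) -> str | None:
    seq = ref[contig]
    if 1 <= pos <= len(seq):
        return str(seq[pos - 1]).upper()
    return None


def _low_retained(ref, j: Junction, step: int) -> str | None:
    """Retained low-side base ``step`` positions before the break (1 = at it)."""
    if j.dir_l == "+":
        return _base(ref, j.contig_l, j.pos_l - (step - 1))
    b = _base(ref, j.contig_l, j.pos_l + (step - 1))
    return _COMP.get(b) if b else None


def _low_continuation(ref, j: Junction, step: int) -> str | None:
    """Reference base ``step`` positions past the break on the low side."""
    if j.dir_l == "+":
        return _base(ref, j.contig_l, j.pos_l + step)
    b = _base(ref, j.contig_l, j.pos_l - step)
    return _COMP.get(b) if b else None


def _high_first(ref, j: Junction, step: int) -> str | None:
    """``step``-th base of the high-side continuation (1 = first retained)."""
    if j.dir_h == "-":
        return _base(ref, j.contig_h, j.pos_h + (step - 1))
    b = _base(ref, j.contig_h, j.pos_h - (step - 1))
    return _COMP.get(b) if b else None


def _high_before(ref, j: Junction, step: int) -> str | None:
    """Reference base ``step`` positions before the high-side continuation."""
    if j.dir_h == "-":
        return _base(ref, j.contig_h, j.pos_h - step)
    b = _base(ref, j.contig_h, j.pos_h + step)
    return _COMP.get(b) if b else None


def exact_homology(ref: dict, j: Junction, max_len: int = 300) -> tuple[int, int, str]:
    """(bases the junction can slide left, slide right, homologous sequence).

    A junction with untemplated inserted sequence has no positional
    ambiguity: (0, 0, "").
    """
    if j.untemplated_seq:
        return 0, 0, ""
    right = 0
    while right < max_len:
        a = _low_continuation(ref, j, right + 1)
        b = _high_first(ref, j, right + 1)
        if a is None or b is None or a != b or a == "N":
            break
        right += 1
    left = 0
    while left < max_len:
        a = _low_retained(ref, j, left + 1)
        b = _high_before(ref, j, left + 1)
        if a is None or b is None or a != b or a == "N":
            break
        left += 1
    seq = "".join(
        _low_retained(ref, j, step) for step in range(left, 0, -1)
    ) + "".join(_low_continuation(ref, j, step) for step in range(1, right + 1))
    return left, right, seq


def inexact_homology(
    ref: dict,
    j: Junction,
    window: int = 300,
    match: int = 1,
    mismatch: int = -4,
) -> tuple[int, int]:
    """(left, right) inexact-homology extents by gapless scored extension."""

    def extend(side_a, side_b) -> int:
        score, best, best_at = 0, 0, 0
        for step in range(1, window + 1):
            a, b = side_a(step), side_b(step)
            if a is None or b is None:
                break
            score += match if a == b and a != "N" else mismatch
            if score > best:
                best, best_at = score, step
            if score < best - 40:  # X-drop
                break
        return best_at

    right = extend(
        lambda s: _low_continuation(ref, j, s), lambda s: _high_first(ref, j, s)
    )
    left = extend(
        lambda s: _low_retained(ref, j, s), lambda s: _high_before(ref, j, s)
    )
    return left, right


def homology_intervals(
    ref: dict, j: Junction, max_len: int = 300
) -> tuple[tuple[int, int], tuple[int, int]]:
    """Closed position intervals of the two break-ends under exact homology.

    Sliding the junction one base 'rightward' (in junction orientation) moves
    a '+' break-end up and a '-' break-end down in genome coordinates on the
    low side, and the reverse on the high side.
    """
    left, right, _ = exact_homology(ref, j, max_len)
    if j.dir_l == "+":
        low = (j.pos_l - left, j.pos_l + right)
    else:
        low = (j.pos_l - right, j.pos_l + left)
    if j.dir_h == "-":
        high = (j.pos_h - left, j.pos_h + right)
    else:
        high = (j.pos_h - right, j.pos_h + left)
    return low, high
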