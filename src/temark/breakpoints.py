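"""Indel breakpoint calling at similarity-block borders.

Given one orthologous locus pair, breakpoints are placed at the inner
borders of the outermost flanking similarity blocks (default thresholds
100 bp / 95% identity), indel lengths are the 1-based closed distance
between the 5' and 3' breakpoints, and tandem copy-number variation and
inversions are detected from self- and cross-comparison block patterns.

Junction-repeat ambiguity
-------------------------
When the two junction sides share an exact repeat (microhomology, a TSD,
or a long recombination repeat), the flanking anchors overlap on the
un-deleted genome by exactly that repeat length; the caller records the
overlap as ``ambiguity_width`` and reports leftmost-normalised
intervals, which makes recovered deletion lengths exact for junctions
with exactly conserved flanks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .homology import (DEFAULT_MIN_IDENTITY, DEFAULT_MIN_LENGTH,
                       SimilarityBlock, find_similarity_blocks,
                       self_repeat_blocks)

REMNANT_BOUND = 100      # bp; junction remnant above this suggests replacement
_N_WINDOW = 100          # bp; N-run within this of a breakpoint -> low confidence


def interval_length(start: int, end: int) -> int:
    """Length of a 1-based closed interval: end - start + 1."""
    if end < start:
        raise ValueError(f"end ({end}) < start ({start})")
    return end - start + 1


@dataclass
class IndelCall:
    """One called rearrangement between two orthologous loci.

    Intervals are 1-based closed in the coordinates of the supplied
    loci (plus any offset); degenerate intervals (end = start - 1,
    length 0) mark a side with no unique sequence at the junction.
    ``breakpoint5``/``breakpoint3`` give the last/first anchored base on
    (A, B) before normalisation.
    """

    locus_id: str
    a_interval: tuple[int, int]
    b_interval: tuple[int, int]
    a_length: int
    b_length: int
    rearrangement_type: str  # deletion_in_b | replacement | copy_number_variation | inversion | none
    breakpoint5: tuple[int, int]
    breakpoint3: tuple[int, int]
    ambiguity_width: int
    flags: list[str] = field(default_factory=list)
    blocks: list[SimilarityBlock] = field(default_factory=list)


@dataclass
class CNVCall:
    """Tandem copy-number variation call for one locus pair."""

    locus_id: str
    unit_interval_a: tuple[int, int] | None
    copies_a: int
    copies_b: int
    unit_identity: float
    details: dict = field(default_factory=dict)


def _shift(iv: tuple[int, int], off: int) -> tuple[int, int]:
    return (iv[0] + off, iv[1] + off)


def _n_run_near(seq: str, pos: int, window: int = _N_WINDOW) -> bool:
    lo = max(0, pos - 1 - window)
    return "N" in seq[lo : pos + window]


def _remnant_homologous_to_flanks(remnant: str, locus_a: str,
                                  a_interval: tuple[int, int],
                                  min_block: int, min_identity: float) -> bool:
    """Is a long B-side junction remnant homologous to the A flanking
    sequence around the indel (the signature of a deletion between long
    direct repeats, where one recombined copy remains in B)?"""
    s, e = a_interval
    flank_span = min(3 * len(remnant), 30000)
    left = locus_a[max(0, s - 1 - flank_span) : s - 1]
    right = locus_a[e : e + flank_span]
    covered = 0
    for ctx in (left, right):
        if len(ctx) < min_block:
            continue
        for b in find_similarity_blocks(remnant, ctx, min_block, min_identity):
            covered = max(covered, b.length)
    return covered >= 0.5 * len(remnant)


def call_indel(
    locus_a: str,
    locus_b: str,
    locus_id: str = "locus",
    a_offset: int = 1,
    b_offset: int = 1,
    min_block: int = DEFAULT_MIN_LENGTH,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    remnant_bound: int = REMNANT_BOUND,
) -> IndelCall:
    """Call the indel between two orthologous loci.

    Both loci must include flanking anchor sequence on each side of the
    variant.  Offsets give the genome coordinate of local position 1 so
    reported intervals are in genome coordinates.

    Classification: ``deletion_in_b`` when the A side exceeds the block
    minimum and the B junction remnant is short (or long but homologous
    to the A flanks, as for recombination between long repeats);
    ``replacement`` when both sides carry substantial unique sequence;
    ``inversion`` when the variant region is spanned by reverse-
    orientation blocks; ``none`` for identical loci.
    """
    off_a, off_b = a_offset - 1, b_offset - 1
    blocks = find_similarity_blocks(locus_a, locus_b, min_block, min_identity,
                                    both_strands=True)
    fwd = [b for b in blocks if b.orientation == "forward"]
    flags: list[str] = []
    if not fwd:
        return IndelCall(locus_id, (a_offset, a_offset - 1), (b_offset, b_offset - 1),
                         0, 0, "none", (0, 0), (0, 0), 0,
                         flags=["partial_no_anchor"], blocks=blocks)
    p = min(fwd, key=lambda b: (b.a_start + b.b_start, b.a_start))
    s = max(fwd, key=lambda b: (b.a_end + b.b_end, b.a_end))
    if p is s:
        cov_a = p.length / len(locus_a)
        t = "none" if cov_a > 0.9 else "none"
        f = [] if cov_a > 0.9 else ["partial_single_anchor"]
        pos_a, pos_b = p.a_end + off_a, p.b_end + off_b
        return IndelCall(locus_id, (pos_a + 1, pos_a), (pos_b + 1, pos_b), 0, 0, t,
                         (pos_a, pos_b), (p.a_start + off_a, p.b_start + off_b),
                         0, flags=f, blocks=blocks)

    amb_a = max(0, p.a_end - s.a_start + 1)
    amb_b = max(0, p.b_end - s.b_start + 1)
    shift = amb_a + amb_b
    a_iv = (p.a_end + 1 - shift, s.a_start - 1)
    b_iv = (p.b_end + 1 - shift, s.b_start - 1)
    a_len = max(0, a_iv[1] - a_iv[0] + 1)
    b_len = max(0, b_iv[1] - b_iv[0] + 1)

    # reverse blocks spanning the variant region -> inversion (blocks may
    # poke a few bases into the anchors through chance palindromic matches,
    # so coverage is measured by overlap, not containment)
    var_lo, var_hi = p.a_end + 1 - shift, s.a_start - 1 + shift
    rev_cover = sum(max(0, min(b.a_end, var_hi) - max(b.a_start, var_lo) + 1)
                    for b in blocks if b.orientation == "reverse")
    if rev_cover >= 0.5 * max(a_len, 1) and a_len > 0:
        rtype = "inversion"
    elif a_len == 0 and b_len == 0:
        rtype = "none"
    elif b_len <= remnant_bound and a_len > min_block:
        rtype = "deletion_in_b"
    elif b_len > remnant_bound and a_len > min_block and _remnant_homologous_to_flanks(
            locus_b[b_iv[0] - 1 : b_iv[1]], locus_a, a_iv, min_block, min_identity):
        rtype = "deletion_in_b"
        flags.append("long_homologous_remnant")
    elif a_len <= remnant_bound and b_len > min_block:
        rtype = "replacement"
        flags.append("insertion_in_b")
    elif a_len > remnant_bound and b_len > remnant_bound:
        rtype = "replacement"
    else:
        rtype = "none"

    for seq, pos in ((locus_a, p.a_end), (locus_a, s.a_start),
                     (locus_b, p.b_end), (locus_b, s.b_start)):
        if _n_run_near(seq, pos):
            if "n_near_breakpoint" not in flags:
                flags.append("n_near_breakpoint")

    return IndelCall(
        locus_id=locus_id,
        a_interval=_shift(a_iv, off_a), b_interval=_shift(b_iv, off_b),
        a_length=a_len, b_length=b_len, rearrangement_type=rtype,
        breakpoint5=(p.a_end + off_a, p.b_end + off_b),
        breakpoint3=(s.a_start + off_a, s.b_start + off_b),
        ambiguity_width=shift, flags=flags, blocks=blocks,
    )


def _self_copy_count(seq: str, min_block: int, min_identity: float):
    """(copies, unit_interval, identity) from off-diagonal self-repeats.

    Only *tandem* evidence counts: the off-diagonal block must span most
    of its own diagonal offset (the repeat unit), which distinguishes an
    adjacent duplication from a pair of short distant repeats.
    """
    blocks = [b for b in self_repeat_blocks(seq, min_block, min_identity)
              if b.orientation == "forward"
              and b.b_start > b.a_start
              and b.length >= 0.8 * (b.b_start - b.a_start)]
    if not blocks:
        return 1, None, 1.0
    best = max(blocks, key=lambda b: b.length)
    unit = best.b_start - best.a_start
    copies = 1 + max(1, round(best.length / unit))
    return copies, (best.a_start, best.a_start + unit - 1), best.identity


def detect_copy_number_variation(
    locus_a: str,
    locus_b: str,
    locus_id: str = "locus",
    min_block: int = DEFAULT_MIN_LENGTH,
    min_identity: float = DEFAULT_MIN_IDENTITY,
) -> CNVCall:
    """Tandem-repeat copy numbers on each genome from self dot plots.

    Unit borders are taken from the off-diagonal self-similarity blocks
    of the genome carrying more copies (the diagonal offset of the
    longest off-diagonal block is the unit length); the cross comparison
    provides a consistency check recorded in ``details``.
    """
    ca, unit_a, ident_a = _self_copy_count(locus_a, min_block, min_identity)
    cb, unit_b, ident_b = _self_copy_count(locus_b, min_block, min_identity)
    unit = unit_a if ca >= cb else unit_b
    ident = ident_a if ca >= cb else ident_b
    details: dict = {}
    if unit is not None:
        # consistency: some cross-alignment discontinuity border must fall
        # at a self-plot unit border
        cross = find_similarity_blocks(locus_a, locus_b, min_block, min_identity)
        borders = (unit[0], unit[0] - 1, unit[1], unit[1] + 1)
        deltas = [min(abs(edge - border) for border in borders)
                  for b in cross for edge in (b.a_start, b.a_end)]
        if deltas:
            details["cross_border_delta"] = min(deltas)
            details["cross_blocks"] = len(cross)
    return CNVCall(locus_id, unit_a if unit_a else unit_b, ca, cb, ident, details)


def detect_inversion(
    blocks: list[SimilarityBlock],
    min_total: int = 2 * DEFAULT_MIN_LENGTH,
    max_gap: int = 100_000,
) -> tuple[tuple[int, int], tuple[int, int]] | None:
    """Inversion interval from a locus pair's similarity blocks.

    Finds the maximal run of reverse-orientation blocks that are
    collinear in reversed order (a ascending, b descending) and returns
    the spanned intervals on (A, B); None when no such run reaches
    ``min_total`` aligned bases.
    """
    rev = sorted((b for b in blocks if b.orientation == "reverse"),
                 key=lambda b: b.a_start)
    if not rev:
        return None
    # best-scoring chain (a ascending, b descending, small overlap slop for
    # chance palindromic block edges) by quadratic DP; block counts are tiny
    slop = 50
    n = len(rev)
    total = [b.length for b in rev]
    prev = [-1] * n
    for i in range(n):
        for j in range(i):
            bi, bj = rev[i], rev[j]
            if bi.a_start >= bj.a_end - slop \
                    and bi.b_end <= bj.b_start + slop \
                    and bi.a_start - bj.a_end < max_gap \
                    and total[j] + bi.length > total[i]:
                total[i] = total[j] + bi.length
                prev[i] = j
    best_i = max(range(n), key=lambda i: total[i])
    if total[best_i] < min_total:
        return None
    chain = []
    i = best_i
    while i >= 0:
        chain.append(rev[i])
        i = prev[i]
    a_iv = (min(b.a_start for b in chain), max(b.a_end for b in chain))
    b_iv = (min(b.b_start for b in chain), max(b.b_end for b in chain))
    return a_iv, b_iv
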