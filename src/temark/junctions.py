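"""Repair-mechanism classification of indel junctions.

Every large indel junction between two genomes carries a sequence
signature of the DNA repair event that produced it.  This module
extracts those signatures and assigns one mechanism per junction:

``unequal_recombination``     deletion flanked in the donor by long
                              (>=100 bp, >=95% identity) direct repeats,
                              one copy retained at the junction
``ltr_recombination``         the long repeats are the LTRs of a single
                              annotated element (solo-LTR formation)
``mmej``                      microhomology-mediated end joining: a short
                              (1-9 bp) direct repeat flanks the deleted
                              segment and appears exactly once at the
                              derived junction
``sdmmej``                    synthesis-dependent MMEJ: a templated
                              ("filler") insertion, or synthesis-created
                              microhomology, reconstructable by one or two
                              rounds of primer-repeat annealing and fill-in
``blunt_cnhej_or_ambiguous``  no junction homology signature
``introgression``             replacement whose inserted segment has no
                              homology to the donor or any reference
``cnv_duplication``           tandem copy-number change

SD-MMEJ reconstruction model
----------------------------
A double-strand break inside the deleted segment leaves two ends.  In
each synthesis round one end's terminal bases (the *primer repeat*)
anneal to a matching site within a configurable window of either
breakpoint -- in direct orientation (loop-out) or to its reverse
complement (snap-back) -- and fill-in synthesis copies template bases,
extending that end.  After at most ``max_rounds`` rounds the two ends
share a junction microhomology (created at least partly by synthesis),
anneal, and seal, retaining one microhomology copy.  A reconstruction is
valid iff replaying it reproduces the derived junction byte-for-byte:
``left + appended + (prepended + right)[len(micro):] == left + net + right``.
The search is exhaustive over primer repeats, template positions, tract
lengths and round orderings within the window, so an empty result means
no SD-MMEJ explanation exists under the model's parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .breakpoints import IndelCall
from .homology import find_similarity_blocks
from .seqs import lcp_len, lcs_len, revcomp

MAX_MICROHOMOLOGY = 9        # "micro" means <10 bp
DEFAULT_WINDOW = 35          # primer/template search window per breakpoint side
DEFAULT_MIN_MICRO = 2        # minimum annealing overlap created by synthesis
MIN_FLANK_REPEAT = 100       # long-repeat floor (shared with block thresholds)
MIN_FLANK_REPEAT_IDENTITY = 0.95
INTROGRESSION_MIN_LENGTH = 1000

MECHANISM_LABELS = (
    "unequal_recombination", "ltr_recombination", "mmej", "sdmmej",
    "blunt_cnhej_or_ambiguous", "introgression", "cnv_duplication",
)


@dataclass(frozen=True)
class SDMMEJReconstruction:
    """One valid SD-MMEJ replay of a junction.

    ``primer_repeat_positions`` are 1-based start positions of the
    template occurrence used in each round, in the coordinates of the
    analysis context (left window + deleted-segment edges + right
    window, as returned alongside the reconstructions);
    ``template_interval`` covers the template of the final round.
    """

    primer_repeat: str
    primer_repeat_positions: tuple[int, ...]
    template_interval: tuple[int, int]
    synthesis_tracts: tuple[str, ...]
    synthesis_rounds: int
    junction_microhomology: str
    net_insertion_explained: str
    repeat_class: str            # "direct" | "inverted"
    sides: tuple[str, ...] = ()  # which DSB end extended in each round

    @property
    def synthesis_tract(self) -> str:
        return "".join(self.synthesis_tracts)

    @property
    def total_synthesis(self) -> int:
        return sum(len(t) for t in self.synthesis_tracts)


@dataclass
class JunctionSignature:
    """All junction evidence for one indel plus the inferred mechanism."""

    locus_id: str
    mechanism: str
    microhomology: str = ""
    microhomology_length: int = 0
    flanking_repeat_length: int = 0
    flanking_repeat_identity: float = 0.0
    net_insertion: str = ""
    reconstructions: list[SDMMEJReconstruction] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)


# --- junction microhomology -------------------------------------------------

def find_junction_microhomology(
    donor_left: str,
    deleted: str,
    donor_right: str,
    derived_junction: str | None = None,
    max_mh: int = MAX_MICROHOMOLOGY,
) -> tuple[str, bool]:
    """Longest direct repeat flanking a deleted segment on both ends.

    The repeat must border the deletion (as a shared prefix of the
    deleted segment and the retained right flank, or a shared suffix of
    the retained left flank and the deleted segment) and appear exactly
    once at the derived junction between the conserved flanks.  Returns
    ``("", True)`` for a blunt junction.  A repeat longer than ``max_mh``
    is truncated (the caller should treat such junctions as
    intermediate-homology, not microhomology).
    """
    m_right = lcp_len(deleted, donor_right)
    m_left = lcs_len(donor_left, deleted)
    mlen = max(m_right, m_left)
    if mlen == 0:
        return "", True
    motif = deleted[:m_right] if m_right >= m_left else donor_left[-m_left:]
    motif = motif[:max_mh] if mlen > max_mh else motif
    if derived_junction is None:
        derived_junction = donor_left + donor_right
    j = len(donor_left)
    lo = max(0, j - len(motif))
    window = derived_junction[lo : j + len(motif)]
    single = window.count(motif) == 1
    return motif, single


def raw_junction_repeat_length(donor_left: str, deleted: str, donor_right: str) -> int:
    """Un-truncated flanking-repeat length (for intermediate-homology calls)."""
    return max(lcp_len(deleted, donor_right), lcs_len(donor_left, deleted))


# --- long flanking repeats --------------------------------------------------

def find_flanking_direct_repeats(
    donor_locus: str,
    breakpoint5: int,
    breakpoint3: int,
    min_length: int = MIN_FLANK_REPEAT,
    min_identity: float = MIN_FLANK_REPEAT_IDENTITY,
    ambiguity: int = 0,
    search_span: int = 10_000,
):
    """Longest direct-repeat pair with one copy at each breakpoint.

    ``breakpoint5``/``breakpoint3`` are 1-based positions in
    ``donor_locus``: the first and last deleted base.  The copies are
    sought within ``search_span`` on either side of each breakpoint
    (placement ambiguity can put a copy just inside or just outside the
    deletion) and must each overlap their breakpoint within
    ``ambiguity`` + 100 bp.  Returns ``(iv5, iv3, length, identity)``
    in donor_locus coordinates, or None.
    """
    tol = ambiguity + 100
    l_lo = max(1, breakpoint5 - search_span)
    l_hi = min(len(donor_locus), breakpoint5 + search_span)
    r_lo = max(1, breakpoint3 - search_span)
    r_hi = min(len(donor_locus), breakpoint3 + search_span)
    left = donor_locus[l_lo - 1 : l_hi]
    right = donor_locus[r_lo - 1 : r_hi]
    if len(left) < min_length or len(right) < min_length:
        return None
    best = None
    for b in find_similarity_blocks(left, right, min_length, min_identity):
        iv5 = (l_lo + b.a_start - 1, l_lo + b.a_end - 1)
        iv3 = (r_lo + b.b_start - 1, r_lo + b.b_end - 1)
        if iv5 == iv3:
            continue
        # each copy must overlap its breakpoint region
        if not (iv5[0] - tol <= breakpoint5 <= iv5[1] + tol):
            continue
        if not (iv3[0] - tol <= breakpoint3 <= iv3[1] + tol):
            continue
        if best is None or b.length > best[2]:
            best = (iv5, iv3, b.length, b.identity)
    return best


def detect_ltr_recombination(breakpoint_regions, te_annotation) -> tuple[bool, tuple | None]:
    """Are both breakpoints inside same-family, same-orientation LTRs?

    ``breakpoint_regions`` is a pair of 1-based closed intervals (the
    breakpoint positions widened by the call's ambiguity).  The
    annotation records need ``start``, ``end``, ``strand``, ``name`` and
    ``feature_class`` attributes; only class ``"ltr"`` records are used.
    Returns (flag, (record5, record3)).
    """
    (lo5, hi5), (lo3, hi3) = breakpoint_regions
    ltrs = [r for r in te_annotation if getattr(r, "feature_class", "") == "ltr"]
    for r5 in ltrs:
        if r5.end < lo5 or r5.start > hi5:
            continue
        for r3 in ltrs:
            if r3 is r5 or r3.end < lo3 or r3.start > hi3:
                continue
            if r5.name == r3.name and r5.strand == r3.strand:
                return True, (r5, r3)
    return False, None


# --- SD-MMEJ reconstruction -------------------------------------------------

class _Context:
    """Template search context: windows around both breakpoints.

    Segments (left-flank tail, deleted-segment head, deleted-segment
    tail, right-flank head) are concatenated into one coordinate system
    for reporting.  ``window`` bounds how far from its breakpoint a
    primer-repeat occurrence may *start*; each segment keeps an extra
    margin of sequence so a synthesis template that begins inside the
    window may extend beyond it (the published worked junctions include
    a 17 bp template starting 21 bp from the breakpoint).  Template
    matches never span segment boundaries.
    """

    _MARGIN = 45

    def __init__(self, donor_left: str, deleted: str, donor_right: str, window: int):
        self.window = window
        w = window + self._MARGIN
        # (sequence, anchor): the breakpoint sits at the "start" or "end"
        segs: list[tuple[str, str]] = [(donor_left[-w:], "end")]
        if deleted:
            if len(deleted) <= 2 * w:
                segs.append((deleted, "both"))
            else:
                segs.append((deleted[:w], "start"))
                segs.append((deleted[-w:], "end"))
        segs.append((donor_right[:w], "start"))
        self.segments: list[tuple[int, str, str]] = []  # (offset, seq, anchor)
        off = 0
        for s, anchor in segs:
            self.segments.append((off, s, anchor))
            off += len(s)

    def occurrences(self, motif: str):
        """(context_pos0, segment_seq, offset_in_segment) of occurrences
        whose start lies within ``window`` of the segment's breakpoint."""
        if not motif:
            return
        for off, seg, anchor in self.segments:
            start = 0
            while True:
                i = seg.find(motif, start)
                if i < 0:
                    break
                near_start = i <= self.window
                near_end = len(seg) - (i + len(motif)) <= self.window
                if (anchor == "start" and near_start) or \
                        (anchor == "end" and near_end) or \
                        (anchor == "both" and (near_start or near_end)):
                    yield off + i, seg, i
                start = i + 1


def _rank_key(rec: SDMMEJReconstruction):
    return (rec.synthesis_rounds, -len(rec.junction_microhomology),
            rec.total_synthesis, rec.primer_repeat_positions,
            rec.sides, rec.repeat_class, rec.synthesis_tracts)


def _identity_key(rec: SDMMEJReconstruction):
    return (rec.synthesis_tracts, rec.sides, rec.repeat_class,
            rec.junction_microhomology, rec.primer_repeat_positions)


def reconstruct_sdmmej(
    donor_left: str,
    donor_right: str,
    net_insertion: str,
    deleted: str = "",
    window: int = DEFAULT_WINDOW,
    max_rounds: int = 2,
    min_primer: int = 1,
    max_primer: int = MAX_MICROHOMOLOGY,
    min_micro: int = DEFAULT_MIN_MICRO,
    max_micro: int = MAX_MICROHOMOLOGY,
) -> list[SDMMEJReconstruction]:
    """Exhaustive SD-MMEJ reconstruction of one junction.

    The derived junction is ``donor_left + net_insertion + donor_right``
    (``net_insertion`` may be empty: an apparently blunt junction can
    still be SD-MMEJ if synthesis created the annealing microhomology).
    Returns every distinct valid reconstruction, ranked by fewest
    rounds, then longest junction microhomology (annealing stability),
    then least total synthesis, then template position.
    """
    ctx = _Context(donor_left, deleted, donor_right, window)
    X = net_insertion
    target = X + donor_right
    results: dict[tuple, SDMMEJReconstruction] = {}
    max_ext = len(X) + max_micro

    def finish(A, B, tracts, positions, sides, classes, last_tpl):
        if not tracts:
            return
        BR = B + donor_right
        LA = donor_left + A
        best_m = 0
        for m in range(min_micro, min(max_micro, len(BR), len(LA)) + 1):
            if LA[-m:] != BR[:m]:
                continue
            if A + BR[m:] != target:
                continue
            # the annealing microhomology must be at least partly synthesis-made
            if not ((A and m <= len(A) + 0) or (B and m <= len(B) + 0)):
                continue
            best_m = m
        if not best_m:
            return
        micro = BR[:best_m]
        rec = SDMMEJReconstruction(
            primer_repeat=positions[0][1],
            primer_repeat_positions=tuple(p + 1 for p, _, _ in positions),
            template_interval=last_tpl,
            synthesis_tracts=tuple(tracts),
            synthesis_rounds=len(tracts),
            junction_microhomology=micro,
            net_insertion_explained=X,
            repeat_class="inverted" if "inverted" in classes else "direct",
            sides=tuple(sides),
        )
        results.setdefault(_identity_key(rec), rec)

    def extend(A, B, tracts, positions, sides, classes, rounds_left):
        finish(A, B, tracts, positions, sides, classes,
               positions[-1][2] if positions else (0, 0))
        if rounds_left == 0:
            return
        # ---- extend the left end (3' end of donor_left + A) ----
        LA = donor_left + A
        budget_a = max_ext - len(A)
        if budget_a > 0:
            for plen in range(min_primer, min(max_primer, len(LA)) + 1):
                primer = LA[-plen:]
                # direct (loop-out / trans direct repeat): copy bases after the occurrence
                for pos0, seg, i in ctx.occurrences(primer):
                    avail = seg[i + plen :]
                    for t in range(1, min(len(avail), budget_a) + 1):
                        tract = avail[:t]
                        A2 = A + tract
                        if not target.startswith(A2):
                            continue
                        tpl = (pos0 + 1, pos0 + plen + t)
                        extend(A2, B, tracts + [tract],
                               positions + [(pos0, primer, tpl)],
                               sides + ["left"], classes + ["direct"],
                               rounds_left - 1)
                # inverted (snap-back): primer anneals where the top strand
                # reads revcomp(primer); synthesis copies leftward bases,
                # reverse-complemented
                for pos0, seg, i in ctx.occurrences(revcomp(primer)):
                    avail = seg[:i]
                    for t in range(1, min(len(avail), budget_a) + 1):
                        tract = revcomp(avail[-t:])
                        A2 = A + tract
                        if not target.startswith(A2):
                            continue
                        tpl = (pos0 - t + 1, pos0 + plen)
                        extend(A2, B, tracts + [tract],
                               positions + [(pos0, primer, tpl)],
                               sides + ["left"], classes + ["inverted"],
                               rounds_left - 1)
        # ---- extend the right end (5'-facing end of B + donor_right) ----
        BR = B + donor_right
        budget_b = max_ext - len(B)
        if budget_b > 0:
            suffix_ok = [BR[m:] for m in range(0, max_micro + 1)]
            for plen in range(min_primer, min(max_primer, len(BR)) + 1):
                primer = BR[:plen]
                for pos0, seg, i in ctx.occurrences(primer):
                    avail = seg[:i]
                    for t in range(1, min(len(avail), budget_b) + 1):
                        tract = avail[-t:]
                        B2 = tract + B
                        B2R = B2 + donor_right
                        if not any(target.endswith(B2R[m:])
                                   for m in range(0, min(max_micro, len(B2R)) + 1)):
                            continue
                        tpl = (pos0 - t + 1, pos0 + plen)
                        extend(A, B2, tracts + [tract],
                               positions + [(pos0, primer, tpl)],
                               sides + ["right"], classes + ["direct"],
                               rounds_left - 1)
                for pos0, seg, i in ctx.occurrences(revcomp(primer)):
                    avail = seg[i + plen :]
                    for t in range(1, min(len(avail), budget_b) + 1):
                        tract = revcomp(avail[:t])
                        B2 = tract + B
                        B2R = B2 + donor_right
                        if not any(target.endswith(B2R[m:])
                                   for m in range(0, min(max_micro, len(B2R)) + 1)):
                            continue
                        tpl = (pos0 + 1, pos0 + plen + t)
                        extend(A, B2, tracts + [tract],
                               positions + [(pos0, primer, tpl)],
                               sides + ["right"], classes + ["inverted"],
                               rounds_left - 1)

    extend("", "", [], [], [], [], max_rounds)
    out = sorted(results.values(), key=_rank_key)
    return out


def replay_reconstruction(donor_left: str, donor_right: str,
                          rec: SDMMEJReconstruction) -> str:
    """Replay a reconstruction to its derived junction sequence.

    Appends left-side tracts, prepends right-side tracts, anneals on the
    junction microhomology and seals -- independent of the search that
    produced the reconstruction, so equality with the observed junction
    is a real check.
    """
    A = "".join(t for t, s in zip(rec.synthesis_tracts, rec.sides) if s == "left")
    B = "".join(t for t, s in reversed(list(zip(rec.synthesis_tracts, rec.sides)))
                if s == "right")
    LA = donor_left + A
    BR = B + donor_right
    m = len(rec.junction_microhomology)
    if m == 0 or LA[-m:] != BR[:m]:
        raise ValueError("reconstruction does not anneal on its stated microhomology")
    return LA + BR[m:]


# --- introgression ----------------------------------------------------------

def detect_introgression(
    net_insertion: str,
    donor_genome: dict,
    other_reference_genomes: tuple[dict, ...] = (),
    min_length: int = INTROGRESSION_MIN_LENGTH,
    min_block: int = MIN_FLANK_REPEAT,
    min_identity: float = MIN_FLANK_REPEAT_IDENTITY,
) -> tuple[bool, dict]:
    """Is an inserted segment foreign to the donor and all references?

    True iff the insert is at least ``min_length`` long and produces no
    similarity block at the configured thresholds against any provided
    genome.  The report records the best hit found, if any.
    """
    report: dict = {"insert_length": len(net_insertion), "best_hit": None}
    if len(net_insertion) < min_length:
        report["reason"] = "insert below minimum length"
        return False, report
    for gi, genome in enumerate((donor_genome, *other_reference_genomes)):
        for chrom, seq in genome.items():
            if len(seq) < min_block:
                continue
            blocks = find_similarity_blocks(net_insertion, seq, min_block,
                                            min_identity, both_strands=True)
            if blocks:
                best = max(blocks, key=lambda b: b.length)
                report["best_hit"] = {
                    "genome_index": gi, "chromosome": chrom,
                    "interval": list(best.b_interval), "length": best.length,
                    "identity": best.identity,
                }
                return False, report
    return True, report


# --- top-level mechanism assignment ----------------------------------------

def classify_mechanism(
    indel: IndelCall,
    donor_seq: str,
    derived_seq: str,
    te_annotation=None,
    donor_genome: dict | None = None,
    reference_genomes: tuple[dict, ...] = (),
    context: int = 200,
    window: int = DEFAULT_WINDOW,
) -> JunctionSignature:
    """Assign one repair mechanism to a called indel.

    Precedence (most specific, cheapest-to-verify evidence first):
    introgression/replacement check, long flanking direct repeats
    (refined to LTR recombination when both breakpoints sit in the LTRs
    of one annotated element), SD-MMEJ (when a net insertion is fully
    explained by templated synthesis), MMEJ (1-9 bp single-copy
    junction repeat), and finally blunt/ambiguous.  All extracted
    evidence is retained on the signature regardless of the label.
    """
    sig = JunctionSignature(locus_id=indel.locus_id, mechanism="blunt_cnhej_or_ambiguous")
    a_s, a_e = indel.a_interval
    b_s, b_e = indel.b_interval
    deleted = donor_seq[a_s - 1 : a_e] if a_e >= a_s else ""
    net = derived_seq[b_s - 1 : b_e] if b_e >= b_s else ""
    left = donor_seq[max(0, a_s - 1 - context) : a_s - 1]
    right = donor_seq[a_e : a_e + context]
    sig.net_insertion = net

    if indel.rearrangement_type == "copy_number_variation":
        sig.mechanism = "cnv_duplication"
        return sig

    # replacement: foreign insert -> introgression
    if indel.rearrangement_type == "replacement" and len(net) >= INTROGRESSION_MIN_LENGTH:
        genome = donor_genome if donor_genome is not None else {"donor": donor_seq}
        foreign, report = detect_introgression(net, genome, reference_genomes)
        if foreign:
            sig.mechanism = "introgression"
            sig.notes.append("inserted segment has no homology to donor or references")
            return sig
        sig.notes.append(f"replacement insert has donor/reference homology: {report['best_hit']}")

    # long direct repeats spanning the breakpoints
    rep = None
    if deleted:
        rep = find_flanking_direct_repeats(
            donor_seq, a_s, a_e, MIN_FLANK_REPEAT, MIN_FLANK_REPEAT_IDENTITY,
            ambiguity=indel.ambiguity_width)
    micro, single = find_junction_microhomology(left, deleted, right,
                                                derived_junction=left + net + right)
    sig.microhomology = micro
    sig.microhomology_length = len(micro)
    if rep is not None:
        iv5, iv3, rlen, rident = rep
        sig.flanking_repeat_length = rlen
        sig.flanking_repeat_identity = rident
        is_ltr = False
        if te_annotation is not None:
            # equivalent placements slide both breakpoints rightward from
            # the leftmost-normalised call by up to the ambiguity width
            amb = indel.ambiguity_width
            regions = ((a_s - 1, a_s + amb + 1), (a_e - 1, a_e + amb + 1))
            is_ltr, pair = detect_ltr_recombination(regions, te_annotation)
        sig.mechanism = "ltr_recombination" if is_ltr else "unequal_recombination"
        return sig

    raw_rep = raw_junction_repeat_length(left, deleted, right) if deleted else 0
    if raw_rep > MAX_MICROHOMOLOGY:
        sig.notes.append(
            f"intermediate junction homology ({raw_rep} bp, between the "
            "microhomology ceiling and the long-repeat floor)")
        return sig

    if net:
        recs = reconstruct_sdmmej(left, right, net, deleted=deleted, window=window)
        sig.reconstructions = recs
        if recs:
            sig.mechanism = "sdmmej"
            return sig
        sig.notes.append("net insertion not explained by templated synthesis")
        return sig

    if 1 <= len(micro) <= MAX_MICROHOMOLOGY and single:
        sig.mechanism = "mmej"
        return sig

    # apparently blunt: attach any SD-MMEJ explanation as evidence only
    recs = reconstruct_sdmmej(left, right, "", deleted=deleted, window=window)
    sig.reconstructions = recs
    if recs:
        sig.notes.append("apparent blunt junction admits an SD-MMEJ explanation")
    if len(deleted) > 10_000:
        sig.notes.append("long deletion: MMEJ-family repair more likely than C-NHEJ")
    return sig
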