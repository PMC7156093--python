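"""Cross-genome matching of TE insertions and ortholocus location.

Insertions retrieved independently from two genomes are paired by best
reciprocal flank similarity; insertions with no counterpart are
candidate species-specific sites.  For each candidate, the orthologous
locus on the other genome is located by chromosome walking --
progressively longer flanking sequence is aligned until significant
anchors bracket the site on both sides -- and the polymorphism source
is classified by a fixed decision tree (cheapest and most exculpatory
evidence first): assembly artifact (Ns at the putative breakpoint),
empty site with a single TSD copy, internal/chimeric element deletion,
replacement by a non-homologous insertion, and finally long-indel
candidate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .breakpoints import IndelCall, call_indel
from .homology import find_similarity_blocks
from .retrieval import TEConsensus, TEInsertion, _union_length

POLYMORPHISM_CATEGORIES = (
    "monomorphic", "empty_site_tsd", "internal_deletion", "chimeric_deletion",
    "assembly_artifact", "long_indel_candidate", "replaced_by_insertion",
)

_INDEX_K = 32            # exact k-mer used to shortlist flank match candidates
_MIN_ANCHOR = 300        # bp of aligned flank considered a significant anchor
_REPLACED_MIN_INSERT = 1000


@dataclass
class PolymorphismCall:
    """Classification of one insertion's cross-genome polymorphism."""

    insertion_id: str
    match_id: str = ""
    category: str = "long_indel_candidate"
    ortholocus_chromosome: str = ""
    ortholocus: tuple[int, int] | None = None
    evidence: list[str] = field(default_factory=list)
    indel: IndelCall | None = None
    flags: list[str] = field(default_factory=list)


@dataclass
class WalkResult:
    """Outcome of one chromosome walk."""

    found: bool
    b_chromosome: str = ""
    interval: tuple[int, int] | None = None   # innermost anchored B positions
    a_inner: tuple[int, int] | None = None    # innermost anchored A positions
    walked_distance: int = 0
    steps: int = 0


def _flank_kmers(ins: TEInsertion, k: int = _INDEX_K):
    for fl in (ins.flank5, ins.flank3):
        for i in range(0, max(0, len(fl) - k + 1), 8):
            yield fl[i : i + k]


def _flank_score(a: TEInsertion, b: TEInsertion) -> float:
    """Fraction of flank sequence covered by >=90%-identity blocks."""
    total = covered = 0
    for fa, fb in ((a.flank5, b.flank5), (a.flank3, b.flank3)):
        total += max(len(fa), len(fb))
        if len(fa) < 50 or len(fb) < 50:
            continue
        blocks = find_similarity_blocks(fa, fb, min_length=50, min_identity=0.9)
        covered += _union_length([blk.a_interval for blk in blocks])
    return covered / total if total else 0.0


def match_insertions_across_genomes(
    insertions_a: list[TEInsertion],
    insertions_b: list[TEInsertion],
    flank_match_cutoff: float = 0.5,
):
    """Pair insertions across genomes by best reciprocal flank similarity.

    Returns ``(pairs, unmatched_a, unmatched_b, flags)`` where pairs are
    ``(a, b, score)`` tuples.  An unmatched insertion whose best
    counterpart is already claimed by a better-scoring partner is
    flagged ``cnv_review`` (two donor insertions sharing one ortholocus
    are copy-number candidates, not noise).
    """
    for ins in (*insertions_a, *insertions_b):
        if not ins.flank5 and not ins.flank3:
            raise ValueError(f"insertion {ins.id} carries no flanking sequence")
    index: dict[str, set[int]] = {}
    for j, ins in enumerate(insertions_b):
        for km in _flank_kmers(ins):
            index.setdefault(km, set()).add(j)
    score: dict[tuple[int, int], float] = {}
    for i, ia in enumerate(insertions_a):
        hits: dict[int, int] = {}
        for km in _flank_kmers(ia):
            for j in index.get(km, ()):
                hits[j] = hits.get(j, 0) + 1
        for j in sorted(hits, key=lambda j: -hits[j])[:5]:
            score[(i, j)] = _flank_score(ia, insertions_b[j])
    best_for_a: dict[int, int] = {}
    best_for_b: dict[int, int] = {}
    for (i, j), s in score.items():
        if i not in best_for_a or s > score[(i, best_for_a[i])]:
            best_for_a[i] = j
        if j not in best_for_b or s > score[(best_for_b[j], j)]:
            best_for_b[j] = i
    pairs, flags = [], {}
    matched_a, matched_b = set(), set()
    for i, j in best_for_a.items():
        if best_for_b.get(j) == i and score[(i, j)] >= flank_match_cutoff:
            pairs.append((insertions_a[i], insertions_b[j], score[(i, j)]))
            matched_a.add(i)
            matched_b.add(j)
    for i, ia in enumerate(insertions_a):
        if i in matched_a:
            continue
        j = best_for_a.get(i)
        if j is not None and j in matched_b and score[(i, j)] >= flank_match_cutoff:
            partner = insertions_a[best_for_b[j]]
            flags[ia.id] = {"flag": "cnv_review",
                            "b_match": insertions_b[j].id,
                            "a_partner": partner.id}
    unmatched_a = [ins for i, ins in enumerate(insertions_a) if i not in matched_a]
    unmatched_b = [ins for j, ins in enumerate(insertions_b) if j not in matched_b]
    return pairs, unmatched_a, unmatched_b, flags


def chromosome_walk(
    genome_a: dict,
    chromosome: str,
    anchor_interval: tuple[int, int],
    genome_b: dict,
    b_chromosome: str | None = None,
    step: int = 5000,
    max_extent: int = 5_000_000,
    min_anchor: int = _MIN_ANCHOR,
) -> WalkResult:
    """Locate the ortholocus of an A-interval on genome B.

    Flanking sequence of geometrically growing size (step, 2*step, ...)
    is aligned to the orthologous B chromosome until significant anchors
    are found on both sides; the returned interval is bracketed by the
    innermost anchored bases.  Exceeding ``max_extent`` without both
    anchors yields ``found=False`` (not an exception).
    """
    seq_a = genome_a[chromosome]
    bchrom = b_chromosome or chromosome
    if bchrom not in genome_b:
        return WalkResult(found=False)
    seq_b = genome_b[bchrom]
    s0, e0 = anchor_interval
    if not (1 <= s0 <= e0 <= len(seq_a)):
        raise ValueError(f"anchor interval {anchor_interval} outside {chromosome}")
    size = step
    steps = 0
    while size <= max_extent:
        steps += 1
        up = seq_a[max(0, s0 - 1 - size) : s0 - 1]
        down = seq_a[e0 : e0 + size]
        up_cands = down_cands = []
        if len(up) >= min_anchor:
            up_cands = [b for b in find_similarity_blocks(up, seq_b)
                        if b.length >= min_anchor]
        if len(down) >= min_anchor:
            down_cands = [b for b in find_similarity_blocks(down, seq_b)
                          if b.length >= min_anchor]
        # choose the consistent anchor pair maximising total anchored flank
        # length net of the unanchored inner slack -- a short multi-mapping
        # fragment (a TE copy in the flank) cannot then outrank the long
        # unique flank match.  Anchors may overlap on B: junction repeats
        # (microhomology, TSDs, recombination repeats, collapsed tandem
        # units) are matched by the flanks of both sides, so the overlap
        # can reach the flank size.
        up_hit = down_hit = None
        best_key = None
        for u in up_cands:
            for d in down_cands:
                if u.b_end - d.b_start > size:
                    continue
                slack = (len(up) - u.a_end) + (d.a_start - 1)
                key = (-(u.length + d.length - slack),
                       abs(d.b_start - u.b_end))
                if best_key is None or key < best_key:
                    best_key, up_hit, down_hit = key, u, d
        if up_hit and down_hit:
            up_a_inner = (s0 - 1 - len(up)) + up_hit.a_end      # genome A coords
            down_a_inner = e0 + down_hit.a_start
            lo = min(up_hit.b_end, down_hit.b_start)
            hi = max(up_hit.b_end, down_hit.b_start)
            return WalkResult(
                found=True, b_chromosome=bchrom,
                interval=(lo, hi),
                a_inner=(up_a_inner, down_a_inner),
                walked_distance=size, steps=steps,
            )
        if size == max_extent:
            break
        size = min(size * 2, max_extent)
    return WalkResult(found=False, b_chromosome=bchrom, walked_distance=min(size, max_extent),
                      steps=steps)


def _consensus_coverage(consensus: TEConsensus, locus: str) -> float:
    if len(locus) < 50:
        return 0.0
    blocks = find_similarity_blocks(consensus.sequence, locus, min_length=50,
                                    min_identity=0.85, both_strands=True)
    return _union_length([b.a_interval for b in blocks]) / len(consensus)


def classify_matched_pair(a: TEInsertion, b: TEInsertion,
                          consensus: TEConsensus,
                          tolerance: int = 100) -> PolymorphismCall:
    """Category for a flank-matched insertion pair.

    Same structure and compatible length -> monomorphic; an element
    whose counterpart lost internal sequence -> internal_deletion.
    """
    call = PolymorphismCall(insertion_id=a.id, match_id=b.id, category="monomorphic",
                            ortholocus_chromosome=b.chromosome,
                            ortholocus=(b.start, b.end))
    if a.structure == "full_length" and b.structure != "full_length" \
            and b.length < a.length - tolerance:
        call.category = "internal_deletion"
        call.evidence.append(
            f"donor copy {a.length} bp ({a.structure}); counterpart {b.length} bp "
            f"({b.structure})")
    elif a.structure != b.structure:
        call.evidence.append(f"structure differs: {a.structure} vs {b.structure}")
    return call


def classify_polymorphism(
    insertion: TEInsertion,
    genome_a: dict,
    genome_b: dict,
    consensus: TEConsensus,
    walk: WalkResult | None = None,
    pad: int = 1500,
) -> PolymorphismCall:
    """Decision tree for a donor-specific insertion given its ortholocus.

    Runs the walk if not supplied, extracts the locus pair, calls the
    indel and assigns exactly one category; the full audit trail is
    retained in ``evidence``.
    """
    call = PolymorphismCall(insertion_id=insertion.id)
    if walk is None:
        walk = chromosome_walk(genome_a, insertion.chromosome,
                               insertion.interval, genome_b)
    if not walk.found:
        call.evidence.append(
            f"ortholocus not found within walk extent ({walk.walked_distance} bp)")
        call.category = "long_indel_candidate"
        call.flags.append("no_ortholocus")
        return call
    call.ortholocus_chromosome = walk.b_chromosome
    call.ortholocus = walk.interval
    seq_a = genome_a[insertion.chromosome]
    seq_b = genome_b[walk.b_chromosome]
    a_lo = max(1, walk.a_inner[0] - pad)
    a_hi = min(len(seq_a), walk.a_inner[1] + pad)
    b_lo = max(1, walk.interval[0] - pad)
    b_hi = min(len(seq_b), walk.interval[1] + pad)
    locus_a = seq_a[a_lo - 1 : a_hi]
    locus_b = seq_b[b_lo - 1 : b_hi]
    indel = call_indel(locus_a, locus_b, locus_id=insertion.id,
                       a_offset=a_lo, b_offset=b_lo)
    call.indel = indel
    call.evidence.append(
        f"walked {walk.walked_distance} bp; indel type {indel.rearrangement_type}, "
        f"a_len {indel.a_length}, b_len {indel.b_length}")

    if "n_near_breakpoint" in indel.flags:
        call.category = "assembly_artifact"
        call.evidence.append("N-run within the breakpoint window")
        return call
    if indel.rearrangement_type == "inversion":
        call.category = "long_indel_candidate"
        call.flags.append("inversion")
        call.evidence.append("ortholocus is inverted")
        return call
    te_span = insertion.length
    tsd_slack = 2 * max(len(insertion.tsd), 6) + 20
    if (indel.rearrangement_type == "deletion_in_b"
            and insertion.tsd
            and abs(indel.a_length - (te_span + len(insertion.tsd))) <= tsd_slack
            and indel.a_interval[0] - tsd_slack <= insertion.start
            and indel.a_interval[1] + tsd_slack >= insertion.end):
        call.category = "empty_site_tsd"
        call.evidence.append(
            f"deletion matches element span +TSD ({insertion.tsd!r}); single copy retained")
        return call
    if indel.rearrangement_type == "deletion_in_b":
        cov_b = _consensus_coverage(consensus, locus_b)
        if cov_b >= 0.2:
            s, e = indel.a_interval
            inside = insertion.start - 50 <= s and e <= insertion.end + 50
            call.category = "internal_deletion" if inside else "chimeric_deletion"
            call.evidence.append(
                f"element partially present at ortholocus (consensus coverage {cov_b:.2f})")
            return call
    if indel.rearrangement_type == "replacement" and indel.b_length >= _REPLACED_MIN_INSERT:
        call.category = "replaced_by_insertion"
        call.evidence.append(f"non-homologous B-side insert of {indel.b_length} bp")
        return call
    call.category = "long_indel_candidate"
    return call
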