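"""Junction signatures: microhomology, SD-MMEJ reconstruction, mechanisms."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from temark.breakpoints import IndelCall
from temark.junctions import (classify_mechanism, detect_introgression,
                              detect_ltr_recombination,
                              find_flanking_direct_repeats,
                              find_junction_microhomology, reconstruct_sdmmej,
                              replay_reconstruction)
from temark.seqs import mutate, random_dna, revcomp
from temark.simulate import EventSpec, SimConfig, simulate_genome_pair
from temark.wheat_loci import worked_junction


# --- junction microhomology -------------------------------------------------

def test_published_mmej_microhomologies():
    """'GCGT' (4 bp) and 'A' (1 bp) junction repeats, single copy retained."""
    wj = worked_junction("5B_4")
    mh, single = find_junction_microhomology(wj.donor_left, wj.deleted,
                                             wj.donor_right, wj.derived_junction)
    assert (mh, single) == ("GCGT", True)
    wj = worked_junction("5B_3")
    mh, single = find_junction_microhomology(wj.donor_left, wj.deleted,
                                             wj.donor_right, wj.derived_junction)
    assert (mh, single) == ("A", True)


def test_blunt_junction_has_empty_microhomology(rng):
    left = random_dna(rng, 80)
    deleted = "C" + random_dna(rng, 200) + "G"
    right = "T" + random_dna(rng, 79)
    left = left[:-1] + "A"
    mh, single = find_junction_microhomology(left, deleted, right)
    assert mh == "" and single


@given(st.integers(0, 100_000))
@settings(max_examples=25, deadline=None)
def test_mmej_single_copy_property(seed):
    """Constructed MMEJ junctions always retain exactly one repeat copy."""
    rng = np.random.default_rng(seed)
    m = random_dna(rng, int(rng.integers(1, 8)))
    left = random_dna(rng, 60)
    core = random_dna(rng, 120)
    right_tail = random_dna(rng, 60)
    # guards pin the repeat to exactly m
    g1 = next(b for b in "ACGT" if b != right_tail[0])
    left = left[:-1] + next(b for b in "ACGT" if b not in (m[-1], core[-1]))
    deleted = m + g1 + core
    right = m + right_tail
    mh, single = find_junction_microhomology(left, deleted, right)
    assert mh == m
    assert single
    # replay: deleting the leftmost placement reproduces the derived junction
    assert left + right == left + deleted[len(m):][len(deleted) - len(m):] + right


# --- SD-MMEJ reconstruction -------------------------------------------------

def test_one_round_templated_insertion_worked_example():
    """Primer 'A' anneals in 'AAATTTG', synthesis 'AATTTG' (6 nt) creates
    'TTG' microhomology, leaving the 'AAT' insertion."""
    wj = worked_junction("3B_2")
    recs = reconstruct_sdmmej(wj.donor_left, wj.donor_right, wj.net_insertion,
                              wj.deleted)
    assert recs
    top = recs[0]
    assert top.synthesis_rounds == 1
    assert top.synthesis_tract == "AATTTG"
    assert top.net_insertion_explained == "AAT"
    assert top.junction_microhomology == "TTG"
    assert top.primer_repeat == "A"


def test_two_round_14bp_insertion_worked_example():
    """A two-round reconstruction explains the 14 bp templated insertion."""
    wj = worked_junction("3B_4")
    recs = reconstruct_sdmmej(wj.donor_left, wj.donor_right, wj.net_insertion,
                              wj.deleted)
    two = [r for r in recs if r.synthesis_rounds == 2
           and r.net_insertion_explained == "TCTAGCACAACTCC"]
    assert two
    assert any(r.junction_microhomology.startswith("GTC") for r in two)


def test_apparent_blunt_junction_admits_sdmmej_explanation():
    """Synthesis on the 'GATC' motif 29 bp downstream can create the
    annealing microhomology of an apparently blunt junction."""
    wj = worked_junction("3B_5")
    recs = reconstruct_sdmmej(wj.donor_left, wj.donor_right, "", wj.deleted)
    assert recs
    assert all(r.net_insertion_explained == "" for r in recs)
    planted = [r for r in recs
               if r.synthesis_tract in ("GA", "TC") and r.total_synthesis == 2]
    assert planted


def test_every_reconstruction_replays_to_derived_junction():
    for lid, net in (("3B_2", None), ("3B_4", None), ("3B_5", "")):
        wj = worked_junction(lid)
        x = wj.net_insertion if net is None else net
        for rec in reconstruct_sdmmej(wj.donor_left, wj.donor_right, x, wj.deleted):
            assert replay_reconstruction(wj.donor_left, wj.donor_right, rec) \
                == wj.donor_left + x + wj.donor_right


# --- naive oracle (plain exhaustive enumeration, no pruning) ---------------

def naive_sdmmej(left, deleted, right, net, window=30, max_rounds=2,
                 min_primer=1, max_primer=9, min_micro=2, max_micro=9):
    """Brute-force enumeration of the SD-MMEJ model on small contexts.

    Assumes len(left), len(right), len(deleted) <= window + 45 so every
    occurrence is within reach of a breakpoint and no position filtering
    applies; template matches stay within one of the three segments.
    """
    segs = []
    off = 0
    for s in (left, deleted, right) if deleted else (left, right):
        segs.append((off, s))
        off += len(s)
    target = net + right
    results = set()

    def occurrences(motif):
        for o, seg in segs:
            for i in range(len(seg) - len(motif) + 1):
                if seg[i : i + len(motif)] == motif:
                    yield o + i, seg, i

    def finish(A, B, tracts, poss, sides, classes):
        if not tracts:
            return
        LA, BR = left + A, B + right
        best = 0
        for m in range(min_micro, min(max_micro, len(LA), len(BR)) + 1):
            if LA[-m:] == BR[:m] and A + BR[m:] == target \
                    and ((A and m <= len(A)) or (B and m <= len(B))):
                best = m
        if best:
            results.add((tuple(tracts), tuple(sides),
                         "inverted" if "inverted" in classes else "direct",
                         BR[:best], tuple(p + 1 for p in poss)))

    def step(A, B, tracts, poss, sides, classes, rounds):
        finish(A, B, tracts, poss, sides, classes)
        if rounds == 0:
            return
        LA, BR = left + A, B + right
        cap = len(net) + max_micro
        for plen in range(min_primer, min(max_primer, len(LA)) + 1):
            primer = LA[-plen:]
            for pos, seg, i in occurrences(primer):
                for t in range(1, min(len(seg) - i - plen, cap - len(A)) + 1):
                    step(A + seg[i + plen : i + plen + t], B,
                         tracts + [seg[i + plen : i + plen + t]], poss + [pos],
                         sides + ["left"], classes + ["direct"], rounds - 1)
            for pos, seg, i in occurrences(revcomp(primer)):
                for t in range(1, min(i, cap - len(A)) + 1):
                    step(A + revcomp(seg[i - t : i]), B,
                         tracts + [revcomp(seg[i - t : i])], poss + [pos],
                         sides + ["left"], classes + ["inverted"], rounds - 1)
        for plen in range(min_primer, min(max_primer, len(BR)) + 1):
            primer = BR[:plen]
            for pos, seg, i in occurrences(primer):
                for t in range(1, min(i, cap - len(B)) + 1):
                    step(A, seg[i - t : i] + B, tracts + [seg[i - t : i]],
                         poss + [pos], sides + ["right"], classes + ["direct"],
                         rounds - 1)
            for pos, seg, i in occurrences(revcomp(primer)):
                for t in range(1, min(len(seg) - i - plen, cap - len(B)) + 1):
                    tract = revcomp(seg[i + plen : i + plen + t])
                    step(A, tract + B, tracts + [tract], poss + [pos],
                         sides + ["right"], classes + ["inverted"], rounds - 1)

    step("", "", [], [], [], [], max_rounds)
    return results


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_reconstruction_equals_naive_enumeration(seed):
    """On small contexts the pruned search equals plain enumeration."""
    rng = np.random.default_rng(seed)
    left = random_dna(rng, 20)
    deleted = random_dna(rng, 30)
    right = random_dna(rng, 20)
    net = random_dna(rng, 2)
    got = {(r.synthesis_tracts, r.sides, r.repeat_class,
            r.junction_microhomology, r.primer_repeat_positions)
           for r in reconstruct_sdmmej(left, right, net, deleted, window=30,
                                       max_rounds=2)}
    want = naive_sdmmej(left, deleted, right, net)
    assert got == want


@given(st.integers(0, 10_000))
@settings(max_examples=10, deadline=None)
def test_window_monotonicity(seed):
    """Enlarging the search window never removes a reconstruction."""
    rng = np.random.default_rng(seed)
    left, deleted, right = random_dna(rng, 60), random_dna(rng, 80), random_dna(rng, 60)
    net = random_dna(rng, 2)
    key = lambda r: (r.synthesis_tracts, r.sides, r.junction_microhomology)
    small = {key(r) for r in reconstruct_sdmmej(left, right, net, deleted,
                                                window=15, max_rounds=1)}
    large = {key(r) for r in reconstruct_sdmmej(left, right, net, deleted,
                                                window=30, max_rounds=1)}
    assert small <= large


def test_simulated_sdmmej_event_recovered_as_top_rank():
    """The planted one-round reconstruction tops the ranking."""
    cfg = SimConfig(n_chromosomes=1, chromosome_length=120_000,
                    te_copies_per_chromosome=0,
                    event_specs=[EventSpec("sdmmej", deletion_length=3000,
                                           insert_te=False)],
                    seed=61)
    pair = simulate_genome_pair(cfg)
    ev = pair.events[0]
    s, e = ev.edit_interval
    seq = pair.genome_a[ev.chromosome]
    recs = reconstruct_sdmmej(seq[s - 201 : s - 1], seq[e : e + 200],
                              ev.net_insertion, seq[s - 1 : e])
    assert recs
    top = recs[0]
    assert top.net_insertion_explained == ev.net_insertion
    assert top.synthesis_rounds == 1
    assert replay_reconstruction(seq[s - 201 : s - 1], seq[e : e + 200], top) \
        == seq[s - 201 : s - 1] + ev.net_insertion + seq[e : e + 200]


# --- long flanking repeats and LTR recombination ---------------------------

def test_flanking_repeats_found_and_thresholded(rng):
    left_bg = random_dna(rng, 2000)
    rep = random_dna(rng, 1000)
    rep99, _ = mutate(rng, rep, 0.01)
    core = random_dna(rng, 6000)
    right_bg = random_dna(rng, 2000)
    donor = left_bg + rep + core + rep99 + right_bg
    bp5 = len(left_bg) + len(rep) + 1           # leftmost deleted base
    bp3 = len(left_bg) + len(rep) + len(core) + len(rep99)
    found = find_flanking_direct_repeats(donor, bp5, bp3, ambiguity=0)
    assert found is not None
    iv5, iv3, length, ident = found
    assert length >= 950 and ident >= 0.98
    # a 4 bp junction repeat is far below the long-repeat floor
    assert find_flanking_direct_repeats(donor, bp5, bp5 + 10) is None


def test_flanking_repeats_identity_sweep(rng):
    """90%-identity repeats fail at the default floor, pass at 0.85."""
    left_bg = random_dna(rng, 1500)
    rep = random_dna(rng, 600)
    rep90, _ = mutate(rng, rep, 0.10)
    core = random_dna(rng, 4000)
    donor = left_bg + rep + core + rep90 + random_dna(rng, 1500)
    bp5 = len(left_bg) + len(rep) + 1
    bp3 = len(left_bg) + len(rep) + len(core) + len(rep90)
    assert find_flanking_direct_repeats(donor, bp5, bp3, min_identity=0.95) is None
    assert find_flanking_direct_repeats(donor, bp5, bp3, min_identity=0.85) is not None


class _Rec:
    def __init__(self, start, end, strand, name, feature_class):
        self.start, self.end, self.strand = start, end, strand
        self.name, self.feature_class = name, feature_class


def test_ltr_recombination_requires_same_family_same_orientation():
    ann = [_Rec(1000, 1300, "+", "famX", "ltr"),
           _Rec(1301, 3400, "+", "famX", "te_internal"),
           _Rec(3401, 3700, "+", "famX", "ltr"),
           _Rec(5000, 5300, "-", "famX", "ltr")]
    hit, pair = detect_ltr_recombination(((1250, 1350), (3450, 3550)), ann)
    assert hit and pair[0].start == 1000 and pair[1].start == 3401
    # one breakpoint in the internal domain only
    assert not detect_ltr_recombination(((2000, 2100), (3450, 3550)), ann)[0]
    # opposite orientation
    assert not detect_ltr_recombination(((1250, 1350), (5100, 5200)), ann)[0]


# --- introgression ----------------------------------------------------------

def test_introgression_detection(rng):
    donor = {"c1": random_dna(rng, 60_000)}
    foreign = random_dna(rng, 2000)
    assert detect_introgression(foreign, donor)[0]
    copied = donor["c1"][10_000:12_000]
    assert not detect_introgression(copied, donor)[0]
    near, _ = mutate(rng, copied, 0.04)            # 96% identity to the donor
    assert not detect_introgression(near, donor)[0]
    short = random_dna(rng, 400)                   # below the length floor
    ok, report = detect_introgression(short, donor)
    assert not ok and "reason" in report


# --- mechanism precedence ---------------------------------------------------

def test_precedence_repeats_beat_microhomology(rng):
    """A junction with both a long flanking repeat and 3 bp microhomology
    is unequal recombination; the microhomology is still reported."""
    rep = random_dna(rng, 400)
    m = "TGC"
    left_bg, core, right_bg = (random_dna(rng, 3000), random_dna(rng, 5000),
                               random_dna(rng, 3000))
    donor = left_bg + rep + m + core + rep + m + right_bg
    derived = left_bg + rep + m + right_bg
    # leftmost placement deletes [m + core + rep]; the retained right flank
    # then starts with the second m copy
    bp5 = len(left_bg) + len(rep) + 1
    bp3 = len(left_bg) + len(rep) + len(m) + len(core) + len(rep)
    indel = IndelCall("t", (bp5, bp3), (bp5, bp5 - 1), bp3 - bp5 + 1,
                      0, "deletion_in_b", (bp5 - 1, bp5 - 1), (bp3 + 1, bp5),
                      ambiguity_width=len(rep) + len(m))
    sig = classify_mechanism(indel, donor, derived)
    assert sig.mechanism == "unequal_recombination"
    assert sig.flanking_repeat_length >= 390
    # the short-homology evidence is still extracted and reported
    assert sig.microhomology_length >= len(m)


def test_long_blunt_deletion_notes_mmej_family(rng):
    left = random_dna(rng, 3000)
    core = random_dna(rng, 23_000)
    right = random_dna(rng, 3000)
    core = next(b for b in "ACGT" if b != right[0]) + core[1:-1] \
        + next(b for b in "ACGT" if b != left[-1])
    donor = left + core + right
    derived = left + right
    bp5, bp3 = len(left) + 1, len(left) + len(core)
    indel = IndelCall("t", (bp5, bp3), (bp5, bp5 - 1), len(core), 0,
                      "deletion_in_b", (bp5 - 1, bp5 - 1), (bp3 + 1, bp5), 0)
    sig = classify_mechanism(indel, donor, derived)
    assert sig.mechanism == "blunt_cnhej_or_ambiguous"
    assert any("C-NHEJ" in n for n in sig.notes)


def test_intermediate_homology_is_flagged_not_mmej(rng):
    """A 30 bp junction repeat is neither microhomology nor a long repeat."""
    m = random_dna(rng, 30)
    left = random_dna(rng, 2000)
    core = random_dna(rng, 4000)
    right_bg = random_dna(rng, 2000)
    donor = left + m + core + m + right_bg
    derived = left + m + right_bg
    bp5 = len(left) + 1
    bp3 = len(left) + len(m) + len(core)
    indel = IndelCall("t", (bp5, bp3), (bp5, bp5 - 1), bp3 - bp5 + 1, 0,
                      "deletion_in_b", (bp5 - 1, bp5 - 1), (bp3 + 1, bp5),
                      ambiguity_width=len(m))
    sig = classify_mechanism(indel, donor, derived)
    assert sig.mechanism == "blunt_cnhej_or_ambiguous"
    assert any("intermediate" in n for n in sig.notes)
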