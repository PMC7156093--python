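"""Genome-pair simulator: determinism, event surgery, ground-truth fidelity."""

import numpy as np
import pytest

from temark.seqs import lcp_len, lcs_len, revcomp
from temark.simulate import (EventSpec, SimConfig, SimulationConfigError,
                             apply_event, default_event_suite, make_ancestor,
                             simulate_genome_pair, synthetic_consensus)


def _diff_single_edit(a: str, b: str):
    """Independent diff oracle for a genome pair differing by one edit.

    Returns the leftmost-normalised (deleted interval on A, replacement
    string in B); for identical sequences returns None.
    """
    if a == b:
        return None
    p = lcp_len(a, b)
    s = lcs_len(a, b)
    s = min(s, len(a) - p, len(b) - p)
    return (p + 1, len(a) - s), b[p : len(b) - s]


def test_same_seed_gives_byte_identical_outputs():
    cfgs = [SimConfig(n_chromosomes=2, chromosome_length=200_000,
                      te_copies_per_chromosome=3,
                      event_specs=default_event_suite(1), seed=1)
            for _ in range(2)]
    p1, p2 = simulate_genome_pair(cfgs[0]), simulate_genome_pair(cfgs[1])
    assert p1.genome_a == p2.genome_a
    assert p1.genome_b == p2.genome_b
    assert p1.truth_json() == p2.truth_json()


def test_zero_mutation_rate_plants_exact_consensus_copies():
    cfg = SimConfig(n_chromosomes=1, chromosome_length=100_000,
                    te_copies_per_chromosome=4, te_mutation_rate=0.0, seed=2)
    genome, te_ann, _ = make_ancestor(cfg)
    cons = cfg.library()[0].sequence
    for rec in te_ann:
        copy = genome[rec.chromosome][rec.start - 1 : rec.end]
        if rec.strand == "-":
            copy = revcomp(copy)
        assert copy == cons
        assert rec.divergence == 0.0


def test_ancestor_divergence_within_binomial_bounds():
    """10 planted copies; realised divergence ~ Binomial(L, rate)/L."""
    rate = 0.03
    cfg = SimConfig(n_chromosomes=2, chromosome_length=150_000,
                    te_copies_per_chromosome=5, te_mutation_rate=rate, seed=3)
    genome, te_ann, _ = make_ancestor(cfg)
    assert len(te_ann) == 10
    L = len(cfg.library()[0].sequence)
    sd = np.sqrt(rate * (1 - rate) / L)
    for rec in te_ann:
        assert abs(rec.divergence - rate) <= 3 * sd
        # recount substitutions directly against the consensus
        copy = genome[rec.chromosome][rec.start - 1 : rec.end]
        if rec.strand == "-":
            copy = revcomp(copy)
        nsub = sum(x != y for x, y in zip(copy, cfg.library()[0].sequence))
        assert nsub == round(rec.divergence * L)


def test_mmej_event_retains_single_microhomology_copy():
    """13 kb MMEJ deletion with 'GCGT': one copy survives at the junction."""
    cfg = SimConfig(n_chromosomes=1, chromosome_length=200_000,
                    te_copies_per_chromosome=0,
                    event_specs=[EventSpec("mmej", microhomology="GCGT",
                                           deletion_length=13_000)],
                    seed=4)
    pair = simulate_genome_pair(cfg)
    ev = pair.events[0]
    assert ev.microhomology == "GCGT"
    s, e = ev.donor_interval
    assert e - s + 1 == 13_000
    donor = pair.genome_a[ev.chromosome]
    assert donor[s - 1 : s + 3] == "GCGT"          # deleted segment starts with it
    assert donor[e : e + 4] == "GCGT"              # retained copy follows
    j = ev.recipient_interval[0]
    derived = pair.genome_b[ev.chromosome]
    window = derived[j - 5 : j + 7]
    assert window.count("GCGT") == 1


def test_empty_event_list_leaves_genome_unchanged():
    cfg = SimConfig(n_chromosomes=1, chromosome_length=80_000,
                    te_copies_per_chromosome=2, event_specs=[], seed=6)
    pair = simulate_genome_pair(cfg)
    assert pair.genome_a == pair.genome_b
    assert pair.events == []


def test_unequal_recombination_matches_string_surgery_oracle():
    cfg = SimConfig(n_chromosomes=1, chromosome_length=120_000,
                    te_copies_per_chromosome=0,
                    event_specs=[EventSpec("unequal_recombination",
                                           deletion_length=4000,
                                           repeat_length=150, insert_te=False)],
                    seed=7)
    pair = simulate_genome_pair(cfg)
    ev = pair.events[0]
    a = pair.genome_a[ev.chromosome]
    s, e = ev.edit_interval
    assert pair.genome_b[ev.chromosome] == a[: s - 1] + a[e:]
    assert ev.ambiguity_width >= 150   # crossover anywhere in the repeat


@pytest.mark.parametrize("mechanism", [
    "unequal_recombination", "ltr_recombination", "mmej", "sdmmej", "blunt",
    "tandem_duplication", "introgression", "te_insertion_full_empty",
    "inversion", "internal_deletion", "assembly_artifact",
])
def test_single_event_rederivable_by_independent_diff(mechanism):
    """Round trip: the planted edit is recoverable from the two genomes."""
    cfg = SimConfig(n_chromosomes=1, chromosome_length=150_000,
                    te_copies_per_chromosome=0,
                    event_specs=[EventSpec(mechanism, deletion_length=3000,
                                           repeat_unit_length=3000,
                                           foreign_length=1500, insert_te=False)],
                    seed=8)
    pair = simulate_genome_pair(cfg)
    ev = pair.events[0]
    diff = _diff_single_edit(pair.genome_a[ev.chromosome], pair.genome_b[ev.chromosome])
    assert diff is not None
    (ds, de), repl = diff
    # the diff oracle is leftmost-normalised by construction; the truth
    # interval agrees up to the recorded placement ambiguity
    assert abs(ds - ev.donor_interval[0]) <= ev.ambiguity_width
    net_change = (de - ds + 1) - len(repl)
    truth_change = (ev.edit_interval[1] - ev.edit_interval[0] + 1) - len(ev.replacement)
    assert net_change == truth_change


def test_one_event_per_mechanism_truth_and_locality(small_pair):
    """11 mechanisms -> 11 truth rows; genomes agree outside event footprints."""
    assert len(small_pair.events) == 11
    assert len({e.mechanism for e in small_pair.events}) == 11
    # independent whole-genome check: replaying the recorded edits onto A
    # reproduces B byte-for-byte
    for chrom in small_pair.genome_a:
        seq = small_pair.genome_a[chrom]
        for ev in sorted((e for e in small_pair.events if e.chromosome == chrom),
                         key=lambda e: -e.edit_interval[0]):
            s, e = ev.edit_interval
            seq = seq[: s - 1] + ev.replacement + seq[e:]
        assert seq == small_pair.genome_b[chrom]


def test_te_insertion_full_site_and_empty_site_tsd():
    cfg = SimConfig(n_chromosomes=1, chromosome_length=100_000,
                    te_copies_per_chromosome=0,
                    event_specs=[EventSpec("te_insertion_full_empty", tsd_length=5)],
                    seed=9)
    pair = simulate_genome_pair(cfg)
    ev = pair.events[0]
    tsd = ev.tsd
    assert len(tsd) == 5
    a = pair.genome_a[ev.chromosome]
    s, e = ev.edit_interval               # element + duplicated TSD copy
    assert a[s - 6 : s - 1] == tsd        # site copy upstream of the element
    assert a[e - 5 : e] == tsd            # duplicated copy at the element's 3' end
    # empty site in B: single copy
    b = pair.genome_b[ev.chromosome]
    j = ev.recipient_interval[0]
    assert b[j - 6 : j - 1] == tsd
    assert b[j - 1 : j + 4] != tsd


def test_assembly_artifact_writes_n_run(small_pair):
    ev = next(e for e in small_pair.events if e.mechanism == "assembly_artifact")
    j, k = ev.recipient_interval
    assert pair_seq(small_pair, ev)[j - 1 : k] == "N" * 500


def pair_seq(pair, ev):
    return pair.genome_b[ev.chromosome]


def test_colliding_explicit_positions_raise_with_event_ids():
    cfg = SimConfig(n_chromosomes=1, chromosome_length=100_000,
                    te_copies_per_chromosome=0,
                    event_specs=[EventSpec("blunt", event_id="evA", position=50_000),
                                 EventSpec("blunt", event_id="evB", position=50_100)],
                    seed=10)
    with pytest.raises(SimulationConfigError, match="evA.*evB|collide"):
        simulate_genome_pair(cfg)


def test_oversized_event_rejected_by_name():
    cfg = SimConfig(n_chromosomes=1, chromosome_length=30_000,
                    event_specs=[EventSpec("blunt", event_id="huge",
                                           deletion_length=20_000)],
                    seed=11)
    with pytest.raises(SimulationConfigError, match="huge"):
        simulate_genome_pair(cfg)


def test_apply_event_rejects_missing_microhomology(small_pair):
    import dataclasses

    ev = next(e for e in small_pair.events if e.mechanism == "mmej")
    broken = dataclasses.replace(ev, microhomology="AAAAAAAA")
    with pytest.raises(SimulationConfigError, match="microhomology"):
        apply_event(small_pair.genome_a, broken)


def test_consensus_library_invariant():
    with pytest.raises(ValueError):
        synthetic_consensus(length=500, ltr_length=300)
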