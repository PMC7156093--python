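"""Shared fixtures: consensus, small and large simulated genome pairs."""

from __future__ import annotations

import numpy as np
import pytest

from temark.annotate import AnnotationTrack
from temark.pipeline import PipelineConfig, run_pipeline
from temark.simulate import (SimConfig, default_event_suite, simulate_genome_pair,
                             synthetic_consensus)


@pytest.fixture(scope="session")
def consensus():
    return synthetic_consensus()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(99)


@pytest.fixture(scope="session")
def small_pair():
    """One event of every mechanism on two 300 kb chromosomes."""
    cfg = SimConfig(n_chromosomes=2, chromosome_length=300_000,
                    te_copies_per_chromosome=4,
                    event_specs=default_event_suite(1), seed=5)
    return simulate_genome_pair(cfg)


@pytest.fixture(scope="session")
def big_pair():
    """Six events of every mechanism (66 events) on six 400 kb chromosomes."""
    cfg = SimConfig(n_chromosomes=6, chromosome_length=400_000,
                    te_copies_per_chromosome=3,
                    event_specs=default_event_suite(6), seed=17)
    return simulate_genome_pair(cfg)


@pytest.fixture(scope="session")
def big_result(big_pair, consensus):
    """Full pipeline output for the 66-event pair (shared across tests)."""
    track = AnnotationTrack(records=list(big_pair.te_annotation))
    return run_pipeline(PipelineConfig(
        genome_a=big_pair.genome_a, genome_b=big_pair.genome_b,
        consensus=consensus, te_annotation=track))


def overlaps(iv, jv):
    return not (iv[1] < jv[0] or iv[0] > jv[1])


def locus_for_event(result, event):
    """The pipeline locus report overlapping one truth event, or None."""
    matches = [l for l in result.loci if l.chromosome == event.chromosome
               and overlaps(l.a_interval, event.donor_interval)]
    return matches[0] if matches else None
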