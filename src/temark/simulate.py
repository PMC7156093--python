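"""Mechanism-explicit synthetic genome-pair generator with ground truth.

This module emulates the comparison of two related genome assemblies
(a retained "donor" genome A, standing in for wild emmer, and a derived
genome B, standing in for bread wheat) at desk scale.  An ancestral
chromosome set carrying TE copies is generated, the donor genome is
augmented with the local sequence structures each rearrangement
mechanism requires (direct repeats, microhomology motifs, primer-repeat
templates, tandem units, target-site duplications), and the derived
genome is produced by applying the corresponding surgery.  Every planted
event is recorded with final coordinates on both genomes, so the whole
discovery pipeline can be scored against known truth.

Mechanisms
----------
``mmej``                  deletion between two short (<10 bp) direct repeats,
                          one copy retained at the junction
``sdmmej``                deletion with a templated ("filler") insertion
                          produced by one or two rounds of primer-repeat
                          annealing and fill-in synthesis
``blunt``                 deletion with no junction homology (C-NHEJ-like)
``unequal_recombination`` deletion between two long (>=100 bp, >=95%
                          identity) direct repeats, one copy retained
``ltr_recombination``     inter-LTR recombination of a full-length element
                          leaving a solo LTR
``tandem_duplication``    tandem array in A collapsed to one unit in B
``introgression``         replacement of a segment with foreign sequence
                          absent from the donor
``te_insertion_full_empty`` full TE site with TSDs in A, empty site with a
                          single TSD copy in B
``inversion``             segment reverse-complemented in B
``internal_deletion``     deletion inside a TE copy (element truncation)
``assembly_artifact``     segment replaced by a run of Ns in B

Coordinates are 1-based closed internally; BED output converts to
0-based half-open at the boundary.  All randomness flows from the single
``SimConfig.seed``; identical configs give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .retrieval import TEConsensus
from .seqs import lcp_len, lcs_len, mutate, random_dna, revcomp, to_bed

MECHANISMS = (
    "unequal_recombination",
    "ltr_recombination",
    "mmej",
    "sdmmej",
    "blunt",
    "tandem_duplication",
    "introgression",
    "te_insertion_full_empty",
    "inversion",
    "internal_deletion",
    "assembly_artifact",
)

#: mechanisms whose B-derivation is a pure deletion from A
DELETION_MECHANISMS = frozenset({
    "unequal_recombination", "ltr_recombination", "mmej", "blunt",
    "tandem_duplication", "te_insertion_full_empty", "internal_deletion",
})

_PLACEMENT_MARGIN = 4000  # bp of untouched background kept around every feature


class SimulationConfigError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


class Genome(dict):
    """Mapping of chromosome name -> sequence string, FASTA-writable."""

    def to_fasta(self, path: str | Path, width: int = 60) -> None:
        with open(path, "w") as fh:
            for name in self:
                fh.write(f">{name}\n")
                seq = self[name]
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")

    @classmethod
    def from_fasta(cls, path: str | Path) -> "Genome":
        from Bio import SeqIO

        return cls((rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta"))


@dataclass
class FeatureRecord:
    """One annotated feature on a genome (TE copy, LTR part, planted repeat)."""

    chromosome: str
    start: int
    end: int
    strand: str
    name: str
    feature_class: str  # "te" | "ltr" | "te_internal" | "planted_repeat" | "tsd"
    divergence: float = 0.0
    tsd: str = ""
    details: dict = field(default_factory=dict)

    def to_bed_line(self) -> str:
        s0, e0 = to_bed(self.start, self.end)
        return f"{self.chromosome}\t{s0}\t{e0}\t{self.name}:{self.feature_class}\t0\t{self.strand}"


@dataclass
class EventSpec:
    """Template for one rearrangement event.

    Only the fields relevant to the chosen mechanism are read.  When
    ``position`` is None the event is auto-placed; explicit positions are
    insertion points in background coordinates and are checked for
    collisions.
    """

    mechanism: str
    event_id: str = ""
    chromosome: str | None = None
    position: int | None = None
    deletion_length: int = 5000
    microhomology: str = ""
    microhomology_length: int = 4
    net_insertion_length: int = 3
    synthesis_rounds: int = 1
    repeat_length: int = 150
    repeat_identity: float = 0.99
    repeat_unit_length: int = 5000
    unit_divergence: float = 0.01
    foreign_length: int = 2000
    tsd_length: int | None = None
    n_run_length: int = 500
    insert_te: bool = True

    def __post_init__(self):
        if self.mechanism not in MECHANISMS:
            raise SimulationConfigError(f"unknown mechanism {self.mechanism!r}")
        if self.mechanism == "mmej":
            mh = self.microhomology or "N" * self.microhomology_length
            if not 1 <= len(mh) <= 9:
                raise SimulationConfigError("mmej microhomology must be 1-9 bp")
        if self.mechanism == "sdmmej":
            if self.net_insertion_length < 1:
                raise SimulationConfigError("sdmmej requires a non-empty net insertion")
            if self.synthesis_rounds not in (1, 2):
                raise SimulationConfigError("synthesis_rounds must be 1 or 2")

    def span(self, te_length: int) -> int:
        """Upper bound on the donor-genome footprint of this event."""
        te = te_length + 20 if self.insert_te else 0
        base = {
            "mmej": self.deletion_length + 18,
            "blunt": self.deletion_length,
            "sdmmej": self.deletion_length + 120,
            "unequal_recombination": self.deletion_length + 2 * self.repeat_length,
            "ltr_recombination": te_length,
            "tandem_duplication": 2 * self.repeat_unit_length,
            "introgression": self.deletion_length,
            "te_insertion_full_empty": te_length + 12,
            "inversion": self.deletion_length,
            "internal_deletion": te_length + 12,
            "assembly_artifact": self.deletion_length,
        }[self.mechanism]
        if self.mechanism in ("mmej", "blunt", "sdmmej", "introgression",
                              "inversion", "assembly_artifact") and self.insert_te:
            base = max(base, te + 400)
        return base


@dataclass
class RearrangementEvent:
    """Finalised ground-truth record of one planted event.

    ``donor_interval`` is the leftmost-normalised footprint on genome A
    (the placement convention when junction homology makes the exact
    breakpoint ambiguous); ``ambiguity_width`` is the number of
    equivalent placements minus one, i.e. the total left+right shift
    under which the derived genome is unchanged.  For repeat-mediated
    mechanisms the crossover point within the repeat is inherently
    undefined, so the ambiguity is the homologous repeat length.
    ``edit_interval``/``replacement`` describe the literal surgery that
    derives genome B, and ``recipient_interval`` the footprint of the
    replacement on B (degenerate, end = start - 1, for pure deletions).
    """

    event_id: str
    mechanism: str
    chromosome: str
    donor_interval: tuple[int, int]
    edit_interval: tuple[int, int]
    replacement: str
    recipient_interval: tuple[int, int] | None = None
    microhomology: str = ""
    net_insertion: str = ""
    primer_repeat: str = ""
    synthesis_rounds: int = 0
    repeat_unit_length: int | None = None
    tsd: str = ""
    ambiguity_width: int = 0
    details: dict = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["donor_interval"] = list(self.donor_interval)
        d["edit_interval"] = list(self.edit_interval)
        if self.recipient_interval is not None:
            d["recipient_interval"] = list(self.recipient_interval)
        return d


@dataclass
class SimConfig:
    """Study conditions for one simulated genome pair."""

    n_chromosomes: int = 2
    chromosome_length: int = 400_000
    gc_content: float = 0.46          # wheat-like GC
    te_library: list[TEConsensus] | None = None
    te_copies_per_chromosome: int = 6
    te_mutation_rate: float = 0.02
    tsd_length_range: tuple[int, int] = (4, 6)
    event_specs: list[EventSpec] = field(default_factory=list)
    n_gap_rate: float = 0.0
    seed: int = 0

    def library(self) -> list[TEConsensus]:
        return self.te_library if self.te_library else [synthetic_consensus()]

    def validate(self) -> None:
        if not 0 <= self.gc_content <= 1:
            raise SimulationConfigError("gc_content must be in [0,1]")
        if not 0 <= self.te_mutation_rate <= 0.2:
            raise SimulationConfigError("te_mutation_rate must be in [0, 0.2]")
        lo, hi = self.tsd_length_range
        if not 1 <= lo <= hi:
            raise SimulationConfigError("invalid tsd_length_range")
        te_len = max(len(c.sequence) for c in self.library())
        for spec in self.event_specs:
            span = spec.span(te_len)
            if span * 10 > self.chromosome_length:
                raise SimulationConfigError(
                    f"event {spec.event_id or spec.mechanism}: span {span} exceeds "
                    f"a tenth of chromosome_length {self.chromosome_length}"
                )


def synthetic_consensus(name: str = "TMK_consensus-1", length: int = 3000,
                        ltr_length: int = 300, gc: float = 0.46,
                        seed: int = 77) -> TEConsensus:
    """A synthetic LTR-retrotransposon consensus: LTR + internal + LTR.

    Stands in for a real family consensus at desk scale; both terminal
    repeats are identical in the consensus.
    """
    if 2 * ltr_length >= length:
        raise SimulationConfigError("2*ltr_length must be < consensus length")
    rng = np.random.default_rng(seed)
    ltr = random_dna(rng, ltr_length, gc)
    internal = random_dna(rng, length - 2 * ltr_length, gc)
    return TEConsensus(name=name, sequence=ltr + internal + ltr, ltr_length=ltr_length)


# --- payload construction ---------------------------------------------------

@dataclass
class _Payload:
    """Sequence spliced into the background at one site, plus metadata.

    Offsets are 0-based relative to the payload start.  ``edit`` is the
    (start_offset, end_offset, replacement) surgery deriving genome B,
    or None for features untouched in B (background TE copies).
    """

    seq: str
    features: list[tuple[int, int, str, str, str, float, str]] = field(default_factory=list)
    # (start_off, end_off, strand, name, feature_class, divergence, tsd)
    edit: tuple[int, int, str] | None = None
    event_extras: dict = field(default_factory=dict)


def _te_copy(rng: np.random.Generator, consensus: TEConsensus, rate: float):
    strand = "+" if rng.random() < 0.5 else "-"
    seq, nsub = mutate(rng, consensus.sequence, rate)
    if strand == "-":
        seq = revcomp(seq)
    return seq, strand, nsub / len(consensus.sequence)


def _te_with_tsd(rng, cfg: SimConfig, consensus: TEConsensus, site_context: str):
    lo, hi = cfg.tsd_length_range
    t = int(rng.integers(lo, hi + 1))
    tsd = site_context[-t:] if len(site_context) >= t else site_context
    te, strand, div = _te_copy(rng, consensus, cfg.te_mutation_rate)
    return te, tsd, strand, div


def _core_with_te(rng, cfg, consensus, length: int, insert_te: bool,
                  name: str) -> _Payload:
    """Random core sequence of the given length, optionally containing a
    full TE copy with TSDs (so the deleted segment anchors the pipeline)."""
    p = _Payload(seq="")
    if insert_te:
        te, strand, div = _te_copy(rng, consensus, cfg.te_mutation_rate)
        lo, hi = cfg.tsd_length_range
        t = int(rng.integers(lo, hi + 1))
        pad = length - len(te) - t
        if pad < 200:
            raise SimulationConfigError(
                f"{name}: deletion_length {length} too small for an internal TE copy")
        left = pad // 2
        filler_l = random_dna(rng, left, cfg.gc_content)
        filler_r = random_dna(rng, pad - left, cfg.gc_content)
        tsd = filler_l[-t:]
        p.seq = filler_l + te + tsd + filler_r
        p.features.append((left, left + len(te) - 1, strand, name, "te", div, tsd))
    else:
        p.seq = random_dna(rng, length, cfg.gc_content)
    return p


def _different_base(rng, *avoid: str) -> str:
    choices = [b for b in "ACGT" if b not in avoid]
    return choices[int(rng.integers(0, len(choices)))]


def _build_payload(spec: EventSpec, rng, cfg: SimConfig, consensus: TEConsensus,
                   site_before: str, site_after: str) -> _Payload:
    """Donor-side payload plus B-surgery for one event.

    ``site_before``/``site_after`` are short background context strings
    around the insertion point, used to pin junction guard bases (e.g. a
    blunt junction must not acquire chance microhomology by construction).
    """
    mech = spec.mechanism
    eid = spec.event_id

    if mech == "mmej":
        mh = spec.microhomology or random_dna(rng, spec.microhomology_length, cfg.gc_content)
        core = _core_with_te(rng, cfg, consensus, spec.deletion_length - len(mh),
                             spec.insert_te, eid)
        # deletion = mh + core ; retained right copy = trailing mh.  Guard
        # bases keep the realised junction repeat at exactly the configured
        # microhomology (chance extension could otherwise push a short
        # repeat past the <10 bp microhomology ceiling).
        cseq = list(core.seq)
        cseq[0] = _different_base(rng, site_after[0] if site_after else "")
        cseq[-1] = _different_base(rng, site_before[-1] if site_before else "")
        seq = mh + "".join(cseq) + mh
        p = _Payload(seq=seq)
        p.features = [(f[0] + len(mh), f[1] + len(mh), f[2], f[3], f[4], f[5], f[6])
                      for f in core.features]
        p.edit = (0, len(mh) + len(core.seq) - 1, "")
        p.event_extras = {"microhomology": mh}
        return p

    if mech == "blunt":
        core = _core_with_te(rng, cfg, consensus, spec.deletion_length, spec.insert_te, eid)
        seq = list(core.seq)
        # forbid chance junction homology at either end
        seq[0] = _different_base(rng, site_after[0] if site_after else "")
        seq[-1] = _different_base(rng, site_before[-1] if site_before else "")
        p = _Payload(seq="".join(seq), features=core.features)
        p.edit = (0, len(seq) - 1, "")
        return p

    if mech == "sdmmej":
        net = random_dna(rng, spec.net_insertion_length, cfg.gc_content)
        mh = random_dna(rng, 3, cfg.gc_content)
        core = _core_with_te(rng, cfg, consensus, spec.deletion_length, spec.insert_te, eid)
        # the deleted segment's edge bases must differ from the insertion's,
        # otherwise the junction is interpretation-equivalent to a shorter
        # blunt deletion and the templated insertion becomes unobservable
        cseq = list(core.seq)
        cseq[0] = _different_base(rng, net[0])
        cseq[-1] = _different_base(rng, net[-1])
        core.seq = "".join(cseq)
        spacer = random_dna(rng, 20, cfg.gc_content)
        if spec.synthesis_rounds == 1:
            primer = random_dna(rng, 2, cfg.gc_content)
            # donor: [primer+net+mh] template, spacer, primer | core | mh, tail
            tail = random_dna(rng, 6, cfg.gc_content)
            tpl = primer + net + mh
            guard = _different_base(rng, spacer[0])  # block longer-microhomology alternates
            left = tpl + spacer + primer
            right = mh + guard + tail
            seq = left + core.seq + right
            p = _Payload(seq=seq)
            p.features = [(f[0] + len(left), f[1] + len(left), f[2], f[3], f[4], f[5], f[6])
                          for f in core.features]
            p.edit = (len(left), len(left) + len(core.seq) - 1, net)
            p.event_extras = {"microhomology": mh, "net_insertion": net,
                              "primer_repeat": primer, "synthesis_rounds": 1}
            return p
        # two rounds, trans-annealing layout: the donor left flank ends with
        # the 1 bp primer p1; the retained right flank starts p1+t1 (round-1
        # template) and carries a downstream t1+t2 copy (round-2 template)
        # whose tail equals the right-flank prefix, providing the final
        # junction microhomology.  Net insertion = t1 + t2 minus that tail.
        if len(net) < 4:
            net = net + random_dna(rng, 4 - len(net), cfg.gc_content)
        p1 = random_dna(rng, 1, cfg.gc_content)
        t1 = net[:3]
        micro = p1 + net[:2]                   # = (p1 + t1)[:3] = right-flank prefix
        t2 = net[3:] + micro
        left_pad = random_dna(rng, 8, cfg.gc_content)
        left = left_pad + p1
        spacer17 = random_dna(rng, 17, cfg.gc_content)
        tail = random_dna(rng, 6, cfg.gc_content)
        right = p1 + t1 + spacer17 + t1 + t2 + tail
        seq = left + core.seq + right
        p = _Payload(seq=seq)
        p.features = [(f[0] + len(left), f[1] + len(left), f[2], f[3], f[4], f[5], f[6])
                      for f in core.features]
        p.edit = (len(left), len(left) + len(core.seq) - 1, net)
        p.event_extras = {"microhomology": micro, "net_insertion": net,
                          "primer_repeat": p1, "synthesis_rounds": 2}
        return p

    if mech == "unequal_recombination":
        rep = random_dna(rng, spec.repeat_length, cfg.gc_content)
        rep2, _ = mutate(rng, rep, 1.0 - spec.repeat_identity)
        core = _core_with_te(rng, cfg, consensus,
                             spec.deletion_length - spec.repeat_length,
                             spec.insert_te, eid)
        seq = rep + core.seq + rep2
        p = _Payload(seq=seq)
        off = len(rep)
        p.features = [(f[0] + off, f[1] + off, f[2], f[3], f[4], f[5], f[6])
                      for f in core.features]
        p.features.append((0, len(rep) - 1, "+", f"{eid}_repeat", "planted_repeat", 0.0, ""))
        p.features.append((len(rep) + len(core.seq), len(seq) - 1, "+",
                           f"{eid}_repeat", "planted_repeat",
                           1.0 - spec.repeat_identity, ""))
        p.edit = (len(rep), len(seq) - 1, "")   # delete core + second repeat
        p.event_extras = {"repeat_length": spec.repeat_length,
                          "repeat_identity": spec.repeat_identity}
        return p

    if mech == "ltr_recombination":
        te, strand, div = _te_copy(rng, consensus, min(cfg.te_mutation_rate, 0.005))
        L = consensus.ltr_length
        if not L:
            raise SimulationConfigError(f"{eid}: consensus has no annotated LTR")
        n = len(te)
        p = _Payload(seq=te)
        fam = consensus.name
        p.features.append((0, L - 1, strand, fam, "ltr", div, ""))
        p.features.append((L, n - L - 1, strand, fam, "te_internal", div, ""))
        p.features.append((n - L, n - 1, strand, fam, "ltr", div, ""))
        p.features.append((0, n - 1, strand, fam, "te", div, ""))
        p.edit = (L, n - 1, "")                 # delete internal + 3' LTR -> solo LTR
        p.event_extras = {"repeat_length": L, "family": fam, "strand": strand}
        return p

    if mech == "tandem_duplication":
        unit = _core_with_te(rng, cfg, consensus, spec.repeat_unit_length,
                             spec.insert_te, eid + "_u1")
        unit2_seq, _ = mutate(rng, unit.seq, spec.unit_divergence)
        seq = unit.seq + unit2_seq
        p = _Payload(seq=seq)
        p.features = list(unit.features)
        n1 = len(unit.seq)
        p.features += [(f[0] + n1, f[1] + n1, f[2], f[3].replace("_u1", "_u2"),
                        f[4], f[5], f[6]) for f in unit.features]
        p.edit = (n1, len(seq) - 1, "")         # collapse to a single unit in B
        p.event_extras = {"unit_length": n1, "copies_a": 2, "copies_b": 1,
                          "unit_identity": 1.0 - spec.unit_divergence}
        return p

    if mech == "introgression":
        core = _core_with_te(rng, cfg, consensus, spec.deletion_length,
                             spec.insert_te, eid)
        foreign = random_dna(rng, spec.foreign_length, cfg.gc_content)
        p = _Payload(seq=core.seq, features=core.features)
        p.edit = (0, len(core.seq) - 1, foreign)
        p.event_extras = {"foreign_length": spec.foreign_length}
        return p

    if mech == "te_insertion_full_empty":
        lo, hi = cfg.tsd_length_range
        t = spec.tsd_length or int(rng.integers(lo, hi + 1))
        tsd = site_before[-t:]
        te, strand, div = _te_copy(rng, consensus, cfg.te_mutation_rate)
        seq = te + tsd                          # site TSD precedes payload in background
        p = _Payload(seq=seq)
        p.features.append((0, len(te) - 1, strand, eid + "_te", "te", div, tsd))
        p.edit = (0, len(seq) - 1, "")          # empty site retains the single bg TSD
        p.event_extras = {"tsd": tsd}
        return p

    if mech == "inversion":
        core = _core_with_te(rng, cfg, consensus, spec.deletion_length,
                             spec.insert_te, eid)
        p = _Payload(seq=core.seq, features=core.features)
        p.edit = (0, len(core.seq) - 1, revcomp(core.seq))
        return p

    if mech == "internal_deletion":
        te, tsd, strand, div = _te_with_tsd(rng, cfg, consensus, site_before)
        seq = te + tsd
        p = _Payload(seq=seq)
        p.features.append((0, len(te) - 1, strand, eid + "_te", "te", div, tsd))
        n = len(te)
        s, e = int(n * 0.3), int(n * 0.7)       # remove the middle 40% of the element
        p.edit = (s, e - 1, "")
        return p

    if mech == "assembly_artifact":
        core = _core_with_te(rng, cfg, consensus, spec.deletion_length,
                             spec.insert_te, eid)
        p = _Payload(seq=core.seq, features=core.features)
        p.edit = (0, len(core.seq) - 1, "N" * spec.n_run_length)
        return p

    raise SimulationConfigError(f"unhandled mechanism {mech}")


# --- placement and assembly -------------------------------------------------

def _spaced_positions(rng, n: int, lo: int, hi: int, spans: list[int],
                      margin: int) -> list[int]:
    """n insertion points in [lo, hi) such that consecutive features
    (with the given spans) keep at least ``margin`` bp of background
    between them.  Deterministic given the rng state."""
    need = sum(spans) + (n + 1) * margin
    free = hi - lo - need
    if free < 0:
        raise SimulationConfigError(
            f"cannot place {n} features totalling {sum(spans)} bp in "
            f"{hi - lo} bp of background with margin {margin}")
    gaps = rng.multinomial(free, [1.0 / (n + 1)] * (n + 1)) if n else []
    pos = []
    cur = lo
    for i in range(n):
        cur += margin + int(gaps[i])
        pos.append(cur)
        # payload occupies no background; spacing only needs the margin
        cur += 0
    return pos


@dataclass
class SimulatedPair:
    """Output bundle of :func:`simulate_genome_pair`."""

    genome_a: Genome
    genome_b: Genome
    events: list[RearrangementEvent]
    te_annotation: list[FeatureRecord]      # on genome A
    repeat_annotation: list[FeatureRecord]  # planted long repeats, on genome A
    config: SimConfig

    def truth_json(self) -> str:
        return json.dumps([e.to_json_dict() for e in self.events], indent=1)

    def truth_bed(self) -> str:
        lines = []
        for e in self.events:
            s0, e0 = to_bed(*e.donor_interval)
            lines.append(f"{e.chromosome}\t{s0}\t{e0}\t{e.event_id}:{e.mechanism}\t0\t+")
        return "\n".join(lines) + ("\n" if lines else "")

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.genome_a.to_fasta(outdir / "genome_A.fa")
        self.genome_b.to_fasta(outdir / "genome_B.fa")
        (outdir / "truth.json").write_text(self.truth_json())
        (outdir / "truth.bed").write_text(self.truth_bed())
        with open(outdir / "te_annotation_A.bed", "w") as fh:
            for rec in self.te_annotation:
                fh.write(rec.to_bed_line() + "\n")


def deletion_ambiguity(seq: str, start: int, end: int) -> tuple[int, int]:
    """Placement freedom of deleting seq[start..end] (1-based closed).

    Returns ``(left_shift, right_shift)``: the deletion can slide left by
    up to ``left_shift`` and right by up to ``right_shift`` bases without
    changing the derived sequence.  Total ambiguity = left + right.
    """
    fwd = lcp_len(seq[start - 1 :], seq[end:])
    back = lcs_len(seq[: start - 1], seq[:end])
    return back, fwd


def make_ancestor(config: SimConfig):
    """Generate the ancestral genome with planted TE copies.

    Returns ``(genome, te_annotation, repeat_annotation)``.  Every TE
    copy is recorded with coordinates, strand, realised divergence from
    its consensus and its TSD; intact copies are flanked by identical
    TSDs by construction.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genome, te_ann, rep_ann, _ = _assemble(config, rng, include_events=False)
    return genome, te_ann, rep_ann


def _assemble(config: SimConfig, rng, include_events: bool):
    """Build genome A (donor) with background TEs and event payloads."""
    consensus = config.library()[0]
    te_len = len(consensus.sequence)
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chromosomes)]

    specs = list(config.event_specs) if include_events else []
    for i, s in enumerate(specs):
        if not s.event_id:
            s.event_id = f"ev{i + 1:03d}_{s.mechanism}"
    # round-robin chromosome assignment for auto-placed events
    per_chrom: dict[str, list[EventSpec]] = {c: [] for c in chrom_names}
    for i, s in enumerate(specs):
        c = s.chromosome or chrom_names[i % len(chrom_names)]
        if c not in per_chrom:
            raise SimulationConfigError(f"event {s.event_id}: unknown chromosome {c}")
        per_chrom[c].append(s)

    genome = Genome()
    te_ann: list[FeatureRecord] = []
    rep_ann: list[FeatureRecord] = []
    planned: list[tuple[str, int, _Payload, EventSpec | None]] = []

    for chrom in chrom_names:
        bg = random_dna(rng, config.chromosome_length, config.gc_content)
        items: list[tuple[int | None, EventSpec | None]] = [
            (None, None)] * config.te_copies_per_chromosome
        items += [(s.position, s) for s in per_chrom[chrom]]
        auto = [it for it in items if it[0] is None]
        fixed = [it for it in items if it[0] is not None]
        spans = [s.span(te_len) if s else te_len + 12 for _, s in auto]
        positions = _spaced_positions(rng, len(auto), 2000,
                                      config.chromosome_length - 2000,
                                      spans, _PLACEMENT_MARGIN)
        placed = sorted(
            [(p, s) for p, (_, s) in zip(positions, auto)] +
            [(p, s) for p, s in fixed],
            key=lambda x: x[0])
        # payloads are spliced at distinct background points and therefore
        # never interleave; two features whose insertion points leave fewer
        # than 600 bp of shared background have overlapping analytical
        # footprints and are rejected as colliding.
        for (p1, s1), (p2, s2) in zip(placed, placed[1:]):
            if p2 - p1 < 600:
                ids = [s.event_id if s else "background_te" for s in (s1, s2)]
                raise SimulationConfigError(f"events collide: {ids}")
        # assemble chromosome
        parts: list[str] = []
        cursor = 0
        a_pos = 0
        for p, s in placed:
            if p > config.chromosome_length:
                raise SimulationConfigError(
                    f"event {s.event_id if s else 'background_te'} exceeds chromosome bounds")
            parts.append(bg[cursor:p])
            a_pos += p - cursor
            site_before = bg[max(0, p - 30):p]
            site_after = bg[p : p + 30]
            if s is None:
                te, tsd, strand, div = _te_with_tsd(rng, config, consensus, site_before)
                payload = _Payload(seq=te + tsd)
                payload.features.append((0, len(te) - 1, strand,
                                         f"{chrom}_bgte_{p}", "te", div, tsd))
            else:
                payload = _build_payload(s, rng, config, consensus,
                                         site_before, site_after)
            start_a = a_pos + 1  # 1-based start of payload on A
            for (fs, fe, strand, name, fclass, div, tsd) in payload.features:
                rec = FeatureRecord(chrom, start_a + fs, start_a + fe, strand,
                                    name, fclass, div, tsd)
                (rep_ann if fclass == "planted_repeat" else te_ann).append(rec)
            planned.append((chrom, start_a, payload, s))
            parts.append(payload.seq)
            a_pos += len(payload.seq)
            cursor = p
        parts.append(bg[cursor:])
        genome[chrom] = "".join(parts)
    te_ann.sort(key=lambda r: (r.chromosome, r.start))
    return genome, te_ann, rep_ann, planned


def _finalize_event(genome_a: Genome, chrom: str, start_a: int,
                    payload: _Payload, spec: EventSpec) -> RearrangementEvent:
    """Turn a planted payload into a truth record with A coordinates."""
    es, ee, repl = payload.edit
    a_start, a_end = start_a + es, start_a + ee
    seq = genome_a[chrom]
    extras = dict(payload.event_extras)
    ev = RearrangementEvent(
        event_id=spec.event_id, mechanism=spec.mechanism, chromosome=chrom,
        donor_interval=(a_start, a_end), edit_interval=(a_start, a_end),
        replacement=repl,
        microhomology=extras.pop("microhomology", ""),
        net_insertion=extras.pop("net_insertion", ""),
        primer_repeat=extras.pop("primer_repeat", ""),
        synthesis_rounds=extras.pop("synthesis_rounds", 0),
        repeat_unit_length=extras.pop("unit_length", None),
        tsd=extras.pop("tsd", ""),
        details=extras,
    )
    if spec.mechanism in DELETION_MECHANISMS and not repl:
        back, fwd = deletion_ambiguity(seq, a_start, a_end)
        if spec.mechanism in ("unequal_recombination", "ltr_recombination",
                              "tandem_duplication"):
            # crossover position within the homologous repeat is undefined
            amb = extras.get("repeat_length") or ev.repeat_unit_length or (back + fwd)
            ev.ambiguity_width = max(int(amb), back + fwd)
            ev.donor_interval = (a_start - back, a_end - back)
        else:
            ev.ambiguity_width = back + fwd
            ev.donor_interval = (a_start - back, a_end - back)
    elif repl and spec.mechanism in ("sdmmej", "introgression", "assembly_artifact",
                                     "inversion"):
        # chance agreement between the deleted edge and the written-in
        # sequence shifts where the breakpoint can be placed
        deleted = seq[a_start - 1 : a_end]
        ev.ambiguity_width = lcp_len(deleted, repl) + lcs_len(deleted, repl)
    return ev


def apply_event(genome: Genome, event: RearrangementEvent) -> tuple[Genome, RearrangementEvent]:
    """Apply one event's B-side surgery to a genome.

    The genome differs from the input only within the event's footprint.
    For junction mechanisms the planted motifs are verified to be present
    at the site before surgery; an unsatisfiable event raises
    :class:`SimulationConfigError` naming the event.
    """
    chrom = event.chromosome
    if chrom not in genome:
        raise SimulationConfigError(f"event {event.event_id}: no chromosome {chrom}")
    seq = genome[chrom]
    s, e = event.edit_interval
    if not (1 <= s <= e <= len(seq)):
        raise SimulationConfigError(
            f"event {event.event_id}: interval {s}-{e} outside chromosome bounds")
    if event.mechanism == "mmej":
        mh = event.microhomology
        deleted = seq[s - 1 : e]
        right = seq[e : e + len(mh)]
        if not (deleted.startswith(mh) and right == mh):
            raise SimulationConfigError(
                f"event {event.event_id}: required microhomology {mh!r} absent at site")
    if event.mechanism == "sdmmej" and event.net_insertion != event.replacement:
        raise SimulationConfigError(
            f"event {event.event_id}: replacement does not equal the net insertion")
    out = Genome(genome)
    out[chrom] = seq[: s - 1] + event.replacement + seq[e:]
    final = dataclasses.replace(event)
    return out, final


def simulate_genome_pair(config: SimConfig) -> SimulatedPair:
    """Generate a donor/derived genome pair with full ground truth.

    Genome A carries every planted structure; genome B is derived by
    applying each event's surgery.  Events never overlap one another's
    footprints (placement guarantees spacing; explicit positions are
    checked).  The truth table records, per event, the leftmost-
    normalised donor interval, the edit actually applied, the realised
    junction ambiguity and the final coordinates on both genomes.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genome_a, te_ann, rep_ann, planned = _assemble(config, rng, include_events=True)

    events: list[RearrangementEvent] = []
    for chrom, start_a, payload, spec in planned:
        if spec is None:
            continue
        events.append(_finalize_event(genome_a, chrom, start_a, payload, spec))

    # derive genome B: apply edits right-to-left so coordinates stay valid,
    # then recompute B coordinates left-to-right from the length deltas.
    genome_b = Genome(genome_a)
    for ev in sorted(events, key=lambda e: (e.chromosome, -e.edit_interval[0])):
        genome_b, _ = apply_event(genome_b, ev)
    for chrom in genome_a:
        offset = 0
        for ev in sorted((e for e in events if e.chromosome == chrom),
                         key=lambda e: e.edit_interval[0]):
            s, e = ev.edit_interval
            b_start = s + offset
            ev.recipient_interval = (b_start, b_start + len(ev.replacement) - 1)
            offset += len(ev.replacement) - (e - s + 1)
    return SimulatedPair(genome_a, genome_b, events, te_ann, rep_ann, config)


def default_event_suite(n_per_mechanism: int = 1,
                        mechanisms: tuple[str, ...] = MECHANISMS,
                        deletion_length: int = 5000) -> list[EventSpec]:
    """One EventSpec per requested mechanism, repeated n times.

    Desk-scale defaults: 5 kb deletions, 150 bp recombination repeats at
    99% identity, 5 kb tandem units, 2 kb foreign introgression inserts.
    """
    specs = []
    for i in range(n_per_mechanism):
        for mech in mechanisms:
            specs.append(EventSpec(mechanism=mech, deletion_length=deletion_length,
                                   synthesis_rounds=1))
    return specs


def replay_junction(left_flank: str, deleted: str, right_flank: str,
                    net_insertion: str = "") -> str:
    """Derived junction produced by deleting ``deleted`` and writing in
    ``net_insertion`` -- the string-surgery oracle used to verify junction
    reconstructions byte-for-byte."""
    return left_flank + net_insertion + right_flank
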