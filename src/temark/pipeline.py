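"""End-to-end orchestration: retrieve -> match -> walk -> call -> classify.

One call to :func:`run_pipeline` reproduces the whole TE-anchored
comparison of two assemblies: retrieve insertions of the anchor family
from both genomes, pair them by flank similarity, locate orthologous
loci of the donor-specific ones by chromosome walking, classify each
polymorphism source, call indel breakpoints and lengths at similarity-
block borders, detect tandem copy-number variation and inversions,
assign a repair mechanism to each junction, and annotate TE content and
breakpoint context.  Assembly-artifact loci (Ns at a breakpoint) are
routed to an exclusion report rather than the indel table.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .annotate import AnnotationTrack, breakpoint_context, te_content
from .breakpoints import IndelCall, call_indel, detect_copy_number_variation
from .junctions import JunctionSignature, classify_mechanism
from .ortholocus import (PolymorphismCall, classify_matched_pair,
                         classify_polymorphism, match_insertions_across_genomes)
from .retrieval import TEConsensus, TEInsertion, retrieve_insertions
from .seqs import to_bed
from .simulate import Genome

log = logging.getLogger("temark.pipeline")


class PipelineError(RuntimeError):
    """A stage failure, annotated with the stage and locus involved."""

    def __init__(self, stage: str, locus: str, original: Exception):
        super().__init__(f"stage {stage!r} failed at locus {locus!r}: {original}")
        self.stage, self.locus = stage, locus


@dataclass
class PipelineConfig:
    genome_a: Genome | str
    genome_b: Genome | str
    consensus: TEConsensus
    te_annotation: AnnotationTrack | None = None
    reference_genomes: tuple = ()
    outdir: str | None = None
    flank: int = 500
    min_block: int = 100
    min_identity: float = 0.95
    flank_match_cutoff: float = 0.5
    walk_step: int = 5000
    walk_max_extent: int = 5_000_000


@dataclass
class LocusReport:
    """One row of the final summary table."""

    locus_id: str
    chromosome: str
    a_interval: tuple[int, int]
    b_interval: tuple[int, int]
    a_length: int
    b_length: int
    rearrangement_type: str
    category: str
    mechanism: str = ""
    te_percent: float | None = None
    breakpoint5_context: str = ""
    breakpoint3_context: str = ""
    ambiguity_width: int = 0
    flags: list[str] = field(default_factory=list)


@dataclass
class PipelineResult:
    insertions_a: list[TEInsertion]
    insertions_b: list[TEInsertion]
    pairs: list
    monomorphic: int
    polymorphism_calls: list[PolymorphismCall]
    loci: list[LocusReport]
    excluded: list[LocusReport]
    signatures: dict[str, JunctionSignature]

    def summary_frame(self) -> pd.DataFrame:
        rows = [dataclasses.asdict(l) for l in self.loci]
        return pd.DataFrame(rows)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        df = self.summary_frame()
        with open(outdir / "summary.tsv", "w") as fh:
            fh.write("# coordinates are 1-based closed; lengths = end - start + 1\n")
            df.to_csv(fh, sep="\t", index=False)
        for name, loci, genome_key in (("loci_A.bed", self.loci, "a_interval"),
                                       ("loci_B.bed", self.loci, "b_interval")):
            with open(outdir / name, "w") as fh:
                for l in loci:
                    iv = getattr(l, genome_key)
                    if iv[1] < iv[0]:
                        continue
                    s0, e0 = to_bed(*iv)
                    fh.write(f"{l.chromosome}\t{s0}\t{e0}\t{l.locus_id}:"
                             f"{l.rearrangement_type}\t0\t+\n")
        detail = {
            "n_insertions_a": len(self.insertions_a),
            "n_insertions_b": len(self.insertions_b),
            "n_monomorphic": self.monomorphic,
            "polymorphism_calls": [dataclasses.asdict(c) if not isinstance(c, dict) else c
                                   for c in map(_call_dict, self.polymorphism_calls)],
            "excluded": [dataclasses.asdict(l) for l in self.excluded],
        }
        (outdir / "detail.json").write_text(json.dumps(detail, indent=1, default=str))


def _call_dict(call: PolymorphismCall) -> dict:
    d = dataclasses.asdict(call)
    d["indel"] = None if call.indel is None else {
        "a_interval": list(call.indel.a_interval),
        "b_interval": list(call.indel.b_interval),
        "type": call.indel.rearrangement_type,
        "ambiguity_width": call.indel.ambiguity_width,
        "flags": call.indel.flags,
    }
    return d


def _load_genome(g) -> Genome:
    return g if isinstance(g, Genome) else Genome.from_fasta(g)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the full comparison; see module docstring for the stages."""
    genome_a = _load_genome(config.genome_a)
    genome_b = _load_genome(config.genome_b)
    refs = tuple(_load_genome(r) for r in config.reference_genomes)
    cons = config.consensus

    log.info("retrieving insertions (consensus %s, %d bp)", cons.name, len(cons))
    try:
        ins_a = retrieve_insertions(genome_a, cons, flank=config.flank)
        ins_b = retrieve_insertions(genome_b, cons, flank=config.flank)
    except Exception as exc:  # pragma: no cover - defensive
        raise PipelineError("retrieve", "-", exc) from exc
    log.info("retrieved %d donor / %d derived insertions", len(ins_a), len(ins_b))

    pairs, unmatched_a, unmatched_b, match_flags = match_insertions_across_genomes(
        ins_a, ins_b, config.flank_match_cutoff)

    calls: list[PolymorphismCall] = []
    monomorphic = 0
    for a, b, score in pairs:
        call = classify_matched_pair(a, b, cons)
        if call.category == "monomorphic":
            monomorphic += 1
        elif call.category == "internal_deletion":
            # deletion within the element (including solo-LTR formation):
            # characterise the junction like any other indel locus
            try:
                pad = 1500
                seq_a, seq_b = genome_a[a.chromosome], genome_b[b.chromosome]
                a_lo = max(1, a.start - pad)
                b_lo = max(1, b.start - pad)
                call.indel = call_indel(
                    seq_a[a_lo - 1 : min(len(seq_a), a.end + pad)],
                    seq_b[b_lo - 1 : min(len(seq_b), b.end + pad)],
                    locus_id=a.id, a_offset=a_lo, b_offset=b_lo,
                    min_block=config.min_block, min_identity=config.min_identity)
                call.ortholocus_chromosome = b.chromosome
            except Exception as exc:
                raise PipelineError("call_indel", a.id, exc) from exc
        calls.append(call)
    for ins in unmatched_a:
        if ins.id in match_flags:
            continue  # copy-number candidates are handled on the whole array
        try:
            call = classify_polymorphism(ins, genome_a, genome_b, cons)
        except Exception as exc:
            raise PipelineError("classify_polymorphism", ins.id, exc) from exc
        calls.append(call)

    loci: list[LocusReport] = []
    excluded: list[LocusReport] = []
    signatures: dict[str, JunctionSignature] = {}
    seen_intervals: list[tuple[str, int, int]] = []
    ins_by_id = {x.id: x for x in ins_a}
    ins_b_by_id = {x.id: x for x in ins_b}

    # two donor insertions sharing one counterpart: examine the whole array
    for ins_id, info in match_flags.items():
        ins = ins_by_id[ins_id]
        partner = ins_by_id[info["a_partner"]]
        b_ins = ins_b_by_id[info["b_match"]]
        call = PolymorphismCall(insertion_id=ins_id, match_id=info["b_match"],
                                category="long_indel_candidate",
                                flags=["cnv_review"],
                                evidence=[f"shares counterpart {info['b_match']} "
                                          f"with {info['a_partner']}"])
        calls.append(call)
        try:
            chrom = ins.chromosome
            seq_a, seq_b = genome_a[chrom], genome_b[b_ins.chromosome]
            lo = min(ins.start, partner.start)
            hi = max(ins.end, partner.end)
            span = hi - lo + 1
            a_lo, a_hi = max(1, lo - span - 2000), min(len(seq_a), hi + span + 2000)
            b_lo = max(1, b_ins.start - span - 2000)
            b_hi = min(len(seq_b), b_ins.end + span + 2000)
            cnv = detect_copy_number_variation(
                seq_a[a_lo - 1 : a_hi], seq_b[b_lo - 1 : b_hi], locus_id=ins_id,
                min_block=config.min_block, min_identity=config.min_identity)
        except Exception as exc:
            raise PipelineError("cnv", ins_id, exc) from exc
        if cnv.copies_a == cnv.copies_b or cnv.unit_interval_a is None:
            call.evidence.append("no copy-number difference detected")
            continue
        unit_len = cnv.unit_interval_a[1] - cnv.unit_interval_a[0] + 1
        u0 = a_lo + cnv.unit_interval_a[0] - 1
        report = LocusReport(
            locus_id=ins_id, chromosome=chrom,
            a_interval=(u0, u0 + cnv.copies_a * unit_len - 1),
            b_interval=(b_lo, b_hi),
            a_length=cnv.copies_a * unit_len, b_length=cnv.copies_b * unit_len,
            rearrangement_type="copy_number_variation",
            category="long_indel_candidate", mechanism="cnv_duplication",
            ambiguity_width=unit_len,
            flags=[f"copies {cnv.copies_a}:{cnv.copies_b}", "cnv_review"],
        )
        loci.append(report)
        seen_intervals.append((chrom, *report.a_interval))
    for call in calls:
        if call.indel is None:
            continue
        indel = call.indel
        ins = ins_by_id[call.insertion_id]
        chrom = ins.chromosome
        key = (chrom, *indel.a_interval)
        # two insertions inside one deleted segment yield one locus
        if any(k[0] == chrom and not (indel.a_interval[1] < k[1] or
                                      indel.a_interval[0] > k[2])
               for k in seen_intervals):
            continue
        seen_intervals.append(key)
        report = LocusReport(
            locus_id=call.insertion_id, chromosome=chrom,
            a_interval=indel.a_interval, b_interval=indel.b_interval,
            a_length=indel.a_length, b_length=indel.b_length,
            rearrangement_type=indel.rearrangement_type,
            category=call.category, ambiguity_width=indel.ambiguity_width,
            flags=list(call.flags) + list(indel.flags),
        )
        if call.category == "assembly_artifact":
            excluded.append(report)
            continue
        seq_a = genome_a[chrom]
        seq_b = genome_b[call.ortholocus_chromosome or chrom]
        # copy-number check on a window wide enough to hold the whole array
        if "cnv_review" in call.flags or indel.ambiguity_width > 5 * config.min_block:
            try:
                pad = indel.ambiguity_width + 2000
                a_lo = max(1, indel.a_interval[0] - pad)
                a_hi = min(len(seq_a), indel.a_interval[1] + pad)
                b_lo = max(1, indel.b_interval[0] - pad)
                b_hi = min(len(seq_b), indel.b_interval[1] + pad)
                cnv = detect_copy_number_variation(
                    seq_a[a_lo - 1 : a_hi], seq_b[b_lo - 1 : b_hi],
                    locus_id=call.insertion_id,
                    min_block=config.min_block, min_identity=config.min_identity)
                if cnv.copies_a != cnv.copies_b and cnv.copies_a > 1:
                    report.rearrangement_type = "copy_number_variation"
                    indel.rearrangement_type = "copy_number_variation"
                    report.flags.append(f"copies {cnv.copies_a}:{cnv.copies_b}")
            except Exception as exc:
                raise PipelineError("cnv", call.insertion_id, exc) from exc
        if report.rearrangement_type in ("deletion_in_b", "replacement",
                                         "copy_number_variation") \
                and call.category != "empty_site_tsd":
            try:
                ann = None
                if config.te_annotation is not None:
                    ann = config.te_annotation.on(chrom)
                sig = classify_mechanism(indel, seq_a, seq_b,
                                         te_annotation=ann,
                                         donor_genome=genome_a,
                                         reference_genomes=refs)
                signatures[call.insertion_id] = sig
                report.mechanism = sig.mechanism
            except Exception as exc:
                raise PipelineError("classify_mechanism", call.insertion_id, exc) from exc
        if config.te_annotation is not None and indel.a_length > 0:
            report.te_percent = te_content(indel.a_interval, config.te_annotation, chrom)
            for which, pos in (("breakpoint5_context", indel.a_interval[0]),
                               ("breakpoint3_context", indel.a_interval[1])):
                rec, dist, status = breakpoint_context(
                    pos, config.te_annotation, chrom,
                    consensus_lengths={cons.name: len(cons)})
                if rec is not None:
                    setattr(report, which, f"{rec.name}:{rec.feature_class}"
                                           f"@{dist}bp:{status}")
        loci.append(report)

    result = PipelineResult(ins_a, ins_b, pairs, monomorphic, calls, loci,
                            excluded, signatures)
    if config.outdir:
        result.write(config.outdir)
    return result
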