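"""TE-content and breakpoint-context annotation from interval files.

Consumes standard interval annotations (BED, 0-based half-open, or
GFF3, 1-based closed) and answers the two questions the rearrangement
reports need: what fraction of a locus is TE-derived, and what feature
does a breakpoint fall in (or sit near), with an intact/truncated
judgement against the family consensus length when one is known.
Coordinates are converted to the package-wide 1-based closed convention
at this boundary layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd


@dataclass
class AnnotationRecord:
    chromosome: str
    start: int          # 1-based closed
    end: int
    name: str
    feature_class: str
    strand: str = "+"


@dataclass
class AnnotationTrack:
    """A sorted set of interval features on one or more chromosomes."""

    records: list = field(default_factory=list)
    source_format: str = "memory"

    def __post_init__(self):
        self.records = sorted(self.records, key=lambda r: (r.chromosome, r.start, r.end))

    @classmethod
    def from_bed(cls, path: str | Path) -> "AnnotationTrack":
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         names=["chrom", "start", "end", "name", "score", "strand"],
                         usecols=range(6), dtype={"chrom": str})
        recs = []
        for row in df.itertuples(index=False):
            name = str(row.name) if not pd.isna(row.name) else "feature"
            fclass = name.rsplit(":", 1)[1] if ":" in name else "feature"
            recs.append(AnnotationRecord(str(row.chrom), int(row.start) + 1,
                                         int(row.end), name.rsplit(":", 1)[0],
                                         fclass,
                                         str(row.strand) if not pd.isna(row.strand) else "+"))
        return cls(records=recs, source_format="BED")

    @classmethod
    def from_gff3(cls, path: str | Path, classes: list[str] | None = None) -> "AnnotationTrack":
        cols = ["chrom", "source", "type", "start", "end", "score", "strand",
                "phase", "attributes"]
        df = pd.read_csv(path, sep="\t", header=None, comment="#", names=cols,
                         dtype={"chrom": str})
        recs = []
        for row in df.itertuples(index=False):
            if classes and row.type not in classes:
                continue
            attrs = dict(kv.split("=", 1) for kv in str(row.attributes).split(";")
                         if "=" in kv)
            recs.append(AnnotationRecord(str(row.chrom), int(row.start), int(row.end),
                                         attrs.get("Name", attrs.get("ID", row.type)),
                                         str(row.type), str(row.strand)))
        return cls(records=recs, source_format="GFF3")

    def on(self, chromosome: str, classes: tuple[str, ...] | None = None):
        return [r for r in self.records if r.chromosome == chromosome
                and (classes is None or r.feature_class in classes)]


def te_content(interval: tuple[int, int], track: AnnotationTrack,
               chromosome: str, classes: tuple[str, ...] | None = None) -> float:
    """Percentage of interval bases covered by features, to two decimals.

    Overlapping features are unioned and clipped to the query interval;
    the result is in [0, 100] and additive over a partition of the query
    when features are clipped per part.
    """
    lo, hi = interval
    if hi < lo:
        raise ValueError("invalid interval")
    covered = 0
    last_end = lo - 1
    for r in track.on(chromosome, classes):
        s, e = max(r.start, lo, last_end + 1), min(r.end, hi)
        if e >= s:
            covered += e - s + 1
            last_end = max(last_end, e)
    return round(100.0 * covered / (hi - lo + 1), 2)


def breakpoint_context(
    position: int,
    track: AnnotationTrack,
    chromosome: str,
    consensus_lengths: dict[str, int] | None = None,
    window: int = 1000,
    intact_fraction: float = 0.9,
):
    """Feature at (or nearest to) a breakpoint, with intactness.

    Returns ``(record, distance, status)``: distance 0 when the
    breakpoint lies inside the feature, otherwise the gap to the nearest
    feature within ``window`` (or ``(None, None, "unannotated")``).
    Status is "intact" when the feature reaches ``intact_fraction`` of
    its family consensus length, "truncated" when it falls short, and
    "unknown" without a consensus length.
    """
    best = None
    best_dist = window + 1
    for r in track.on(chromosome):
        if r.start <= position <= r.end:
            best, best_dist = r, 0
            break
        dist = r.start - position if r.start > position else position - r.end
        if 0 < dist < best_dist:
            best, best_dist = r, dist
    if best is None:
        return None, None, "unannotated"
    status = "unknown"
    if consensus_lengths:
        clen = consensus_lengths.get(best.name) or consensus_lengths.get(
            best.name.split(":")[0])
        if clen:
            status = "intact" if (best.end - best.start + 1) >= intact_fraction * clen \
                else "truncated"
    return best, best_dist, status
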