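"""Published wheat rearrangement loci and synthetic worked junctions.

``PUBLISHED_LOCI`` transcribes the breakpoint coordinates of the eleven
curated large-scale rearrangement loci between the wild emmer
(WEWSeq v1.0) and bread wheat (IWGSC RefSeq v1.0) assemblies on
chromosomes 3B and 5B, with the reported locus lengths on each genome
(length = end - start + 1, the package-wide 1-based closed convention).

``worked_junction`` builds SYNTHETIC junction contexts for the loci
whose junction motifs were characterised at base resolution.  The
published motifs (microhomologies, primer repeats, templated
insertions and their spacings) are embedded exactly; all filler
sequence is arbitrary seeded random DNA, deliberately screened so that
it cannot create a second copy of any signature motif.  These contexts
reproduce the published junction *logic*, not the wheat sequence
itself, and are the desk-scale inputs for the microhomology and
SD-MMEJ worked examples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .seqs import random_dna, revcomp


@dataclass(frozen=True)
class PublishedLocus:
    locus_id: str
    chromosome: str
    emmer_start: int
    emmer_end: int
    bread_start: int
    bread_end: int
    emmer_length: int
    bread_length: int
    rearrangement: str


PUBLISHED_LOCI: tuple[PublishedLocus, ...] = (
    PublishedLocus("5B_1", "5B", 566939353, 567135082, 561057394, 561064945,
                   195730, 7552, "deletion_in_b"),
    PublishedLocus("3B_1", "3B", 774200469, 774452950, 760803787, 760805537,
                   252482, 1751, "deletion_in_b"),
    PublishedLocus("5B_2", "5B", 516702290, 516721374, 511383608, 511385023,
                   19085, 1416, "deletion_in_b"),
    PublishedLocus("5B_3", "5B", 363487255, 363551431, 349934346, 349934349,
                   64177, 4, "deletion_in_b"),
    PublishedLocus("5B_4", "5B", 587350647, 587364130, 581381548, 581381551,
                   13484, 4, "deletion_in_b"),
    PublishedLocus("3B_2", "3B", 284755035, 284771490, 286353814, 286353819,
                   16456, 6, "deletion_in_b"),
    PublishedLocus("3B_3", "3B", 493386824, 493410158, 482234389, 482234390,
                   23335, 2, "deletion_in_b"),
    PublishedLocus("3B_4", "3B", 538946011, 540047920, 527682008, 527682029,
                   1101910, 22, "deletion_in_b"),
    PublishedLocus("3B_5", "3B", 606914695, 606946995, 596314588, 596314620,
                   32301, 33, "deletion_in_b"),
    PublishedLocus("5B_5", "5B", 610009239, 610050693, 603942312, 603952982,
                   41455, 10671, "introgression"),
    PublishedLocus("5B_6", "5B", 84661892, 85585936, 81624361, 82045980,
                   924045, 421620, "copy_number_variation"),
)


@dataclass(frozen=True)
class WorkedJunction:
    """Synthetic donor/derived junction contexts for one worked locus."""

    locus_id: str
    donor_left: str      # retained left flank (donor genome)
    deleted: str         # deleted segment (leftmost placement)
    donor_right: str     # retained right flank
    net_insertion: str   # sequence written in at the derived junction

    @property
    def derived_junction(self) -> str:
        return self.donor_left + self.net_insertion + self.donor_right

    @property
    def donor_context(self) -> str:
        return self.donor_left + self.deleted + self.donor_right


def _clean_filler(rng: np.random.Generator, n: int, forbidden: tuple[str, ...]) -> str:
    """Random filler screened against forbidden motifs (and their reverse
    complements).  Motifs shorter than 3 bp are ignored -- they cannot be
    excluded from random sequence and are pinned by guard bases instead."""
    long_motifs = [m for m in forbidden if len(m) >= 3]
    bad = tuple(long_motifs) + tuple(revcomp(m) for m in long_motifs)
    for _ in range(500):
        s = random_dna(rng, n)
        if not any(m in s for m in bad):
            return s
    raise RuntimeError("could not build clean filler")  # pragma: no cover


def _guard(rng: np.random.Generator, *avoid: str) -> str:
    choices = [b for b in "ACGT" if b not in avoid]
    return choices[int(rng.integers(0, len(choices)))]


def worked_junction(locus_id: str, flank: int = 60, deleted_length: int = 300,
                    seed: int = 2020) -> WorkedJunction:
    """Synthetic junction context embedding a locus's published motifs.

    Supported loci: 5B_3 and 5B_4 (MMEJ microhomologies 'A' and
    'GCGT'), 3B_2 (one-round SD-MMEJ: primer 'A' on the 'AAATTTG'
    template 22 bp upstream, synthesis 'AATTTG', insertion 'AAT',
    microhomology 'TTG'), 3B_4 (two-round SD-MMEJ: primer 'G', first
    tract 'TCT', second template 20 bp downstream of the 3' 'G',
    14 bp insertion 'TCTAGCACAACTCC', microhomology 'GTC') and 3B_5
    (apparently blunt; primer 'GA'/'TC' on the 'GATC' motif 29 bp
    downstream of the 3' breakpoint).
    """
    rng = np.random.default_rng(seed)
    if locus_id in ("5B_3", "5B_4"):
        mh = "A" if locus_id == "5B_3" else "GCGT"
        core = _clean_filler(rng, deleted_length - len(mh), (mh,))
        right_tail = _clean_filler(rng, flank - len(mh), (mh,))
        # deleted segment starts with the repeat (leftmost placement); the
        # retained right flank carries the single remaining copy.  Guard
        # bases pin the repeat length exactly: no leftward extension (the
        # left flank must not end with the motif's last base or mirror the
        # deleted segment's end) and no rightward extension (the bases
        # after the two copies must differ).
        g = _guard(rng, right_tail[0] if right_tail else "")
        deleted = mh + g + core[1:]
        right = mh + right_tail
        left = _clean_filler(rng, flank, (mh,))
        left = left[:-1] + _guard(rng, mh[-1], deleted[-1])
        return WorkedJunction(locus_id, left, deleted, right, "")

    if locus_id == "3B_2":
        # screen fillers only against the long signature motifs; a second
        # copy of one of these could create an equally-ranked alternate
        motifs = ("AAATTTG", "AATTTG")
        spacer = _clean_filler(rng, 22, motifs)
        spacer = spacer[:-1] + _guard(rng, "A", spacer[-2])
        left_pad = _clean_filler(rng, flank - 22 - 8, motifs)
        left = left_pad + "AAATTTG" + spacer + "A"
        deleted = _clean_filler(rng, deleted_length, motifs)
        deleted = _guard(rng, "A") + deleted[1:]             # keep the 'A' micro unique
        tail = _clean_filler(rng, flank - 4, motifs)
        right = "TTG" + _guard(rng, spacer[0], "G") + tail   # block micro extension
        return WorkedJunction(locus_id, left, deleted, right, "AAT")

    if locus_id == "3B_4":
        net = "TCTAGCACAACTCC"
        motifs = (net, "TCTAGCACAACTCCGTC")
        left_pad = _clean_filler(rng, flank - 1, motifs)
        left = left_pad[:-1] + _guard(rng, "G") + "G"
        deleted = _clean_filler(rng, deleted_length, motifs)
        deleted = _guard(rng, "G") + deleted[1:-1] + _guard(rng, "G")
        spacer = _clean_filler(rng, 17, motifs)
        spacer = spacer[:-1] + _guard(rng, "G", spacer[-2])  # no 'G'+template doubles
        tail = _clean_filler(rng, flank - 38, motifs)
        right = "G" + "TCT" + spacer + "TCTAGCACAACTCC" + "GTC" + tail
        return WorkedJunction(locus_id, left, deleted, right, net)

    if locus_id == "3B_5":
        motifs = ("GATC",)
        left_pad = _clean_filler(rng, flank - 2, motifs)
        left = left_pad + "GA"
        deleted = _clean_filler(rng, deleted_length, motifs)
        spacer = _clean_filler(rng, 29, motifs)
        tail = _clean_filler(rng, flank - 35, motifs)
        right = "TC" + spacer + "GATC" + tail
        return WorkedJunction(locus_id, left, deleted, right, "")

    raise KeyError(f"no worked junction defined for locus {locus_id!r}")
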