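"""Alignment core: gapless similarity blocks and scored local hits.

The central object is the :class:`SimilarityBlock`, the dot-plot primitive
used throughout the package: a gapless pairing of equal-length intervals on
two sequences whose percent identity meets a configured threshold
(defaults: 100 bp minimum length, 95% identity, the parameters used to
define breakpoints as similarity-block borders).

Block semantics
---------------
Blocks are found by the standard seed-and-extend recipe: every maximal
exact match of at least the seed length (default k=12) is extended in
both directions along its diagonal under match/mismatch scoring
(+1/-4), stopping when the running score drops more than the X-drop
threshold (25) below its maximum, and the block is trimmed back to the
score maxima.  A reported block therefore:

1. is gapless (one diagonal; indels split blocks);
2. has overall identity >= the configured minimum over its full length;
3. is end-trimmed to the score peaks, so extending it in either
   direction would lower the alignment score -- borders sit at the last
   matching base of the homology (plus at most a chance exact match
   run, ~1 base of random sequence), which is what makes block borders
   usable as rearrangement breakpoints;
4. has length >= the configured minimum.

Ambiguous bases (N) count as mismatches, including N against N.

Seeding is exhaustive for the default thresholds: a >=100 bp block at
>=95% identity must contain an exact 12-mer (killing every 12-mer in a
window of length L needs more than L/20 mismatches for L > 27), so no
qualifying block can be missed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Sequence

import numpy as np

from .seqs import encode, kmer_codes, revcomp

DEFAULT_MIN_LENGTH = 100
DEFAULT_MIN_IDENTITY = 0.95
DEFAULT_SEED_K = 12

# seed clusters on a diagonal are merged when closer than this, and the
# examined window extends this far beyond the outermost seeds; see module
# docstring for why qualifying blocks cannot extend further than ~2k bases
# past their last exact seed.
_CLUSTER_GAP = 400
_CLUSTER_MARGIN = 250
# diagonals of comparisons up to this total size are scanned in full,
# without seed-window clipping (used by small fixtures and by tests that
# compare against an exhaustive oracle).
_FULL_SCAN_LIMIT = 4096


@dataclass(frozen=True)
class SimilarityBlock:
    """A gapless high-identity match between two sequences.

    Intervals are 1-based closed.  For ``orientation == "reverse"`` the
    b-interval is given on the forward strand of B; base ``a_start``
    pairs with base ``b_end``.
    """

    a_start: int
    a_end: int
    b_start: int
    b_end: int
    orientation: str  # "forward" | "reverse"
    identity: float
    length: int

    def __post_init__(self):
        if self.a_end - self.a_start != self.b_end - self.b_start:
            raise ValueError("similarity blocks are gapless: intervals must have equal length")
        if self.length != self.a_end - self.a_start + 1:
            raise ValueError("length inconsistent with a_interval")

    @property
    def a_interval(self) -> tuple[int, int]:
        return (self.a_start, self.a_end)

    @property
    def b_interval(self) -> tuple[int, int]:
        return (self.b_start, self.b_end)

    def transpose(self) -> "SimilarityBlock":
        """The same block viewed with the roles of A and B swapped."""
        return SimilarityBlock(
            self.b_start, self.b_end, self.a_start, self.a_end,
            self.orientation, self.identity, self.length,
        )


MISMATCH_PENALTY = 4
XDROP = 25


def _identity_fraction(min_identity: float) -> Fraction:
    frac = Fraction(min_identity).limit_denominator(100000)
    if not 0 < frac <= 1:
        raise ValueError("min_identity must be in (0, 1]")
    return frac


def _xdrop_blocks(match: np.ndarray, frac: Fraction, min_len: int,
                  seed_k: int) -> list[tuple[int, int]]:
    """Seed-and-extend blocks of a 0/1 match array, half-open (start, end).

    Every maximal exact run of length >= seed_k is extended both ways
    with +1/-MISMATCH_PENALTY scoring and XDROP termination, trimmed to
    the score maxima; distinct seeds reaching the same trimmed interval
    are deduplicated.  Filters to length >= min_len and overall identity
    >= frac.
    """
    n = match.size
    if n == 0:
        return []
    m = match.astype(np.int64)
    padded = np.empty(n + 2, dtype=np.int64)
    padded[0] = padded[-1] = 0
    padded[1:-1] = m
    d = np.diff(padded)
    run_starts = np.flatnonzero(d == 1)
    run_ends = np.flatnonzero(d == -1)          # one past each match run
    run_lens = run_ends - run_starts
    r = run_starts.size
    if r == 0:
        return []
    cs = np.concatenate(([0], np.cumsum(m)))
    num, den = frac.numerator, frac.denominator
    out: set[tuple[int, int]] = set()
    for si in np.flatnonzero(run_lens >= seed_k):
        # extend right from the seed run's end, run by run
        score = 0
        best, best_pos = 0, int(run_ends[si])
        j = si + 1
        while j < r:
            gap = int(run_starts[j] - run_ends[j - 1])
            score -= MISMATCH_PENALTY * gap
            if score < best - XDROP:
                break
            score += int(run_lens[j])
            if score > best:
                best, best_pos = score, int(run_ends[j])
            j += 1
        right = best_pos
        # extend left from the seed run's start
        score = 0
        best, best_pos = 0, int(run_starts[si])
        j = si - 1
        while j >= 0:
            gap = int(run_starts[j + 1] - run_ends[j])
            score -= MISMATCH_PENALTY * gap
            if score < best - XDROP:
                break
            score += int(run_lens[j])
            if score > best:
                best, best_pos = score, int(run_starts[j])
            j -= 1
        left = best_pos
        if right - left >= min_len:
            matches = int(cs[right] - cs[left])
            if matches * den >= num * (right - left):
                out.add((left, right))
    return sorted(out)


def _seed_pairs(ea: np.ndarray, eb: np.ndarray, k: int, max_occ: int = 1000):
    """Exact k-mer seed positions grouped by diagonal (a_pos - b_pos)."""
    ca, va = kmer_codes(ea, k)
    cb, vb = kmer_codes(eb, k)
    if ca.size == 0 or cb.size == 0:
        return {}
    b_idx = np.flatnonzero(vb)
    order = np.argsort(cb[b_idx], kind="stable")
    sorted_codes = cb[b_idx][order]
    sorted_pos = b_idx[order]
    a_idx = np.flatnonzero(va)
    lo = np.searchsorted(sorted_codes, ca[a_idx], side="left")
    hi = np.searchsorted(sorted_codes, ca[a_idx], side="right")
    counts = hi - lo
    keep = (counts > 0) & (counts <= max_occ)
    a_keep = a_idx[keep]
    lo, hi = lo[keep], hi[keep]
    diag_map: dict[int, list[int]] = {}
    for apos, l, h in zip(a_keep, lo, hi):
        for bpos in sorted_pos[l:h]:
            diag_map.setdefault(int(apos) - int(bpos), []).append(int(apos))
    return diag_map


def _diag_windows(a_positions: list[int], d: int, la: int, lb: int, k: int,
                  full_scan: bool) -> list[tuple[int, int]]:
    """Half-open windows (in a-coordinates) to examine on diagonal d."""
    a_lo = max(0, d)
    a_hi = min(la, lb + d)
    if a_hi <= a_lo:
        return []
    if full_scan:
        return [(a_lo, a_hi)]
    pts = sorted(set(a_positions))
    windows = []
    start = pts[0]
    prev = pts[0]
    for p in pts[1:]:
        if p - prev > _CLUSTER_GAP:
            windows.append((max(a_lo, start - _CLUSTER_MARGIN),
                            min(a_hi, prev + k + _CLUSTER_MARGIN)))
            start = p
        prev = p
    windows.append((max(a_lo, start - _CLUSTER_MARGIN),
                    min(a_hi, prev + k + _CLUSTER_MARGIN)))
    # merge any overlap introduced by the margins
    merged = [windows[0]]
    for s, e in windows[1:]:
        if s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def _forward_blocks(ea: np.ndarray, eb: np.ndarray, min_len: int, frac: Fraction,
                    k: int) -> list[tuple[int, int, int, float]]:
    """(a_start0, b_start0, length, identity) for forward-orientation blocks."""
    la, lb = ea.size, eb.size
    full_scan = la + lb <= _FULL_SCAN_LIMIT
    if full_scan:
        diag_map = {d: [max(0, d)] for d in range(-(lb - 1), la)}
    else:
        diag_map = _seed_pairs(ea, eb, k)
    out = []
    for d, apos in diag_map.items():
        for w_lo, w_hi in _diag_windows(apos, d, la, lb, k, full_scan):
            match = (ea[w_lo:w_hi] == eb[w_lo - d : w_hi - d])
            for a, b in _xdrop_blocks(match, frac, min_len, k):
                seg = match[a:b]
                ident = float(seg.sum()) / (b - a)
                out.append((w_lo + a, w_lo + a - d, b - a, ident))
    return out


def find_similarity_blocks(
    seq_a: str,
    seq_b: str,
    min_length: int = DEFAULT_MIN_LENGTH,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    both_strands: bool = False,
    seed_k: int = DEFAULT_SEED_K,
) -> list[SimilarityBlock]:
    """Find all maximal gapless similarity blocks between two sequences.

    Parameters mirror the dot-plot settings used to define rearrangement
    breakpoints: ``min_length`` is the minimum reported repeat length and
    ``min_identity`` the identity threshold (defaults 100 bp / 0.95).
    With ``both_strands`` set, reverse-orientation blocks (A against the
    reverse complement of B) are reported as well.

    Returns blocks sorted by a_interval, then b_interval.
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    if min_length < seed_k:
        raise ValueError(f"min_length ({min_length}) must be >= seed size ({seed_k})")
    frac = _identity_fraction(min_identity)
    ea = encode(seq_a, unknown=4)
    eb = encode(seq_b, unknown=5)
    blocks: list[SimilarityBlock] = []
    for a0, b0, length, ident in _forward_blocks(ea, eb, min_length, frac, seed_k):
        blocks.append(SimilarityBlock(a0 + 1, a0 + length, b0 + 1, b0 + length,
                                      "forward", ident, length))
    if both_strands:
        eb_rc = encode(revcomp(seq_b), unknown=5)
        lb = eb_rc.size
        for a0, b0, length, ident in _forward_blocks(ea, eb_rc, min_length, frac, seed_k):
            # map reverse-complement coordinates back to the forward strand
            b_end = lb - b0          # 1-based
            b_start = lb - (b0 + length) + 1
            blocks.append(SimilarityBlock(a0 + 1, a0 + length, b_start, b_end,
                                          "reverse", ident, length))
    blocks.sort(key=lambda b: (b.a_start, b.a_end, b.b_start, b.orientation))
    return blocks


def self_repeat_blocks(
    seq: str,
    min_length: int = DEFAULT_MIN_LENGTH,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    seed_k: int = DEFAULT_SEED_K,
) -> list[SimilarityBlock]:
    """Direct and inverted repeats within one sequence (self dot plot).

    The trivial self-diagonal is excluded and each mirrored pair is
    reported once, with ``a_start <= b_start``.
    """
    blocks = find_similarity_blocks(seq, seq, min_length, min_identity,
                                    both_strands=True, seed_k=seed_k)
    out = []
    for b in blocks:
        if b.orientation == "forward":
            if b.a_interval == b.b_interval:
                continue  # self-diagonal
            if b.a_start > b.b_start:
                continue  # mirror duplicate
        else:
            if b.a_start > b.b_start:
                continue
        out.append(b)
    return out


# --- scored local alignment -------------------------------------------------

@dataclass(frozen=True)
class Scoring:
    """Linear gap scoring for local alignment."""

    match: int = 1
    mismatch: int = -2
    gap: int = -3

    def __post_init__(self):
        if self.match <= 0:
            raise ValueError("match score must be positive")
        if self.mismatch >= 0 or self.gap >= 0:
            raise ValueError("mismatch and gap scores must be negative")


@dataclass(frozen=True)
class LocalHit:
    """One scored local alignment hit.

    ``expect`` is a Karlin-Altschul style expectation computed from the
    score and the sequence lengths, with the (lambda, K) parameters used
    recorded on the hit; it is a comparable significance statistic, not a
    replication of BLAST's exact statistics.
    """

    query_start: int
    query_end: int
    subject_start: int
    subject_end: int
    strand: str          # "+" | "-"
    score: int
    identity: float
    expect: float
    aligned_query: str
    aligned_subject: str
    ka_lambda: float
    ka_k: float
    scoring: Scoring


def karlin_altschul_lambda(scoring: Scoring) -> float:
    """Ungapped Karlin-Altschul lambda for uniform base composition.

    Solves sum_ij p_i p_j exp(lambda * s_ij) = 1 with p = 1/4; for
    match/mismatch scoring this is 0.0625*16*(0.25 e^(l*m) + 0.75 e^(l*x)).
    """
    from scipy.optimize import brentq

    m, x = scoring.match, scoring.mismatch

    def f(lam):
        return 0.25 * math.exp(lam * m) + 0.75 * math.exp(lam * x) - 1.0

    return float(brentq(f, 1e-9, 10.0))


_KA_K = 0.333  # fixed default; recorded on every hit


def expect_value(score: int, m: int, n: int, scoring: Scoring) -> float:
    lam = karlin_altschul_lambda(scoring)
    return _KA_K * m * n * math.exp(-lam * score)


def _smith_waterman(q: str, s: str, sc: Scoring):
    """Plain Smith-Waterman with linear gaps; returns the single best hit.

    O(len(q)*len(s)) dynamic programming over int arrays; intended for
    flank/locus scale sequences, not whole chromosomes.
    """
    nq, ns = len(q), len(s)
    eq = encode(q, unknown=4)
    es = encode(s, unknown=5)
    H = np.zeros((nq + 1, ns + 1), dtype=np.int64)
    best = (0, 0, 0)
    for i in range(1, nq + 1):
        sub = np.where(es == eq[i - 1], sc.match, sc.mismatch)
        row = H[i]
        prev = H[i - 1]
        diag = prev[:-1] + sub
        up = prev[1:] + sc.gap
        cand = np.maximum(np.maximum(diag, up), 0)
        # horizontal dependency resolved sequentially
        run = 0
        for j in range(1, ns + 1):
            run = max(cand[j - 1], run + sc.gap)
            row[j] = run
        m = int(row.max())
        if m > best[0]:
            best = (m, i, int(row.argmax()))
    score, bi, bj = best
    if score <= 0:
        return None
    # traceback
    i, j = bi, bj
    aq, as_ = [], []
    while i > 0 and j > 0 and H[i, j] > 0:
        h = H[i, j]
        sub = sc.match if eq[i - 1] == es[j - 1] else sc.mismatch
        if h == H[i - 1, j - 1] + sub:
            aq.append(q[i - 1]); as_.append(s[j - 1]); i -= 1; j -= 1
        elif h == H[i - 1, j] + sc.gap:
            aq.append(q[i - 1]); as_.append("-"); i -= 1
        else:
            aq.append("-"); as_.append(s[j - 1]); j -= 1
    aq.reverse(); as_.reverse()
    matches = sum(1 for x, y in zip(aq, as_) if x == y and x != "-")
    ident = matches / len(aq)
    return score, i + 1, bi, j + 1, bj, ident, "".join(aq), "".join(as_)


def local_align(query: str, subject: str, scoring: Scoring | None = None,
                both_strands: bool = True) -> list[LocalHit]:
    """Score local alignments of query against subject (both strands).

    Returns hits sorted by descending score (at most one per strand).
    Subject coordinates are always on the forward strand; for a minus
    hit, subject_start/end delimit the forward-strand interval whose
    reverse complement aligns to the query.
    """
    sc = scoring or Scoring()
    lam = karlin_altschul_lambda(sc)
    hits: list[LocalHit] = []
    strands = [("+", subject)] + ([("-", revcomp(subject))] if both_strands else [])
    ns = len(subject)
    for strand, subj in strands:
        res = _smith_waterman(query, subj, sc)
        if res is None:
            continue
        score, q1, q2, s1, s2, ident, aq, asub = res
        if strand == "-":
            s1, s2 = ns - s2 + 1, ns - s1 + 1
        hits.append(LocalHit(
            query_start=q1, query_end=q2, subject_start=s1, subject_end=s2,
            strand=strand, score=score, identity=ident,
            expect=_KA_K * len(query) * ns * math.exp(-lam * score),
            aligned_query=aq, aligned_subject=asub,
            ka_lambda=lam, ka_k=_KA_K, scoring=sc,
        ))
    hits.sort(key=lambda h: -h.score)
    return hits


def blocks_to_tsv(blocks: Iterable[SimilarityBlock]) -> str:
    """Serialise blocks as a TSV table (dot-plot export)."""
    lines = ["a_start\ta_end\tb_start\tb_end\torientation\tidentity\tlength"]
    for b in blocks:
        lines.append(f"{b.a_start}\t{b.a_end}\t{b.b_start}\t{b.b_end}\t"
                     f"{b.orientation}\t{b.identity:.4f}\t{b.length}")
    return "\n".join(lines) + "\n"


def render_dotplot(blocks: Sequence[SimilarityBlock], path: str,
                   title: str = "dot plot") -> None:
    """Render blocks as a dot-plot PNG (forward green, reverse red)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    for b in blocks:
        if b.orientation == "forward":
            ax.plot([b.a_start, b.a_end], [b.b_start, b.b_end], color="green", lw=1)
        else:
            ax.plot([b.a_start, b.a_end], [b.b_end, b.b_start], color="red", lw=1)
    ax.set_xlabel("sequence A (bp)")
    ax.set_ylabel("sequence B (bp)")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
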