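"""Similarity-block and local-alignment core: examples, oracle, properties."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from temark.homology import (Scoring, find_similarity_blocks, local_align,
                             self_repeat_blocks)
from temark.seqs import mutate, random_dna, revcomp

# ---------------------------------------------------------------------------
# independent per-base oracle: same block definition (exact-run seeds,
# +1/-4 X-drop extension trimmed to score peaks), implemented naively over
# every diagonal with no k-mer indexing, windowing or run compression.

def oracle_blocks(seq_a, seq_b, min_len=100, min_id=0.95, k=12,
                  penalty=4, xdrop=25):
    la, lb = len(seq_a), len(seq_b)
    out = set()
    for d in range(-(lb - 1), la):
        a0, a1 = max(0, d), min(la, lb + d)
        if a1 - a0 < min_len:
            continue
        m = [seq_a[i] == seq_b[i - d] and seq_a[i] in "ACGT"
             for i in range(a0, a1)]
        n = len(m)
        # maximal exact runs >= k
        i = 0
        seeds = []
        while i < n:
            if m[i]:
                j = i
                while j < n and m[j]:
                    j += 1
                if j - i >= k:
                    seeds.append((i, j))
                i = j
            else:
                i += 1
        for s, e in seeds:
            # extend right, per base
            score, best, pos = 0, 0, e
            for j in range(e, n):
                score += 1 if m[j] else -penalty
                if score < best - xdrop:
                    break
                if score > best:
                    best, pos = score, j + 1
            right = pos
            score, best, pos = 0, 0, s
            for j in range(s - 1, -1, -1):
                score += 1 if m[j] else -penalty
                if score < best - xdrop:
                    break
                if score > best:
                    best, pos = score, j
            left = pos
            if right - left >= min_len and sum(m[left:right]) >= min_id * (right - left):
                out.add((a0 + left + 1, a0 + right, a0 + left - d + 1, a0 + right - d))
    return out


def block_set(blocks):
    return {(b.a_start, b.a_end, b.b_start, b.b_end)
            for b in blocks if b.orientation == "forward"}


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_block_set_matches_exhaustive_oracle(seed):
    """Seeded/windowed search equals the naive all-diagonal scan on 2 kb pairs."""
    rng = np.random.default_rng(seed)
    base = random_dna(rng, 2000)
    mutated, _ = mutate(rng, base, 0.03)
    fixtures = [
        (base, mutated),                                  # 97% identity pair
        (base, base[:700] + base[1200:]),                 # internal deletion
        (base[:1000], random_dna(rng, 1000)),             # unrelated pair
        (base[:600] + base[:600], base[:600]),            # duplicated query
    ]
    for a, b in fixtures:
        got = block_set(find_similarity_blocks(a, b))
        want = oracle_blocks(a, b)
        assert got == want


def test_identical_sequences_single_full_block():
    rng = np.random.default_rng(7)
    s = random_dna(rng, 1000)
    blocks = find_similarity_blocks(s, s)
    assert len(blocks) == 1
    b = blocks[0]
    assert b.a_interval == (1, 1000) and b.b_interval == (1, 1000)
    assert b.identity == 1.0 and b.orientation == "forward"


def test_deletion_splits_into_two_blocks_at_exact_borders():
    """A deletion yields two blocks whose borders sit at the junction."""
    rng = np.random.default_rng(11)
    a = random_dna(rng, 1000)
    # guard against chance junction microhomology so borders are unambiguous
    while a[400] == a[700] or a[399] == a[699]:
        a = random_dna(rng, 1000)
    b = a[:400] + a[700:]
    blocks = find_similarity_blocks(a, b)
    assert block_set(blocks) == {(1, 400, 1, 400), (701, 1000, 401, 700)}


def test_unrelated_sequences_have_no_blocks():
    """Two independent random 10 kb sequences share no 100 bp window at 95%."""
    rng = np.random.default_rng(13)
    a, b = random_dna(rng, 10_000), random_dna(rng, 10_000)
    assert find_similarity_blocks(a, b, both_strands=True) == []
    # brute-force confirmation on a subsample of window pairs
    ea = np.frombuffer(a[:2000].encode(), dtype=np.uint8)
    eb = np.frombuffer(b[:2000].encode(), dtype=np.uint8)
    best = 0.0
    for i in range(0, 1901, 20):
        for j in range(0, 1901, 20):
            ident = float((ea[i:i + 100] == eb[j:j + 100]).mean())
            best = max(best, ident)
    assert best < 0.95


def test_symmetry_blocks_transpose():
    """blocks(A, B) equals blocks(B, A) with intervals transposed."""
    rng = np.random.default_rng(17)
    a = random_dna(rng, 3000)
    b = a[:1200] + random_dna(rng, 500) + a[1800:]
    fwd = block_set(find_similarity_blocks(a, b))
    rev = {(bs, be, as_, ae) for (as_, ae, bs, be)
           in block_set(find_similarity_blocks(b, a))}
    assert fwd == rev


@given(st.integers(0, 10_000))
@settings(max_examples=15, deadline=None)
def test_monotonicity_in_thresholds(seed):
    """Raising min_identity or min_length never adds a block."""
    rng = np.random.default_rng(seed)
    base = random_dna(rng, 1500)
    mutated, _ = mutate(rng, base, 0.04)
    loose = block_set(find_similarity_blocks(base, mutated, 100, 0.90))
    tight_id = block_set(find_similarity_blocks(base, mutated, 100, 0.97))
    tight_len = block_set(find_similarity_blocks(base, mutated, 300, 0.90))
    for t in tight_id:
        assert any(t[0] >= l[0] and t[1] <= l[1] for l in loose)
    assert tight_len <= loose


def test_self_repeats_direct_and_inverted(rng):
    x = random_dna(rng, 5000)
    direct = self_repeat_blocks(x + x)
    assert len(direct) == 1
    assert direct[0].orientation == "forward"
    assert direct[0].a_interval == (1, 5000) and direct[0].b_interval == (5001, 10000)
    inverted = self_repeat_blocks(x + revcomp(x))
    assert len(inverted) == 1 and inverted[0].orientation == "reverse"


def test_self_repeat_identity_tracks_planted_divergence(rng):
    x = random_dna(rng, 5000)
    x2, nsub = mutate(rng, x, 0.04)
    blocks = [b for b in self_repeat_blocks(x + x2) if b.orientation == "forward"]
    assert blocks
    planted = 1 - nsub / 5000
    assert abs(max(blocks, key=lambda b: b.length).identity - planted) <= 0.01


# --- local alignment --------------------------------------------------------

def test_local_align_exact_substring(rng):
    subject = random_dna(rng, 1500)
    query = subject[400:900]
    hit = local_align(query, subject, Scoring(1, -2, -3), both_strands=False)[0]
    assert hit.score == 500
    assert hit.identity == 1.0
    assert (hit.subject_start, hit.subject_end) == (401, 900)


def test_local_align_matches_biopython_smith_waterman(rng):
    """Scores agree with an independent dynamic-programming reference."""
    from Bio import Align

    subject = random_dna(rng, 1200)
    query, _ = mutate(rng, subject[300:800], 0.03)
    sc = Scoring(1, -2, -3)
    aligner = Align.PairwiseAligner(mode="local", match_score=1, mismatch_score=-2,
                                    open_gap_score=-3, extend_gap_score=-3)
    ours = local_align(query, subject, sc, both_strands=False)[0]
    assert ours.score == aligner.score(subject, query)
    assert ours.identity >= 0.95
    assert ours.expect < 1e-50


def test_local_align_strand_symmetry(rng):
    subject = random_dna(rng, 1000)
    query = subject[200:600]
    plus = local_align(query, subject)[0]
    minus = local_align(revcomp(query), subject)[0]
    assert minus.strand == "-"
    assert minus.score == plus.score
    assert (minus.subject_start, minus.subject_end) == (plus.subject_start,
                                                        plus.subject_end)


def test_degenerate_scoring_rejected():
    with pytest.raises(ValueError):
        Scoring(match=0, mismatch=-1, gap=-1)
    with pytest.raises(ValueError):
        Scoring(match=1, mismatch=1, gap=-1)
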