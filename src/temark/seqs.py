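"""Low-level nucleotide sequence helpers shared across the package.

Sequences are plain Python strings (uppercase A/C/G/T plus N for assembly
gaps).  Heavy per-base work is done on numpy uint8 arrays produced by
:func:`encode`.  Coordinates are 1-based closed everywhere in the public
API; helper converters to/from BED's 0-based half-open convention live
here so the off-by-one arithmetic exists in exactly one place.
"""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: numeric codes: A=0 C=1 G=2 T=3, anything else (N, IUPAC ambiguity) = 4
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _c in enumerate("ACGT"):
    _CODE[ord(_c)] = _i
    _CODE[ord(_c.lower())] = _i

ALPHABET = "ACGT"


def revcomp(seq: str) -> str:
    """Reverse complement (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str, unknown: int = 4) -> np.ndarray:
    """Encode a sequence as uint8 codes; non-ACGT bases get ``unknown``.

    Callers that compare two sequences give each side a *different*
    unknown code so that N never matches anything, including another N.
    """
    arr = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)].copy()
    if unknown != 4:
        arr[arr == 4] = unknown
    return arr


def kmer_codes(arr: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Polynomial 2-bit codes of all k-mers of an encoded sequence.

    Returns ``(codes, valid)`` of length ``len(arr) - k + 1``; ``valid``
    is False wherever the window contains a non-ACGT base.  k is capped
    at 31 to keep codes inside int64.
    """
    if not 1 <= k <= 31:
        raise ValueError("k must be in [1, 31]")
    n = arr.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    c = arr.astype(np.int64)
    bad = (arr >= 4).astype(np.int64)
    codes = np.zeros(n, dtype=np.int64)
    badcount = np.zeros(n, dtype=np.int64)
    for j in range(k):
        codes <<= 2
        codes += np.where(c[j : j + n] < 4, c[j : j + n], 0)
        badcount += bad[j : j + n]
    return codes, badcount == 0


def random_dna(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    """i.i.d. random sequence with the given GC fraction."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=length, p=p)
    return "".join(ALPHABET[i] for i in idx)


def mutate(rng: np.random.Generator, seq: str, rate: float) -> tuple[str, int]:
    """Apply i.i.d. substitutions at the given per-base rate.

    Returns the mutated sequence and the realised substitution count.
    Each chosen site is replaced with one of the three other bases.
    """
    if rate <= 0:
        return seq, 0
    arr = encode(seq)
    hit = rng.random(arr.size) < rate
    hit &= arr < 4
    n_hit = int(hit.sum())
    if n_hit == 0:
        return seq, 0
    shift = rng.integers(1, 4, size=n_hit)
    arr = arr.astype(np.int64)
    arr[hit] = (arr[hit] + shift) % 4
    out = "".join(ALPHABET[v] if v < 4 else "N" for v in arr)
    return out, n_hit


# --- coordinate conventions -------------------------------------------------

def to_bed(start1: int, end1: int) -> tuple[int, int]:
    """1-based closed -> 0-based half-open."""
    return start1 - 1, end1


def from_bed(start0: int, end0: int) -> tuple[int, int]:
    """0-based half-open -> 1-based closed."""
    return start0 + 1, end0


def lcp_len(a: str, b: str) -> int:
    """Length of the longest common prefix of two strings."""
    n = min(len(a), len(b))
    i = 0
    while i < n and a[i] == b[i]:
        i += 1
    return i


def lcs_len(a: str, b: str) -> int:
    """Length of the longest common suffix of two strings."""
    n = min(len(a), len(b))
    i = 0
    while i < n and a[-1 - i] == b[-1 - i]:
        i += 1
    return i
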