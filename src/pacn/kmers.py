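"""Canonical k-mer primitives.

Every sequence comparison in this package is alignment-free and built on
canonical k-mers: a window and its reverse complement are collapsed to the
lexicographically smaller of the two, so strand never affects a profile.
Internally k-mers are packed into 2-bit-per-base ``uint64`` codes (k <= 31);
the base order A < C < G < T matches the numeric order of the encoding, so
lexicographic comparison of strings and numeric comparison of codes agree.
Strings appear only at serialization boundaries.
"""

from __future__ import annotations

from collections import Counter

import numpy as np

__all__ = [
    "MAX_K",
    "canonical_kmers",
    "decode_kmer",
    "encode_kmer",
    "kmer_set",
    "revcomp",
    "window_codes",
]

MAX_K = 31

_CODES = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODES[_b] = _i
    _CODES[_b + 32] = _i  # lowercase
_BASES = "ACGT"

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (case preserved, N passes through)."""
    return seq.translate(_COMP)[::-1]


def _check_k(k: int) -> None:
    if not (3 <= k <= MAX_K):
        raise ValueError(f"k must be in [3, {MAX_K}], got {k}")
    if k % 2 == 0:
        raise ValueError(f"k must be odd to avoid palindromic k-mers, got {k}")


def window_codes(seq: str, k: int, canonical: bool = True) -> np.ndarray:
    """Packed codes of all k-length windows of ``seq``, in sequence order.

    Windows containing a non-ACGT character are dropped.  With
    ``canonical=True`` (the default) each window contributes
    ``min(forward, reverse-complement)``.
    """
    _check_k(k)
    n = len(seq)
    if n < k:
        return np.empty(0, dtype=np.uint64)
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    b = _CODES[raw]
    bad = b == 255
    bb = np.where(bad, 0, b).astype(np.uint64)
    m = n - k + 1
    fwd = np.zeros(m, dtype=np.uint64)
    for j in range(k):
        fwd = (fwd << np.uint64(2)) | bb[j : j + m]
    if canonical:
        cc = np.where(bad, 0, 3 - b).astype(np.uint64)
        rev = np.zeros(m, dtype=np.uint64)
        for j in range(k - 1, -1, -1):
            rev = (rev << np.uint64(2)) | cc[j : j + m]
        codes = np.minimum(fwd, rev)
    else:
        codes = fwd
    if bad.any():
        cum = np.concatenate(([0], np.cumsum(bad)))
        ok = (cum[k:] - cum[:-k]) == 0
        codes = codes[ok]
    return codes


def encode_kmer(kmer: str) -> int:
    """Pack a single k-mer string (not canonicalized)."""
    code = 0
    for ch in kmer.upper():
        v = "ACGT".find(ch)
        if v < 0:
            raise ValueError(f"non-ACGT base in k-mer: {kmer!r}")
        code = (code << 2) | v
    return code


def decode_kmer(code: int, k: int) -> str:
    out = []
    c = int(code)
    for _ in range(k):
        out.append(_BASES[c & 3])
        c >>= 2
    return "".join(reversed(out))


def canonical_kmers(seq: str, k: int) -> Counter:
    """Multiset of canonical k-mers of ``seq`` as a ``Counter`` of strings.

    Convenience form for small sequences; the pipeline itself stays on
    packed codes (:func:`window_codes`).
    """
    codes = window_codes(seq, k)
    if codes.size == 0:
        return Counter()
    uniq, counts = np.unique(codes, return_counts=True)
    return Counter({decode_kmer(c, k): int(n) for c, n in zip(uniq, counts)})


def kmer_set(seq: str, k: int) -> np.ndarray:
    """Sorted unique canonical k-mer codes of a sequence."""
    return np.unique(window_codes(seq, k))
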