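"""Canonical k-mer encoding shared by the reference index and the classifier.

k-mers up to k=31 are packed 2 bits/base into uint64 and canonicalized as the
numeric minimum of a k-mer and its reverse complement; windows containing any
non-ACGT base are invalid. Longer k (up to 63) fall back to string canonical
form upstream.
"""

from __future__ import annotations

import numpy as np

_CODE = np.full(256, 4, dtype=np.uint8)
for _b, _c in zip(b"ACGT", range(4)):
    _CODE[_b] = _c
    _CODE[_b + 32] = _c  # lowercase

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Base codes A=0 C=1 G=2 T=3, anything else 4."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def kmer_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Forward-strand packed k-mers of every window plus a validity mask.

    Returns ``(kmers, valid)`` of length ``len(codes) - k + 1``; windows
    containing a non-ACGT code are marked invalid (their packed value is
    meaningless).
    """
    if not 1 <= k <= 31:
        raise ValueError("packed k-mers require 1 <= k <= 31")
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool)
    c = codes.astype(np.uint64)
    bad = codes >= 4
    kmers = np.zeros(n, dtype=np.uint64)
    valid = np.ones(n, dtype=bool)
    for j in range(k):
        kmers |= (c[j : j + n] & np.uint64(3)) << np.uint64(2 * (k - 1 - j))
        valid &= ~bad[j : j + n]
    return kmers, valid


def revcomp_codes(kmers: np.ndarray, k: int) -> np.ndarray:
    """Reverse complement of packed k-mers (vectorized)."""
    comp = ~kmers  # 2-bit complement: 3 - code == ~code & 3
    out = np.zeros_like(kmers)
    for j in range(k):
        out |= ((comp >> np.uint64(2 * j)) & np.uint64(3)) << np.uint64(2 * (k - 1 - j))
    return out


def canonical_kmers(seq: str, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Canonical (strand-collapsed) packed k-mers of every window of ``seq``.

    Returns ``(canon, valid)``; ``canon[i]`` is defined only where
    ``valid[i]``.
    """
    codes = encode(seq)
    fwd, valid = kmer_codes(codes, k)
    if fwd.size == 0:
        return fwd, valid
    rev = revcomp_codes(fwd, k)
    return np.minimum(fwd, rev), valid
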