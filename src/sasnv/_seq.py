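"""Low-level sequence encoding helpers shared across the package.

Bases are encoded as uint8 codes A=0, C=1, G=2, T=3 so that code order
equals lexicographic order.  k-mers with k <= 30 pack into a single
uint64 (2 bits per base, first base in the most significant position),
preserving lexicographic order of the underlying strings.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"

_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

_DECODE = np.frombuffer(BASES.encode(), dtype=np.uint8)

# complement of code c is 3 - c  (A<->T, C<->G)


def encode(seq: str) -> np.ndarray:
    """Encode an A/C/G/T string into uint8 codes. Raises on other letters."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = _ENCODE[raw]
    if codes.max(initial=0) > 3:
        bad = chr(raw[int(np.argmax(codes > 3))])
        raise ValueError(f"non-ACGT character {bad!r} in sequence")
    return codes


def decode(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode("ascii")


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return (3 - codes)[::-1]


def revcomp(seq: str) -> str:
    return decode(revcomp_codes(encode(seq)))


def pack_kmers(codes: np.ndarray, k: int) -> np.ndarray:
    """Pack every k-mer of ``codes`` into uint64 keys (2 bits per base).

    Returns an array of length ``len(codes) - k + 1``; entry ``i`` packs
    ``codes[i:i+k]``.  Key order equals lexicographic k-mer order.
    """
    if not 1 <= k <= 30:
        raise ValueError("k must be in [1, 30] to fit a 60-bit key")
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    keys = np.zeros(n, dtype=np.uint64)
    # pack two bases per pass to halve the number of 64-bit sweeps
    if k >= 2:
        b2 = (codes[:-1] << 2) | codes[1:]  # uint8, values 0..15
        b2 = b2.astype(np.uint64)
        for j in range(0, k - 1, 2):
            keys <<= np.uint64(4)
            keys |= b2[j : j + n]
    if k % 2 == 1:
        keys <<= np.uint64(2)
        keys |= codes[k - 1 : k - 1 + n].astype(np.uint64)
    return keys


def pack_kmers_at(codes: np.ndarray, positions: np.ndarray, k: int) -> np.ndarray:
    """Pack the k-mers starting at ``positions`` only (cheaper than
    :func:`pack_kmers` when few positions are needed)."""
    positions = np.asarray(positions, dtype=np.int64)
    keys = np.zeros(len(positions), dtype=np.uint64)
    for j in range(k):
        keys <<= np.uint64(2)
        keys |= codes[positions + j].astype(np.uint64)
    return keys


def revcomp_keys(keys: np.ndarray, k: int) -> np.ndarray:
    """Reverse-complement packed k-mer keys without unpacking.

    Complements each 2-bit base (base -> 3 - base) and reverses base order
    within the low 2k bits.
    """
    keys = np.asarray(keys, dtype=np.uint64)
    out = ~keys  # complement every 2-bit group
    # swap adjacent 2-bit groups, then 4-bit, 8-bit, 16-bit, 32-bit blocks
    m2 = np.uint64(0x3333333333333333)
    m4 = np.uint64(0x0F0F0F0F0F0F0F0F)
    m8 = np.uint64(0x00FF00FF00FF00FF)
    m16 = np.uint64(0x0000FFFF0000FFFF)
    out = ((out >> np.uint64(2)) & m2) | ((out & m2) << np.uint64(2))
    out = ((out >> np.uint64(4)) & m4) | ((out & m4) << np.uint64(4))
    out = ((out >> np.uint64(8)) & m8) | ((out & m8) << np.uint64(8))
    out = ((out >> np.uint64(16)) & m16) | ((out & m16) << np.uint64(16))
    out = (out >> np.uint64(32)) | (out << np.uint64(32))
    return out >> np.uint64(64 - 2 * k)


def pack_single(codes: np.ndarray) -> int:
    """Pack one k-mer (len <= 30) into its uint64 key."""
    key = 0
    for c in codes.tolist():
        key = (key << 2) | int(c)
    return key
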