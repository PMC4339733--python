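"""Low-level 2-bit DNA encoding shared by k-mer counting and Markov scoring.

Bases map A,C,G,T -> 0..3; anything else (N, IUPAC ambiguity codes) maps to
4 and invalidates every window that covers it.  Windows are packed into
uint64 keys (supports k <= 31), most-significant 2 bits first, so integer
comparison of packed keys equals lexicographic comparison of the strings.
"""

from __future__ import annotations

import numpy as np

_LUT = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _LUT[_b] = _i
for _i, _b in enumerate(b"acgt"):
    _LUT[_b] = _i

_BASES = "ACGT"
_RC_TABLE = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (case-preserving, N -> N)."""
    return seq.translate(_RC_TABLE)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string to uint8 codes (A=0,C=1,G=2,T=3, other=4)."""
    return _LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def encode_concat(seqs: list[str]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Encode many sequences joined with an ``N`` separator.

    Returns ``(codes, starts, lengths)``: sequence ``r`` occupies
    ``codes[starts[r]:starts[r] + lengths[r]]``.  The separator guarantees
    that no fixed-length window spans two sequences and survives the
    validity mask.
    """
    lengths = np.fromiter((len(s) for s in seqs), count=len(seqs), dtype=np.int64)
    big = "N".join(seqs)
    codes = encode(big) if big else np.empty(0, dtype=np.uint8)
    starts = np.zeros(len(seqs), dtype=np.int64)
    if len(seqs) > 1:
        np.cumsum(lengths[:-1] + 1, out=starts[1:])
    return codes, starts, lengths


def window_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Packed forward-strand codes for every length-k window.

    Returns ``(km, valid)``; ``km`` holds garbage wherever ``valid`` is
    False (a window containing a non-ACGT code).
    """
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool)
    bad = np.concatenate(([0], np.cumsum(codes == 4, dtype=np.int64)))
    valid = (bad[k:] - bad[:-k]) == 0
    c = np.minimum(codes, 3).astype(np.uint64)  # clamp 4 -> 3; masked anyway
    km = np.zeros(n, dtype=np.uint64)
    for j in range(k):
        km <<= np.uint64(2)
        km |= c[j : j + n]
    return km, valid


def revcomp_window_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Packed codes of the reverse complement of every length-k window."""
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    comp = (3 - np.minimum(codes, 3)).astype(np.uint64)
    rc = np.zeros(n, dtype=np.uint64)
    for j in range(k):
        rc |= comp[j : j + n] << np.uint64(2 * j)
    return rc


def canonical_window_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Canonical (min of strand and reverse complement) packed window codes."""
    km, valid = window_codes(codes, k)
    if km.size == 0:
        return km, valid
    rc = revcomp_window_codes(codes, k)
    return np.minimum(km, rc), valid


def decode(code: int, k: int) -> str:
    """Unpack a uint64 k-mer code back into its string."""
    out = []
    code = int(code)
    for j in range(k):
        out.append(_BASES[(code >> (2 * (k - 1 - j))) & 3])
    return "".join(out)


def pack_kmer(kmer: str) -> int:
    """Pack an ACGT string into its integer code (inverse of :func:`decode`)."""
    code = 0
    for ch in kmer:
        b = _LUT[ord(ch)]
        if b > 3:
            raise ValueError(f"non-ACGT base {ch!r} in k-mer")
        code = (code << 2) | int(b)
    return code
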