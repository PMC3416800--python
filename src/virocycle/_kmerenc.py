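"""Vectorised 2-bit kmer encoding.

Kmers up to k=63 are packed into two little-endian uint64 words (a high
word for the leading bases, a low word for the trailing <=32 bases) so
that whole read sets can be scanned, canonicalised and counted with
numpy instead of per-kmer Python loops.  Positions holding characters
outside ACGT (including the sentinel used to join sequences) invalidate
every window that covers them.
"""
from __future__ import annotations

import numpy as np

MAX_K = 63
_SENTINEL = np.uint8(4)

_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
for _i, _b in enumerate(b"acgt"):
    _CODE[_b] = _i

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

KEY_DTYPE = np.dtype([("hi", "<u8"), ("lo", "<u8")])


def encode(seq: str) -> np.ndarray:
    """2-bit codes for *seq*; non-ACGT characters become the invalid code 4."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def concat_encoded(seqs) -> np.ndarray:
    """Concatenate sequences with a sentinel code between them."""
    parts: list[np.ndarray] = []
    sep = np.array([_SENTINEL], dtype=np.uint8)
    for s in seqs:
        parts.append(encode(s))
        parts.append(sep)
    if not parts:
        return np.empty(0, dtype=np.uint8)
    return np.concatenate(parts[:-1])


def _pack(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """(hi, lo) words for every length-k window of *codes*."""
    n = codes.size - k + 1
    if n <= 0:
        z = np.empty(0, dtype=np.uint64)
        return z, z
    w_lo = min(k, 32)
    w_hi = k - w_lo
    c64 = codes.astype(np.uint64)
    # invalid code 4 would bleed into neighbouring bits; mask to 2 bits and
    # track validity separately
    c64 &= np.uint64(3)
    hi = np.zeros(n, dtype=np.uint64)
    lo = np.zeros(n, dtype=np.uint64)
    for j in range(w_hi):
        hi = (hi << np.uint64(2)) | c64[j : j + n]
    for j in range(w_hi, k):
        lo = (lo << np.uint64(2)) | c64[j : j + n]
    return hi, lo


def _valid_windows(codes: np.ndarray, k: int) -> np.ndarray:
    bad = (codes >= 4).astype(np.int32)
    cs = np.concatenate(([0], np.cumsum(bad, dtype=np.int64)))
    return (cs[k:] - cs[:-k]) == 0


def window_words(codes: np.ndarray, k: int):
    """Packed words for every window of *codes*, both strands.

    Returns (hi_f, lo_f, hi_r, lo_r, valid); the *_r arrays hold the
    reverse complement of window i at index i.
    """
    hi_f, lo_f = _pack(codes, k)
    comp = np.where(codes < 4, 3 - codes, codes).astype(np.uint8)[::-1]
    hi_rv, lo_rv = _pack(comp, k)
    return hi_f, lo_f, hi_rv[::-1], lo_rv[::-1], _valid_windows(codes, k)


def make_keys(hi: np.ndarray, lo: np.ndarray) -> np.ndarray:
    """Combine word arrays into a sortable structured key array."""
    keys = np.empty(hi.size, dtype=KEY_DTYPE)
    keys["hi"], keys["lo"] = hi, lo
    return keys


def window_keys(codes: np.ndarray, k: int):
    """Forward and reverse-complement structured keys for every window."""
    hi_f, lo_f, hi_r, lo_r, valid = window_words(codes, k)
    return make_keys(hi_f, lo_f), make_keys(hi_r, lo_r), valid


def _unique_counts(hi: np.ndarray, lo: np.ndarray):
    order = np.lexsort((lo, hi))
    hi_s, lo_s = hi[order], lo[order]
    if hi_s.size == 0:
        return hi_s, lo_s, np.empty(0, dtype=np.int64)
    diff = (hi_s[1:] != hi_s[:-1]) | (lo_s[1:] != lo_s[:-1])
    starts = np.concatenate(([0], np.nonzero(diff)[0] + 1))
    counts = np.diff(np.concatenate((starts, [hi_s.size])))
    return hi_s[starts], lo_s[starts], counts


def count_canonical(seqs, k: int, min_count: int = 1):
    """Count canonical kmers over an iterable of sequences.

    Returns (keys, counts): unique canonical kmer keys (structured dtype,
    lexicographically sorted) and their total observation counts.  Each
    valid window contributes exactly one observation to the canonical
    (lexicographic minimum of kmer and reverse complement) key.
    """
    codes = concat_encoded(seqs)
    hi_f, lo_f, hi_r, lo_r, valid = window_words(codes, k)
    take_rev = (hi_r < hi_f) | ((hi_r == hi_f) & (lo_r < lo_f))
    hi_c = np.where(take_rev, hi_r, hi_f)[valid]
    lo_c = np.where(take_rev, lo_r, lo_f)[valid]
    if hi_c.size == 0:
        return np.empty(0, dtype=KEY_DTYPE), np.empty(0, dtype=np.int64)
    hi_u, lo_u, counts = _unique_counts(hi_c, lo_c)
    if min_count > 1:
        keep = counts >= min_count
        hi_u, lo_u, counts = hi_u[keep], lo_u[keep], counts[keep]
    return make_keys(hi_u, lo_u), counts


def decode(keys: np.ndarray, k: int) -> list[str]:
    """Kmer strings for an array of packed keys."""
    m = keys.size
    if m == 0:
        return []
    w_lo = min(k, 32)
    w_hi = k - w_lo
    out = np.empty((m, k), dtype=np.uint8)
    lo = np.ascontiguousarray(keys["lo"])
    hi = np.ascontiguousarray(keys["hi"])
    for j in range(w_lo):
        out[:, k - 1 - j] = _BASES[((lo >> np.uint64(2 * j)) & np.uint64(3)).astype(np.intp)]
    for j in range(w_hi):
        out[:, w_hi - 1 - j] = _BASES[((hi >> np.uint64(2 * j)) & np.uint64(3)).astype(np.intp)]
    blob = out.tobytes()
    return [blob[i * k : (i + 1) * k].decode("ascii") for i in range(m)]
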