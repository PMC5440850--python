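"""2-bit kmer encoding, canonicalization and the repetitive-kmer filter.

Kmers are packed big-endian into uint64 (first base most significant),
so kmer length is limited to 32 bp. The canonical form of a kmer is the
smaller of its own code and its reverse complement's code; kmers
overlapping an N (or any ambiguity code) are invalid everywhere.
"""

from __future__ import annotations

import numpy as np

from .seqio import ReferenceSequence

_CODE_LUT = np.full(256, 4, dtype=np.uint8)
for _i, _c in enumerate("ACGT"):
    _CODE_LUT[ord(_c)] = _i
    _CODE_LUT[ord(_c.lower())] = _i

_BASES = "ACGT"


def seq_to_codes(seq: str) -> np.ndarray:
    """Per-base codes A=0 C=1 G=2 T=3; anything else (N) = 4."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _CODE_LUT[raw]


def decode_kmer(code: int, k: int) -> str:
    return "".join(_BASES[(code >> (2 * (k - 1 - j))) & 3] for j in range(k))


def _window_valid(base_ok: np.ndarray, k: int) -> np.ndarray:
    """True where the length-k window starting at i contains no bad base."""
    bad = (~base_ok).astype(np.int64)
    csum = np.concatenate(([0], np.cumsum(bad)))
    return (csum[k:] - csum[:-k]) == 0


def forward_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Pack every length-k window; returns (codes, valid) arrays.

    Invalid entries (windows touching an N) hold unspecified values.
    """
    if not 1 <= k <= 32:
        raise ValueError("kmer length must be in [1, 32]")
    n = codes.size
    if n < k:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool)
    m = n - k + 1
    b = (codes & 3).astype(np.uint64)
    out = np.zeros(m, dtype=np.uint64)
    for j in range(k):
        out = (out << np.uint64(2)) | b[j : j + m]
    return out, _window_valid(codes < 4, k)


def revcomp_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Reverse-complement code of every length-k window (same order)."""
    n = codes.size
    m = n - k + 1
    if m <= 0:
        return np.empty(0, dtype=np.uint64)
    comp = ((3 - (codes & 3)) & 3).astype(np.uint64)
    out = np.zeros(m, dtype=np.uint64)
    # base j of the window lands at position k-1-j of the rc kmer
    for j in range(k):
        out |= comp[j : j + m] << np.uint64(2 * j)
    return out


def canonical_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Canonical (strand-insensitive) code of every window: min(fwd, rc)."""
    fwd, valid = forward_codes(codes, k)
    if fwd.size == 0:
        return fwd, valid
    rc = revcomp_codes(codes, k)
    return np.minimum(fwd, rc), valid


def canonical_kmer(kmer: str) -> str:
    """Canonical string form of a single kmer (test/reference helper)."""
    codes = seq_to_codes(kmer)
    if np.any(codes > 3):
        raise ValueError("kmer contains non-ACGT base")
    canon, _ = canonical_codes(codes, len(kmer))
    return decode_kmer(int(canon[0]), len(kmer))


class KmerFilter:
    """Membership test for repetitive canonical kmers.

    A canonical kmer whose genome-wide occurrence count exceeds C_max is
    "repetitive" and excluded from fingerprinting; kmers containing N
    are always excluded (they never reach the filter: callers combine
    this test with the validity mask from :func:`canonical_codes`).
    """

    def __init__(self, k: int, repetitive: np.ndarray, c_max: int):
        self.k = k
        self.repetitive = np.sort(np.asarray(repetitive, dtype=np.uint64))
        self.c_max = c_max

    def __len__(self) -> int:
        return int(self.repetitive.size)

    def is_repetitive(self, canon: np.ndarray) -> np.ndarray:
        """Vectorized membership: True where the canonical code is repetitive."""
        canon = np.asarray(canon, dtype=np.uint64)
        if self.repetitive.size == 0:
            return np.zeros(canon.shape, dtype=bool)
        idx = np.searchsorted(self.repetitive, canon)
        idx[idx == self.repetitive.size] = 0
        return self.repetitive[idx] == canon


def build_kmer_filter(
    refs: list[ReferenceSequence], k: int, c_max: int
) -> KmerFilter:
    """Count canonical kmers genome-wide and flag those occurring > c_max."""
    if all(len(r) < k for r in refs):
        raise ValueError(f"k={k} exceeds the length of every reference sequence")
    chunks = []
    for r in refs:
        if len(r) < k:
            continue
        canon, valid = canonical_codes(seq_to_codes(r.seq), k)
        chunks.append(canon[valid])
    allk = np.concatenate(chunks) if chunks else np.empty(0, dtype=np.uint64)
    values, counts = np.unique(allk, return_counts=True)
    return KmerFilter(k, values[counts > c_max], c_max)


def kmer_profile(
    seq: str, k: int, kfilter: KmerFilter | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Canonical codes of all windows plus the surviving-kmer mask."""
    canon, valid = canonical_codes(seq_to_codes(seq), k)
    if kfilter is not None and canon.size:
        valid = valid & ~kfilter.is_repetitive(canon)
    return canon, valid


def kmer_set(
    seq: str, k: int, kfilter: KmerFilter | None = None
) -> set[tuple[int, int]]:
    """(canonical-code, position) pairs of every surviving kmer of ``seq``."""
    if len(seq) < k:
        raise ValueError(f"sequence length {len(seq)} < k={k}")
    canon, valid = kmer_profile(seq, k, kfilter)
    pos = np.flatnonzero(valid)
    return {(int(canon[p]), int(p)) for p in pos}
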