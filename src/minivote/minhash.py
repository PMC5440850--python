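"""MinHash fingerprinting of reads and genome windows.

A sequence is reduced to its set of canonical kmer codes; each code is
scrambled by a 64-bit mixer H and then pushed through L universal hash
functions h_i(x) = a_i*x + b_i (mod 2^64, a_i odd). The fingerprint is
the vector of per-function minima; the fraction of equal entries between
two fingerprints is an unbiased estimate of the Jaccard similarity of
the underlying kmer sets.

The per-window fingerprints of a long sequence are produced by a rolling
computation: the affine-transformed hash values are laid out once per
hash function and each window's minimum is taken with an O(n) two-pass
block (prefix/suffix) sliding-minimum, bit-identical to recomputing each
window from scratch.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np

from .kmers import KmerFilter, kmer_profile, seq_to_codes, canonical_codes

UINT64_MAX = np.uint64(0xFFFFFFFFFFFFFFFF)

_HASH_FAMILY_STREAM = 0x6D696E68  # domain tag for seed derivation


def splitmix64(x: np.ndarray) -> np.ndarray:
    """Fast 64-bit mixer used as the base kmer hash H in vanilla mode."""
    z = np.asarray(x, dtype=np.uint64).copy()
    z ^= z >> np.uint64(30)
    z *= np.uint64(0xBF58476D1CE4E5B9)
    z ^= z >> np.uint64(27)
    z *= np.uint64(0x94D049BB133111EB)
    z ^= z >> np.uint64(31)
    return z


@dataclass
class HashFamily:
    """L universal hash functions h_i(x) = a_i*x + b_i over Z_2^64."""

    a: np.ndarray  # (L,) uint64, all odd
    b: np.ndarray  # (L,) uint64
    seed: int

    @property
    def L(self) -> int:
        return int(self.a.size)

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, HashFamily)
            and np.array_equal(self.a, other.a)
            and np.array_equal(self.b, other.b)
        )


def init_hash_family(L: int, seed: int) -> HashFamily:
    if L < 1:
        raise ValueError("L must be >= 1")
    rng = np.random.Generator(
        np.random.PCG64(np.random.SeedSequence([seed, _HASH_FAMILY_STREAM]))
    )
    a = rng.integers(0, 2**64, size=L, dtype=np.uint64) | np.uint64(1)
    b = rng.integers(0, 2**64, size=L, dtype=np.uint64)
    return HashFamily(a=a, b=b, seed=seed)


@dataclass
class Fingerprint:
    """L per-hash-function minima over a sequence's surviving kmer set."""

    mins: np.ndarray  # (L,) uint64
    valid: bool
    n_kmers: int = 0
    family_seed: int = field(default=0, repr=False)

    @property
    def L(self) -> int:
        return int(self.mins.size)

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, Fingerprint)
            and self.valid == other.valid
            and np.array_equal(self.mins, other.mins)
        )


def fingerprint(
    kmers: Iterable[int] | np.ndarray,
    family: HashFamily,
    min_kmers: int = 1,
) -> Fingerprint:
    """Direct fingerprint of a kmer-code set (the rolling oracle path)."""
    codes = np.unique(np.fromiter(kmers, dtype=np.uint64)) if not isinstance(
        kmers, np.ndarray
    ) else np.unique(np.asarray(kmers, dtype=np.uint64))
    n = int(codes.size)
    if n == 0:
        return Fingerprint(
            mins=np.full(family.L, UINT64_MAX, dtype=np.uint64),
            valid=False,
            n_kmers=0,
            family_seed=family.seed,
        )
    hv = splitmix64(codes)
    # (L, n) affine transforms, wrap-around on uint64 is intentional
    vals = family.a[:, None] * hv[None, :] + family.b[:, None]
    return Fingerprint(
        mins=vals.min(axis=1),
        valid=n >= min_kmers,
        n_kmers=n,
        family_seed=family.seed,
    )


def jaccard_exact(A: Iterable[int], B: Iterable[int]) -> float:
    """|A ∩ B| / |A ∪ B|; 0 when both sets are empty."""
    sa, sb = set(A), set(B)
    union = len(sa | sb)
    return len(sa & sb) / union if union else 0.0


def jaccard_estimate(fa: Fingerprint, fb: Fingerprint) -> float:
    """Fraction of fingerprint entries shared by two valid fingerprints."""
    if not (fa.valid and fb.valid):
        raise ValueError("cannot estimate similarity from an invalid fingerprint")
    if fa.L != fb.L:
        raise ValueError(f"fingerprint lengths differ: {fa.L} != {fb.L}")
    if fa.family_seed != fb.family_seed:
        raise ValueError("fingerprints come from different hash families")
    return float(np.mean(fa.mins == fb.mins))


def sliding_min(a: np.ndarray, w: int) -> np.ndarray:
    """Minimum of every length-w window of ``a`` (van Herk two-pass)."""
    n = a.size
    m = n - w + 1
    if m <= 0:
        raise ValueError(f"window {w} exceeds array length {n}")
    if w == 1:
        return a.copy()
    nblocks = -(-n // w)
    pad = np.full(nblocks * w, UINT64_MAX, dtype=np.uint64)
    pad[:n] = a
    x = pad.reshape(nblocks, w)
    prefix = np.minimum.accumulate(x, axis=1).ravel()
    suffix = np.minimum.accumulate(x[:, ::-1], axis=1)[:, ::-1].ravel()
    return np.minimum(suffix[:m], prefix[w - 1 : w - 1 + m])


def window_minima(
    canon: np.ndarray,
    valid: np.ndarray,
    W: int,
    k: int,
    family: HashFamily,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-window fingerprint minima for every window of a sequence.

    Parameters are the per-position canonical codes and survival mask of
    the whole sequence. Returns ``(mins, counts)`` where ``mins`` is an
    (L, n_windows) uint64 matrix and ``counts`` the number of surviving
    kmers per window. Windows with zero survivors hold UINT64_MAX.

    Duplicate kmers within a window do not perturb the minima, so the
    per-position layout computes exactly the set-based fingerprint.
    """
    win = W - k + 1
    if canon.size < win:
        raise ValueError("sequence shorter than one window")
    hv = splitmix64(canon)
    ok = valid.astype(np.int64)
    csum = np.concatenate(([0], np.cumsum(ok)))
    counts = csum[win:] - csum[:-win]
    m = counts.size
    mins = np.empty((family.L, m), dtype=np.uint64)
    for i in range(family.L):
        vals = family.a[i] * hv + family.b[i]
        vals[~valid] = UINT64_MAX
        mins[i] = sliding_min(vals, win)
    return mins, counts


def rolling_fingerprints(
    seq: str,
    W: int,
    k: int,
    family: HashFamily,
    kfilter: KmerFilter | None = None,
    min_kmers: int | None = None,
) -> Iterator[tuple[int, Fingerprint]]:
    """Stream (window start, Fingerprint) for every window of ``seq``.

    Bit-identical to calling :func:`fingerprint` on each window's
    surviving kmer set, but computed in O(len(seq) * L) overall.
    """
    if len(seq) < W:
        raise ValueError(f"sequence length {len(seq)} < window {W}")
    if W < k:
        raise ValueError(f"window {W} < kmer length {k}")
    if min_kmers is None:
        min_kmers = max(1, int(0.8 * (W - k + 1)))
    canon, valid = kmer_profile(seq, k, kfilter)
    mins, counts = window_minima(canon, valid, W, k, family)
    for p in range(counts.size):
        yield p, Fingerprint(
            mins=mins[:, p].copy(),
            valid=int(counts[p]) >= min_kmers,
            n_kmers=int(counts[p]),
            family_seed=family.seed,
        )
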