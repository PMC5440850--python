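"""Algorithm parameters shared by indexing, candidate selection and voting."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Any

import yaml

MODES = ("vanilla", "secure")


@dataclass
class Params:
    """Tunable parameters of the two-phase aligner.

    Attributes
    ----------
    W : int
        Genome window length in bp; equal to the nominal read length.
    k_mh : int
        MinHash (phase-1) kmer length in bp.
    v : int
        Voting (phase-2) kmer length in bp.
    L : int
        Number of universal hash functions per MinHash fingerprint.
    T : int
        Number of LSH hash tables in the reference index.
    b : int
        Dimension of each fingerprint projection (entries per table key).
    M : int
        Bucket-address bits; each table has ``2**M`` buckets.
    beta : int
        Position-bin size for the secure transform (kmers per bin).
    rho : float
        Contig kmer sampling rate in (0, 1].
    n_conv : int
        Vote-convolution radius (positions collected on each side).
    b_min_hits : int
        Minimum number of distinct index tables that must contain a
        candidate for it to survive phase 1.
    alpha : int
        Mapping-quality scale: mapq = round(alpha * (r1 - r2) / r1).
    C_max : int
        Genome-wide occurrence count above which a MinHash kmer is
        considered repetitive and dropped.
    bucket_cap : int
        Buckets holding more entries are treated as high-frequency and
        skipped at lookup time.
    max_candidates : int
        At most this many top-ranked candidates proceed to voting.
    min_kmers : int | None
        Minimum surviving kmers for a fingerprint to be "valid";
        ``None`` means 80% of the nominal kmer count W - k_mh + 1.
    seed : int
        Master RNG seed; every random choice derives from it.
    mode : str
        ``"secure"`` (keyed hashing, masking, binning, sampling) or
        ``"vanilla"`` (plain hashing, exact positions).
    """

    W: int = 150
    k_mh: int = 20
    v: int = 20
    L: int = 128
    T: int = 78
    b: int = 2
    M: int = 18
    beta: int = 20
    rho: float = 1.0
    n_conv: int = 10
    b_min_hits: int = 2
    alpha: int = 60
    C_max: int = 1000
    bucket_cap: int = 5000
    max_candidates: int = 30
    min_kmers: int | None = None
    seed: int = 7
    mode: str = "secure"

    def __post_init__(self) -> None:
        if self.b > self.L:
            raise ValueError(f"b={self.b} must not exceed L={self.L}")
        if self.beta < 1:
            raise ValueError("beta must be >= 1")
        if not (0.0 < self.rho <= 1.0):
            raise ValueError("rho must be in (0, 1]")
        if self.M > 32:
            raise ValueError("M must be <= 32")
        if self.v > self.W:
            raise ValueError(f"v={self.v} must not exceed W={self.W}")
        if self.k_mh > self.W:
            raise ValueError(f"k_mh={self.k_mh} must not exceed W={self.W}")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if self.L < 1 or self.T < 1 or self.n_conv < 0:
            raise ValueError("L, T must be >= 1 and n_conv >= 0")

    def effective_min_kmers(self, length: int | None = None) -> int:
        """Validity threshold for a fingerprint over ``length`` bp.

        Defaults to 80% of the full kmer complement of the sequence.
        """
        if self.min_kmers is not None:
            return self.min_kmers
        n = (length if length is not None else self.W) - self.k_mh + 1
        return max(1, int(0.8 * n))

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "Params":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown parameter(s): {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str, **overrides: Any) -> "Params":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        d.update(overrides)
        return cls.from_dict(d)
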