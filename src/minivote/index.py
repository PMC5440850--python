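"""The MinHash reference genome index (MHG).

T hash tables of 2^M buckets store genome windows keyed by b-dimensional
projections of their MinHash fingerprints. Runs of consecutive windows
that land in the same bucket of the same table are compressed into
single (start, length) contig entries; expanding all entries of a table
reproduces the per-window bucketing exactly.
"""

from __future__ import annotations

import json
import struct
from dataclasses import dataclass

import numpy as np

from .kmers import KmerFilter, build_kmer_filter, kmer_profile
from .minhash import Fingerprint, HashFamily, init_hash_family, window_minima
from .params import Params
from .seqio import ReferenceSequence

_PROJ_STREAM = 0x70726F6A
_MAGIC = b"MHGX"
_VERSION = 1

# Contig entries are (start, length) int64 pairs, sorted by start and
# maximally merged within each bucket.
ContigEntry = tuple[int, int]


@dataclass
class ProjectionSet:
    """T fixed b-dimensional projections plus the multiply-shift key A."""

    P: np.ndarray  # (T, b) int64 indices into [0, L)
    A: np.ndarray  # (b,) uint64, all odd
    M: int
    seed: int

    @property
    def T(self) -> int:
        return int(self.P.shape[0])

    @property
    def b(self) -> int:
        return int(self.P.shape[1])


def init_projections(T: int, b: int, L: int, M: int, seed: int) -> ProjectionSet:
    """Draw T index vectors (without replacement per table) and the A key."""
    if b > L:
        raise ValueError(f"b={b} must not exceed L={L}")
    if T < 1:
        raise ValueError("T must be >= 1")
    rng = np.random.Generator(
        np.random.PCG64(np.random.SeedSequence([seed, _PROJ_STREAM]))
    )
    P = np.stack([rng.choice(L, size=b, replace=False) for _ in range(T)])
    A = rng.integers(0, 2**64, size=b, dtype=np.uint64) | np.uint64(1)
    return ProjectionSet(P=P.astype(np.int64), A=A, M=M, seed=seed)


def bucket_hash(F: Fingerprint, t: int, proj: ProjectionSet) -> int:
    """Multiply-shift bucket address of fingerprint F in table t."""
    if not F.valid:
        raise ValueError("cannot bucket an invalid fingerprint")
    if not 0 <= t < proj.T:
        raise ValueError(f"table id {t} outside [0, {proj.T})")
    return int(_bucket_matrix(F.mins[:, None], proj)[t, 0])


def _bucket_matrix(mins: np.ndarray, proj: ProjectionSet) -> np.ndarray:
    """Bucket ids for all tables x windows at once; shape (T, n_windows)."""
    sel = mins[proj.P]  # (T, b, n)
    acc = np.zeros((proj.T, sel.shape[2]), dtype=np.uint64)
    for i in range(proj.b):
        acc += proj.A[i] * sel[:, i, :]
    return (acc >> np.uint64(64 - proj.M)).astype(np.uint64)


class MHGIndex:
    """T bucket tables of contig-compressed genome window positions."""

    def __init__(
        self,
        params: Params,
        family: HashFamily,
        projections: ProjectionSet,
        kfilter: KmerFilter,
        tables: list[dict[int, np.ndarray]],
        n_windows: int,
    ):
        self.params = params
        self.family = family
        self.projections = projections
        self.kfilter = kfilter
        # tables[t]: bucket id -> (n, 2) int64 array of (start, len) entries
        self.tables = tables
        self.n_windows = n_windows  # number of valid-fingerprint windows

    def lookup(self, F: Fingerprint) -> list[np.ndarray] | None:
        """Bucket contents of F in every table; None if F is invalid.

        High-frequency buckets (more than ``bucket_cap`` entries) are
        skipped, mirroring repetitive-region suppression.
        """
        if not F.valid:
            return None
        buckets = _bucket_matrix(F.mins[:, None], self.projections)[:, 0]
        empty = np.empty((0, 2), dtype=np.int64)
        out = []
        for t in range(self.projections.T):
            entries = self.tables[t].get(int(buckets[t]))
            if entries is None or entries.shape[0] > self.params.bucket_cap:
                out.append(empty)
            else:
                out.append(entries)
        return out


def _compress_runs(
    gpos: np.ndarray, buckets: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Split the position-sorted window stream into same-bucket runs.

    Returns (run starts, run lengths, run bucket ids). A run breaks when
    the window position jumps or the bucket changes.
    """
    n = gpos.size
    if n == 0:
        z = np.empty(0, dtype=np.int64)
        return z, z, np.empty(0, dtype=np.uint64)
    brk = np.flatnonzero((np.diff(gpos) != 1) | (np.diff(buckets) != 0))
    starts_idx = np.concatenate(([0], brk + 1))
    ends_idx = np.concatenate((brk, [n - 1]))
    return gpos[starts_idx], ends_idx - starts_idx + 1, buckets[starts_idx]


def build_index(refs: list[ReferenceSequence], params: Params) -> MHGIndex:
    """Index every window of every reference sequence.

    Windows whose fingerprint is invalid (too few surviving kmers) are
    not indexed and do not appear in any bucket.
    """
    W, k = params.W, params.k_mh
    for r in refs:
        if len(r) < W:
            raise ValueError(
                f"reference {r.name!r} is shorter ({len(r)}) than the window ({W})"
            )
    family = init_hash_family(params.L, params.seed)
    proj = init_projections(params.T, params.b, params.L, params.M, params.seed)
    kfilter = build_kmer_filter(refs, k, params.C_max)
    min_kmers = params.effective_min_kmers()

    T = params.T
    acc: list[dict[int, list[np.ndarray]]] = [dict() for _ in range(T)]
    n_windows = 0
    for r in refs:
        canon, valid = kmer_profile(r.seq, k, kfilter)
        mins, counts = window_minima(canon, valid, W, k, family)
        ok = counts >= min_kmers
        if not np.any(ok):
            continue
        gpos = np.flatnonzero(ok).astype(np.int64) + r.offset
        n_windows += int(gpos.size)
        bmat = _bucket_matrix(mins[:, ok], proj)
        for t in range(T):
            starts, lens, bids = _compress_runs(gpos, bmat[t])
            order = np.argsort(bids, kind="stable")
            bids_s = bids[order]
            bounds = np.flatnonzero(np.diff(bids_s)) + 1
            for grp, bid in zip(
                np.split(order, bounds),
                bids_s[np.concatenate(([0], bounds))] if bids_s.size else [],
            ):
                entries = np.column_stack((starts[grp], lens[grp]))
                acc[t].setdefault(int(bid), []).append(entries)

    tables: list[dict[int, np.ndarray]] = []
    for t in range(T):
        table = {}
        for bid, chunks in acc[t].items():
            entries = np.concatenate(chunks) if len(chunks) > 1 else chunks[0]
            # refs are processed in offset order, so entries stay sorted
            table[bid] = entries
        tables.append(table)
    return MHGIndex(params, family, proj, kfilter, tables, n_windows)


def save_index(index: MHGIndex, path: str) -> None:
    """Versioned little-endian binary dump with a JSON parameter header."""
    header = {
        "version": _VERSION,
        "params": index.params.to_dict(),
        "n_windows": index.n_windows,
        "n_repetitive": len(index.kfilter),
    }
    hjson = json.dumps(header).encode()
    with open(path, "wb") as fh:
        fh.write(_MAGIC)
        fh.write(struct.pack("<I", len(hjson)))
        fh.write(hjson)
        fh.write(index.kfilter.repetitive.astype("<u8").tobytes())
        for t in range(index.params.T):
            table = index.tables[t]
            fh.write(struct.pack("<I", len(table)))
            for bid in sorted(table):
                entries = table[bid]
                fh.write(struct.pack("<QI", bid, entries.shape[0]))
                fh.write(entries.astype("<i8").tobytes())


def load_index(path: str) -> MHGIndex:
    with open(path, "rb") as fh:
        magic = fh.read(4)
        if magic != _MAGIC:
            raise ValueError(f"{path} is not an MHG index file")
        (hlen,) = struct.unpack("<I", fh.read(4))
        header = json.loads(fh.read(hlen))
        if header.get("version") != _VERSION:
            raise ValueError(
                f"unsupported index version {header.get('version')!r}"
            )
        params = Params.from_dict(header["params"])
        rep = np.frombuffer(
            fh.read(8 * header["n_repetitive"]), dtype="<u8"
        ).astype(np.uint64)
        tables: list[dict[int, np.ndarray]] = []
        for _ in range(params.T):
            (nbuckets,) = struct.unpack("<I", fh.read(4))
            table = {}
            for _ in range(nbuckets):
                bid, n = struct.unpack("<QI", fh.read(12))
                entries = np.frombuffer(fh.read(16 * n), dtype="<i8")
                table[int(bid)] = entries.reshape(n, 2).astype(np.int64)
            tables.append(table)
        trailing = fh.read(1)
        if trailing:
            raise ValueError(f"corrupt index file {path}: trailing bytes")
    family = init_hash_family(params.L, params.seed)
    proj = init_projections(params.T, params.b, params.L, params.M, params.seed)
    kfilter = KmerFilter(params.k_mh, rep, params.C_max)
    return MHGIndex(params, family, proj, kfilter, tables, header["n_windows"])
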