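"""Phase-2 kmer voting and the privacy-preserving transform.

A voting task is one (read, candidate-contig) pair. The client applies
the secure transform — per-task keyed hashing, local-repeat masking,
position binning with in-bin shuffling, and contig-kmer sampling — and
ships only hashed values with bin indices. The untrusted side detects
kmer matches, casts displacement votes, convolves them to absorb indel
jitter, and returns the best displacement with its vote count; the
client maps displacements back to genome coordinates and derives the
mapping quality from the best and second-best scores.

Kmer hashing: h_K(s) is the first 64 bits of HMAC-SHA1 of the packed
kmer under a 256-bit session secret K; each task rekeys every value as
((h_K(s) XOR k1) * k2) mod 2^64 with fresh (k1, k2), k2 odd, so that
matches are detectable within a task but never across tasks.
"""

from __future__ import annotations

import hashlib
import hmac
import struct
from dataclasses import dataclass, field
from math import floor

import numpy as np

from .kmers import forward_codes, seq_to_codes
from .minhash import splitmix64
from .params import Params

MASK64 = 0xFFFFFFFFFFFFFFFF

_TASK_HDR = struct.Struct("<QHHIII")  # task_id, beta, n_conv, n_read, n_contig, pad
_RESULT_FMT = struct.Struct("<Qqi")  # task_id, displacement, score


@dataclass
class TaskKeys:
    """Session secret plus the per-task rekeying pair."""

    K: bytes  # 256-bit session secret
    k1: int  # 64-bit xor key
    k2: int  # odd 64-bit multiplier

    def __post_init__(self) -> None:
        if len(self.K) != 32:
            raise ValueError("session key K must be 32 bytes (256 bits)")
        if self.k2 % 2 == 0:
            raise ValueError("k2 must be odd (bijectivity modulo 2^64)")


def keyed_base_hash(code: int, K: bytes) -> int:
    """h_K: first 64 bits of HMAC-SHA1 of the packed kmer under K."""
    digest = hmac.new(K, int(code).to_bytes(8, "big"), hashlib.sha1).digest()
    return int.from_bytes(digest[:8], "big")


def keyed_kmer_hash(code: int, keys: TaskKeys) -> int:
    """Per-task kmer hash ((h_K(s) XOR k1) * k2) mod 2^64."""
    return ((keyed_base_hash(code, keys.K) ^ keys.k1) * keys.k2) & MASK64


def rekey(base: np.ndarray, keys: TaskKeys) -> np.ndarray:
    """Vectorized per-task rekeying of precomputed h_K values."""
    out = np.asarray(base, dtype=np.uint64) ^ np.uint64(keys.k1)
    out = out * np.uint64(keys.k2)
    return out


class KeyedHashCache:
    """Memoized h_K evaluation (HMAC is the per-kmer hot spot)."""

    def __init__(self, K: bytes):
        self.K = K
        self._cache: dict[int, int] = {}

    def get(self, codes: np.ndarray) -> np.ndarray:
        out = np.empty(codes.size, dtype=np.uint64)
        cache = self._cache
        K = self.K
        for i, c in enumerate(codes.tolist()):
            h = cache.get(c)
            if h is None:
                h = keyed_base_hash(c, K)
                cache[c] = h
            out[i] = h
        return out


def voting_kmers(seq: str, v: int) -> tuple[np.ndarray, np.ndarray]:
    """Strand-specific packed v-mers and their no-N validity mask.

    Voting kmers are deliberately not canonicalized: orientation is
    resolved by running each read in both orientations and letting the
    higher-scoring one win, which requires strand-specific matching.
    """
    return forward_codes(seq_to_codes(seq), v)


def _enforce_min_runs(mask: np.ndarray, v: int) -> np.ndarray:
    """Extend every maximal masked run to length >= v (in place)."""
    n = mask.size
    if not mask.any():
        return mask
    if n < v:
        mask[:] = True
        return mask
    idx = np.flatnonzero(mask)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([idx[0]], idx[breaks + 1]))
    ends = np.concatenate((idx[breaks], [idx[-1]]))
    for s, e in zip(starts, ends):
        run = e - s + 1
        if run < v:
            grow = v - run
            right = min(n, e + 1 + grow)
            grow -= right - (e + 1)
            left = max(0, s - grow)
            mask[left:right] = True
    return mask


def mask_repeats(codes: np.ndarray, valid: np.ndarray, v: int) -> np.ndarray:
    """Local-repeat-structure mask over kmer positions.

    Every kmer occurring more than once within the sequence (and every
    N-containing kmer) is masked together with its neighbours so that
    each repeat sits inside a maximal masked run of at least v kmers —
    otherwise a match/mismatch pattern would betray where masking
    happened.
    """
    n = codes.size
    masked = ~valid.copy()
    if n == 0:
        return masked
    vals, counts = np.unique(codes[valid], return_counts=True)
    dup = vals[counts > 1]
    if dup.size:
        masked |= np.isin(codes, dup) & valid
    if masked.any():
        # dilate each seed by v-1 on both sides (centre slice of the
        # full convolution; 'same' misbehaves when the kernel is longer)
        kernel = np.ones(2 * v - 1, dtype=np.int64)
        full = np.convolve(masked.astype(np.int64), kernel, mode="full")
        masked = full[v - 1 : v - 1 + n] > 0
        masked = _enforce_min_runs(masked, v)
    return masked


@dataclass
class VotingTask:
    """One secure-transformed read/contig-chunk pair.

    The ``*_hvals`` / ``*_bins`` arrays are the only payload the cloud
    sees; everything else is client-side bookkeeping (keys, genomic
    anchor, which payload entries are maskers) used for finalization
    and for auditing the no-leak invariants.
    """

    task_id: int
    beta: int
    n_conv: int
    read_hvals: np.ndarray
    read_bins: np.ndarray
    contig_hvals: np.ndarray
    contig_bins: np.ndarray
    pad: int
    # client-side bookkeeping
    keys: TaskKeys | None = None
    chunk_gstart: int = 0
    strand: str = "+"
    read_payload_masked: np.ndarray | None = field(default=None, repr=False)
    contig_payload_masked: np.ndarray | None = field(default=None, repr=False)
    read_pos_masked: np.ndarray | None = field(default=None, repr=False)
    contig_pos_masked: np.ndarray | None = field(default=None, repr=False)


def serialize_task(task: VotingTask) -> bytes:
    """The exact client-to-cloud byte payload of one task."""
    return b"".join(
        (
            _TASK_HDR.pack(
                task.task_id,
                task.beta,
                task.n_conv,
                task.read_hvals.size,
                task.contig_hvals.size,
                task.pad,
            ),
            task.read_hvals.astype("<u8").tobytes(),
            task.read_bins.astype("<i4").tobytes(),
            task.contig_hvals.astype("<u8").tobytes(),
            task.contig_bins.astype("<i4").tobytes(),
        )
    )


def deserialize_task(buf: bytes) -> VotingTask:
    """Reconstruct the cloud's view of a task (payload fields only)."""
    task_id, beta, n_conv, n_read, n_contig, pad = _TASK_HDR.unpack_from(buf)
    off = _TASK_HDR.size
    read_hvals = np.frombuffer(buf, dtype="<u8", count=n_read, offset=off)
    off += 8 * n_read
    read_bins = np.frombuffer(buf, dtype="<i4", count=n_read, offset=off)
    off += 4 * n_read
    contig_hvals = np.frombuffer(buf, dtype="<u8", count=n_contig, offset=off)
    off += 8 * n_contig
    contig_bins = np.frombuffer(buf, dtype="<i4", count=n_contig, offset=off)
    off += 4 * n_contig
    if off != len(buf):
        raise ValueError("task payload has trailing bytes")
    return VotingTask(
        task_id=task_id,
        beta=beta,
        n_conv=n_conv,
        read_hvals=read_hvals.astype(np.uint64),
        read_bins=read_bins.astype(np.int64),
        contig_hvals=contig_hvals.astype(np.uint64),
        contig_bins=contig_bins.astype(np.int64),
        pad=pad,
    )


def serialize_result(task_id: int, displacement: int, score: int) -> bytes:
    return _RESULT_FMT.pack(task_id, displacement, score)


def deserialize_result(buf: bytes) -> tuple[int, int, int]:
    return _RESULT_FMT.unpack(buf)


def _rand64(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.integers(0, 2**64, size=n, dtype=np.uint64)


def build_task(
    task_id: int,
    read_codes: np.ndarray,
    read_valid: np.ndarray,
    contig_codes: np.ndarray,
    contig_valid: np.ndarray,
    params: Params,
    keys: TaskKeys,
    rng: np.random.Generator,
    chunk_gstart: int,
    strand: str,
    read_base: np.ndarray | None = None,
    contig_base: np.ndarray | None = None,
    pad_to: int | None = None,
) -> VotingTask:
    """Apply the secure (or vanilla) transform to one read/chunk pair.

    ``read_base`` / ``contig_base`` are optional precomputed h_K arrays
    aligned with the code arrays (secure mode only); ``pad_to`` is the
    uniform contig payload length for chunked contigs.
    """
    v, rho = params.v, params.rho
    secure = params.mode == "secure"
    beta = params.beta if secure else 1

    if not secure:
        r_keep = np.flatnonzero(read_valid)
        c_keep = np.flatnonzero(contig_valid)
        if rho < 1.0 and c_keep.size:
            c_keep = c_keep[rng.random(c_keep.size) < rho]
        task = VotingTask(
            task_id=task_id,
            beta=1,
            n_conv=params.n_conv,
            read_hvals=splitmix64(read_codes[r_keep]),
            read_bins=r_keep.astype(np.int64),
            contig_hvals=splitmix64(contig_codes[c_keep]),
            contig_bins=c_keep.astype(np.int64),
            pad=0,
            keys=keys,
            chunk_gstart=chunk_gstart,
            strand=strand,
            read_payload_masked=np.zeros(r_keep.size, dtype=bool),
            contig_payload_masked=np.zeros(c_keep.size, dtype=bool),
            read_pos_masked=~read_valid,
            contig_pos_masked=~contig_valid,
        )
        return task

    # --- secure transform ---
    r_masked = mask_repeats(read_codes, read_valid, v)
    c_masked = mask_repeats(contig_codes, contig_valid, v)

    def _hashed(codes, base, masked):
        hv = np.empty(codes.size, dtype=np.uint64)
        keep = ~masked
        if keep.any():
            if base is None:
                base_vals = np.fromiter(
                    (keyed_base_hash(int(c), keys.K) for c in codes[keep]),
                    dtype=np.uint64,
                    count=int(keep.sum()),
                )
            else:
                base_vals = base[keep]
            hv[keep] = rekey(base_vals, keys)
        hv[masked] = _rand64(rng, int(masked.sum()))
        return hv

    r_hv = _hashed(read_codes, read_base, r_masked)
    c_hv = _hashed(contig_codes, contig_base, c_masked)

    # read: every kmer is shipped, binned and shuffled within bins
    nr = read_codes.size
    r_bins = np.arange(nr, dtype=np.int64) // beta
    perm = np.lexsort((rng.random(nr), r_bins))
    read_hvals = r_hv[perm]
    read_bins = r_bins[perm]
    read_payload_masked = r_masked[perm]

    # contig: per-bin sampling at rate rho; bins that cannot supply
    # their quota of unique unmasked kmers are masked entirely
    nc = contig_codes.size
    nbins = -(-nc // beta) if nc else 0
    hv_parts: list[np.ndarray] = []
    bin_parts: list[np.ndarray] = []
    masked_parts: list[np.ndarray] = []
    for i in range(nbins):
        lo, hi = i * beta, min((i + 1) * beta, nc)
        size = hi - lo
        quota = max(1, floor(size * rho))
        unmasked = lo + np.flatnonzero(~c_masked[lo:hi])
        if unmasked.size >= quota:
            if unmasked.size > quota:
                pick = rng.choice(unmasked, size=quota, replace=False)
            else:
                pick = unmasked
            vals = c_hv[pick]
            rng.shuffle(vals)
            sent_masked = np.zeros(quota, dtype=bool)
        else:
            vals = _rand64(rng, quota)
            sent_masked = np.ones(quota, dtype=bool)
            c_masked[lo:hi] = True
        hv_parts.append(vals)
        bin_parts.append(np.full(quota, i, dtype=np.int64))
        masked_parts.append(sent_masked)

    # pad the payload to the uniform chunk length with random kmers
    pad = 0
    if pad_to is not None:
        sent = sum(p.size for p in hv_parts)
        pad = max(0, pad_to - sent)
        if pad:
            quota_full = max(1, floor(beta * rho))
            hv_parts.append(_rand64(rng, pad))
            bin_parts.append(
                nbins + np.arange(pad, dtype=np.int64) // quota_full
            )
            masked_parts.append(np.ones(pad, dtype=bool))

    cat = lambda parts, dt: (
        np.concatenate(parts) if parts else np.empty(0, dtype=dt)
    )
    return VotingTask(
        task_id=task_id,
        beta=beta,
        n_conv=params.n_conv,
        read_hvals=read_hvals,
        read_bins=read_bins,
        contig_hvals=cat(hv_parts, np.uint64),
        contig_bins=cat(bin_parts, np.int64),
        pad=pad,
        keys=keys,
        chunk_gstart=chunk_gstart,
        strand=strand,
        read_payload_masked=read_payload_masked,
        contig_payload_masked=cat(masked_parts, bool),
        read_pos_masked=r_masked,
        contig_pos_masked=c_masked,
    )


def contig_chunks(contig_len: int, read_len: int) -> list[tuple[int, int]]:
    """Split a contig into cap-length chunks overlapping by a read length.

    The cap is twice the read length, so a chunked task never reveals
    the true contig length; overlap of one read length guarantees every
    alignment position lies fully inside some chunk.
    """
    cap = 2 * read_len
    if contig_len <= cap:
        return [(0, contig_len)]
    step = cap - read_len
    starts = list(range(0, contig_len - cap, step)) + [contig_len - cap]
    return [(s, s + cap) for s in starts]


def chunk_payload_target(read_len: int, params: Params) -> int:
    """Uniform contig payload length of a full cap-length chunk."""
    if params.mode != "secure":
        return 0
    cap = 2 * read_len
    n = cap - params.v + 1
    beta, rho = params.beta, params.rho
    full, tail = divmod(n, beta)
    total = full * max(1, floor(beta * rho))
    if tail:
        total += max(1, floor(tail * rho))
    return total


def prepare_voting_tasks(
    read_seq: str,
    contig_seq: str,
    contig_gstart: int,
    strand: str,
    params: Params,
    session_key: bytes,
    rng: np.random.Generator,
    first_task_id: int = 0,
    contig_codes: np.ndarray | None = None,
    contig_valid: np.ndarray | None = None,
    contig_base: np.ndarray | None = None,
    read_cache: KeyedHashCache | None = None,
) -> list[VotingTask]:
    """Transform one read/candidate pair into one task per contig chunk."""
    if len(read_seq) < params.v:
        raise ValueError("read shorter than the voting kmer length")
    if len(contig_seq) < len(read_seq):
        raise ValueError("candidate contig shorter than the read")
    r_codes, r_valid = voting_kmers(read_seq, params.v)
    if contig_codes is None:
        contig_codes, contig_valid = voting_kmers(contig_seq, params.v)
    secure = params.mode == "secure"
    r_base = None
    if secure:
        cache = read_cache or KeyedHashCache(session_key)
        r_base = cache.get(r_codes)

    chunks = contig_chunks(len(contig_seq), len(read_seq))
    pad_to = chunk_payload_target(len(read_seq), params) if len(chunks) > 1 else None
    tasks = []
    for ci, (s, e) in enumerate(chunks):
        nk = (e - s) - params.v + 1
        keys = TaskKeys(
            K=session_key,
            k1=int(rng.integers(0, 2**64, dtype=np.uint64)),
            k2=int(rng.integers(0, 2**64, dtype=np.uint64)) | 1,
        )
        tasks.append(
            build_task(
                task_id=first_task_id + ci,
                read_codes=r_codes,
                read_valid=r_valid,
                contig_codes=contig_codes[s : s + nk],
                contig_valid=contig_valid[s : s + nk],
                params=params,
                keys=keys,
                rng=rng,
                chunk_gstart=contig_gstart + s,
                strand=strand,
                read_base=r_base,
                contig_base=None if contig_base is None else contig_base[s : s + nk],
                pad_to=pad_to,
            )
        )
    return tasks


@dataclass
class VoteVector:
    """Votes indexed by candidate displacement phi = p_C - p_R."""

    V: np.ndarray  # raw votes
    phi_min: int  # displacement of V[0]
    Vconv: np.ndarray | None = None
    conv_phi_min: int | None = None


def cast_votes(task: VotingTask) -> VoteVector:
    """Count displacement votes from all equal-hash read/contig pairs.

    With bins of size beta, a matched pair whose kmers lie in read bin
    [l_R, h_R) and contig bin [l_C, h_C) votes once for every
    displacement in [l_C - h_R + 1, h_C - l_R) — exactly the set of
    p_C - p_R values the hidden positions could take. beta == 1 reduces
    to a single vote at the exact displacement.
    """
    r_h, r_b = task.read_hvals, task.read_bins
    c_h, c_b = task.contig_hvals, task.contig_bins
    beta = task.beta
    if r_h.size == 0 or c_h.size == 0:
        return VoteVector(V=np.zeros(1, dtype=np.int64), phi_min=0)

    phi_min = int(c_b.min() - r_b.max()) * beta - beta + 1
    phi_max = int(c_b.max() - r_b.min()) * beta + beta - 1
    width = phi_max - phi_min + 1
    diff = np.zeros(width + 1, dtype=np.int64)

    order = np.argsort(c_h, kind="stable")
    cs = c_h[order]
    left = np.searchsorted(cs, r_h, side="left")
    right = np.searchsorted(cs, r_h, side="right")
    counts = right - left
    hit = np.flatnonzero(counts)
    if hit.size:
        ri = np.repeat(hit, counts[hit])
        ci = np.concatenate([order[left[i] : right[i]] for i in hit])
        lo = (c_b[ci] - r_b[ri]) * beta - beta + 1 - phi_min
        np.add.at(diff, lo, 1)
        np.add.at(diff, lo + 2 * beta - 1, -1)
    V = np.cumsum(diff[:-1])
    return VoteVector(V=V, phi_min=phi_min)


def convolve_votes(votes: VoteVector, n_conv: int) -> VoteVector:
    """Window-sum of radius n_conv: Vconv[j] = sum_{|i-j|<=n_conv} V[i]."""
    if n_conv == 0:
        votes.Vconv = votes.V.copy()
        votes.conv_phi_min = votes.phi_min
        return votes
    kernel = np.ones(2 * n_conv + 1, dtype=np.int64)
    votes.Vconv = np.convolve(votes.V, kernel, mode="full")
    votes.conv_phi_min = votes.phi_min - n_conv
    return votes


def score_task(votes: VoteVector) -> tuple[int, int]:
    """Best displacement and its convolved vote count.

    Ties (a plateau of equal maxima) resolve to the middle position —
    the lower median of the tied displacements. A zero score means the
    task produced no evidence.
    """
    vc = votes.Vconv
    if vc is None:
        raise ValueError("convolve_votes must run before scoring")
    score = int(vc.max()) if vc.size else 0
    if score <= 0:
        return 0, 0
    idx = np.flatnonzero(vc == score)
    pick = int(idx[(idx.size - 1) // 2])
    return votes.conv_phi_min + pick, score


def process_task_bytes(buf: bytes) -> bytes:
    """The whole untrusted-side computation for one serialized task."""
    task = deserialize_task(buf)
    votes = convolve_votes(cast_votes(task), task.n_conv)
    disp, score = score_task(votes)
    return serialize_result(task.task_id, disp, score)


@dataclass
class TaskResult:
    """Client-side view of one task outcome, in genome coordinates."""

    gpos: int
    strand: str
    score: int


@dataclass
class AlignmentResult:
    read_id: str
    gpos: int
    strand: str
    r1: int
    r2: int
    mapq: int
    mapped: bool


def compute_mapq(r1: int, r2: int, alpha: int) -> int:
    """round(alpha * (r1 - r2) / r1), clamped to [0, alpha]."""
    if r1 <= 0 or r2 >= r1:
        return 0
    return max(0, min(alpha, round(alpha * (r1 - r2) / r1)))


def finalize_alignment(
    read_id: str,
    results: list[TaskResult],
    alpha: int,
    W: int,
) -> AlignmentResult:
    """Pick the best-scoring task; the runner-up must be a genuinely
    different locus (more than W bp from the winner) to depress mapq."""
    scored = [r for r in results if r.score > 0]
    if not scored:
        return AlignmentResult(read_id, -1, "+", 0, 0, 0, mapped=False)
    scored.sort(key=lambda r: (-r.score, r.gpos, r.strand))
    best = scored[0]
    r1 = best.score
    r2 = max(
        (r.score for r in scored[1:] if abs(r.gpos - best.gpos) > W),
        default=0,
    )
    return AlignmentResult(
        read_id=read_id,
        gpos=best.gpos,
        strand=best.strand,
        r1=r1,
        r2=r2,
        mapq=compute_mapq(r1, r2, alpha),
        mapped=True,
    )
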