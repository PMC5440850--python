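"""End-to-end alignment: the client/cloud phase split, SAM output and
accuracy evaluation.

The untrusted ("cloud") side is simulated in-process behind a strict
serialization boundary: voting consumes only the serialized task bytes
produced by the client, so by construction it never sees raw sequence,
genome coordinates or keys — only per-task keyed hashes and bin ids.
Byte counts of the task and result streams feed the bandwidth report.
"""

from __future__ import annotations

import hashlib
import time
from dataclasses import dataclass, field

import numpy as np
import pysam

from .candidates import select_candidates
from .index import MHGIndex
from .params import Params
from .seqio import GenomeCoordinates, ReadRecord, ReferenceSequence, revcomp
from .simulate import TruthRecord
from .voting import (
    AlignmentResult,
    KeyedHashCache,
    TaskKeys,
    TaskResult,
    build_task,
    chunk_payload_target,
    contig_chunks,
    deserialize_result,
    finalize_alignment,
    keyed_base_hash,
    process_task_bytes,
    serialize_task,
    voting_kmers,
)

_ALIGN_STREAM = 0x616C6E


def session_key(seed: int) -> bytes:
    """Derive the 256-bit voting session secret from the master seed."""
    return hashlib.sha256(f"minivote-session-{seed}".encode()).digest()


@dataclass
class AlignStats:
    """Per-run counters: phase wall times and client/cloud traffic."""

    n_reads: int = 0
    n_mapped: int = 0
    n_tasks: int = 0
    tasks_bytes: int = 0
    results_bytes: int = 0
    candidates_per_read: list[int] = field(default_factory=list)
    phase_seconds: dict[str, float] = field(
        default_factory=lambda: {
            "fingerprinting_selection": 0.0,
            "encryption_masking": 0.0,
            "voting": 0.0,
            "reporting": 0.0,
        }
    )


def bandwidth_report(stats: AlignStats) -> dict[str, int]:
    """Exact serialized byte counts shipped in each direction."""
    return {
        "tasks_bytes": stats.tasks_bytes,
        "results_bytes": stats.results_bytes,
    }


class _ReferenceVotingHashes:
    """Per-reference voting-kmer codes with optional precomputed h_K."""

    def __init__(self, refs: list[ReferenceSequence], params: Params, key: bytes | None):
        self.codes: list[np.ndarray] = []
        self.valid: list[np.ndarray] = []
        self.base: list[np.ndarray | None] = []
        self.cache = KeyedHashCache(key) if key is not None else None
        for r in refs:
            codes, valid = voting_kmers(r.seq, params.v)
            self.codes.append(codes)
            self.valid.append(valid)
            if key is None:
                self.base.append(None)
                continue
            base = np.zeros(codes.size, dtype=np.uint64)
            if codes.size:
                uniq, inv = np.unique(codes[valid], return_inverse=True)
                ubase = np.fromiter(
                    (keyed_base_hash(int(c), key) for c in uniq),
                    dtype=np.uint64,
                    count=uniq.size,
                )
                base[valid] = ubase[inv]
                # reads share almost all their kmers with the genome:
                # seed the read-side cache with the genome table
                self.cache._cache.update(
                    zip(uniq.tolist(), ubase.tolist())
                )
            self.base.append(base)


def align(
    reads,
    index: MHGIndex,
    refs: list[ReferenceSequence],
    params: Params | None = None,
    sam_path: str | None = None,
) -> tuple[list[AlignmentResult], AlignStats]:
    """Align an iterable of reads, optionally writing a SAM file.

    The index must have been built with the same parameters; the per-read
    outcome list is returned together with phase statistics.
    """
    if params is None:
        params = index.params
    # voting knobs (mode, beta, rho, ...) are free at align time, but the
    # phase-1 parameters must match the ones the index was built with
    _INDEX_FIELDS = ("W", "k_mh", "L", "T", "b", "M", "C_max", "seed", "min_kmers")
    for f in _INDEX_FIELDS:
        if getattr(params, f) != getattr(index.params, f):
            raise ValueError(
                f"parameter {f} mismatch between index "
                f"({getattr(index.params, f)}) and configuration "
                f"({getattr(params, f)})"
            )
    coords = GenomeCoordinates(refs)
    secure = params.mode == "secure"
    key = session_key(params.seed) if secure else None
    ref_hashes = _ReferenceVotingHashes(refs, params, key)
    ref_index = {r.name: i for i, r in enumerate(refs)}

    stats = AlignStats()
    results: list[AlignmentResult] = []
    records: list[tuple[ReadRecord, AlignmentResult]] = []

    for ridx, read in enumerate(reads):
        stats.n_reads += 1
        t0 = time.perf_counter()
        cands = select_candidates(read, index) if len(read) >= params.k_mh else []
        t1 = time.perf_counter()
        stats.phase_seconds["fingerprinting_selection"] += t1 - t0
        stats.candidates_per_read.append(len(cands))
        if not cands:
            res = AlignmentResult(read.id, -1, "+", 0, 0, 0, mapped=False)
            results.append(res)
            records.append((read, res))
            continue

        rng = np.random.Generator(
            np.random.PCG64(
                np.random.SeedSequence([params.seed, _ALIGN_STREAM, ridx])
            )
        )
        rlen = len(read)
        oriented: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray | None]] = {}
        for strand, seq in (("+", read.seq), ("-", revcomp(read.seq))):
            codes, valid = voting_kmers(seq, params.v)
            base = ref_hashes.cache.get(codes) if secure else None
            oriented[strand] = (codes, valid, base)

        task_bufs: list[bytes] = []
        book: dict[int, tuple[int, str]] = {}
        tid = 0
        t2 = time.perf_counter()
        for cand in cands:
            for lo, hi in coords.clip_to_record(cand.gstart, cand.gend):
                if hi - lo < rlen:
                    continue
                ref, local = coords.locate(lo)
                i = ref_index[ref.name]
                chunks = contig_chunks(hi - lo, rlen)
                pad_to = (
                    chunk_payload_target(rlen, params) if len(chunks) > 1 else None
                )
                for s, e in chunks:
                    nk = (e - s) - params.v + 1
                    a, b = local + s, local + s + nk
                    c_codes = ref_hashes.codes[i][a:b]
                    c_valid = ref_hashes.valid[i][a:b]
                    c_base = (
                        ref_hashes.base[i][a:b] if secure else None
                    )
                    for strand in ("+", "-"):
                        r_codes, r_valid, r_base = oriented[strand]
                        keys = TaskKeys(
                            K=key if secure else b"\x00" * 32,
                            k1=int(rng.integers(0, 2**64, dtype=np.uint64)),
                            k2=int(rng.integers(0, 2**64, dtype=np.uint64)) | 1,
                        )
                        task = build_task(
                            task_id=tid,
                            read_codes=r_codes,
                            read_valid=r_valid,
                            contig_codes=c_codes,
                            contig_valid=c_valid,
                            params=params,
                            keys=keys,
                            rng=rng,
                            chunk_gstart=lo + s,
                            strand=strand,
                            read_base=r_base,
                            contig_base=c_base,
                            pad_to=pad_to,
                        )
                        buf = serialize_task(task)
                        task_bufs.append(buf)
                        book[tid] = (lo + s, strand)
                        tid += 1
        t3 = time.perf_counter()
        stats.phase_seconds["encryption_masking"] += t3 - t2
        stats.n_tasks += len(task_bufs)
        stats.tasks_bytes += sum(len(b) for b in task_bufs)

        # ---- untrusted side: bytes in, bytes out ----
        result_bufs = [process_task_bytes(b) for b in task_bufs]
        t4 = time.perf_counter()
        stats.phase_seconds["voting"] += t4 - t3
        stats.results_bytes += sum(len(b) for b in result_bufs)

        task_results: list[TaskResult] = []
        for buf in result_bufs:
            task_id, disp, score = deserialize_result(buf)
            if score <= 0:
                continue
            gstart, strand = book[task_id]
            gpos = gstart + disp
            # clamp junk displacements into the containing reference
            ref, _ = coords.locate(min(max(gpos, 0), coords.total - 1))
            gpos = min(max(gpos, ref.offset), ref.offset + len(ref) - rlen)
            task_results.append(TaskResult(gpos=gpos, strand=strand, score=score))
        res = finalize_alignment(read.id, task_results, params.alpha, params.W)
        if res.mapped:
            stats.n_mapped += 1
        results.append(res)
        records.append((read, res))
        stats.phase_seconds["reporting"] += time.perf_counter() - t4

    if sam_path is not None:
        t5 = time.perf_counter()
        write_sam(records, refs, sam_path, params)
        stats.phase_seconds["reporting"] += time.perf_counter() - t5
    return results, stats


def write_sam(
    records: list[tuple[ReadRecord, AlignmentResult]],
    refs: list[ReferenceSequence],
    path: str,
    params: Params,
) -> None:
    """Emit one SAM record per read (1-based coordinates, @HD/@SQ/@PG)."""
    coords = GenomeCoordinates(refs)
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": r.name, "LN": len(r)} for r in refs],
        "PG": [
            {
                "ID": "minivote",
                "PN": "minivote",
                "CL": f"minivote align --mode {params.mode}",
            }
        ],
    }
    name_to_id = {r.name: i for i, r in enumerate(refs)}
    with pysam.AlignmentFile(path, "w", header=header) as out:
        for read, res in records:
            a = pysam.AlignedSegment(out.header)
            a.query_name = read.id
            if res.mapped:
                ref, local = coords.locate(res.gpos)
                a.flag = 16 if res.strand == "-" else 0
                a.reference_id = name_to_id[ref.name]
                a.reference_start = local
                a.mapping_quality = res.mapq
                a.cigarstring = f"{len(read)}M"
                if res.strand == "-":
                    a.query_sequence = revcomp(read.seq)
                    a.query_qualities = pysam.qualitystring_to_array(
                        read.qual[::-1]
                    )
                else:
                    a.query_sequence = read.seq
                    a.query_qualities = pysam.qualitystring_to_array(read.qual)
                a.set_tag("AS", res.r1)
                a.set_tag("XS", res.r2)
            else:
                a.flag = 4
                a.reference_id = -1
                a.reference_start = -1
                a.mapping_quality = 0
                a.query_sequence = read.seq
                a.query_qualities = pysam.qualitystring_to_array(read.qual)
            out.write(a)


@dataclass
class EvalSummary:
    """Q10 yield and Q10 error, both as percentages of the stated sets."""

    pct_q10: float
    err_q10: float
    n_reads: int
    n_q10: int
    n_wrong: int


def evaluate(
    sam_path: str,
    truth: list[TruthRecord],
    qmin: int = 10,
    tol: int = 20,
) -> EvalSummary:
    """Score a SAM file against simulation ground truth.

    pct_q10: percentage of all reads mapped with mapq >= qmin.
    err_q10: percentage of those whose position is farther than ``tol``
    bp from the true position.
    """
    truth_by_id = {t.read_id: t for t in truth}
    n_q10 = 0
    n_wrong = 0
    with pysam.AlignmentFile(sam_path, "r") as sam:
        offsets = {}
        off = 0
        for sq in sam.header["SQ"]:
            offsets[sq["SN"]] = off
            off += sq["LN"]
        for rec in sam.fetch(until_eof=True):
            t = truth_by_id.get(rec.query_name)
            if t is None:
                raise ValueError(f"read {rec.query_name!r} missing from truth")
            if rec.is_unmapped or rec.mapping_quality < qmin:
                continue
            n_q10 += 1
            gpos = offsets[rec.reference_name] + rec.reference_start
            if abs(gpos - t.pos) > tol:
                n_wrong += 1
    n_reads = len(truth)
    pct = 100.0 * n_q10 / n_reads if n_reads else 0.0
    err = 100.0 * n_wrong / n_q10 if n_q10 else 0.0
    return EvalSummary(
        pct_q10=pct, err_q10=err, n_reads=n_reads, n_q10=n_q10, n_wrong=n_wrong
    )
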