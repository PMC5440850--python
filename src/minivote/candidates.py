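"""Phase-1 candidate contig selection on the private client.

The read is fingerprinted over its own kmer set, its T index buckets
are fetched, and the bucket contents — already sorted by start position
within each bucket — are n-way merged with a min-priority heap. Entries
whose genomic extents overlap or abut within W bp collapse into one
candidate; the number of distinct tables contributing to a candidate is
its bucket-hit count b_hits.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass
from math import ceil

from .index import MHGIndex
from .kmers import kmer_profile
from .minhash import fingerprint
from .seqio import ReadRecord


@dataclass
class Candidate:
    """A merged genome interval [gstart, gend) with its bucket support."""

    gstart: int
    gend: int
    b_hits: int
    b_best_hits: int = 0

    @property
    def interval(self) -> tuple[int, int]:
        return (self.gstart, self.gend)


def read_fingerprint(read: ReadRecord, index: MHGIndex):
    """MinHash fingerprint of a read over its own (filtered) kmer set."""
    p = index.params
    canon, valid = kmer_profile(read.seq, p.k_mh, index.kfilter)
    codes = canon[valid]
    return fingerprint(
        codes, index.family, p.effective_min_kmers(len(read.seq))
    )


def select_candidates(read: ReadRecord, index: MHGIndex) -> list[Candidate]:
    """Merged, thresholded, b_hits-ranked candidate contigs for one read.

    Returns [] (read unmappable) when the read's fingerprint is invalid
    or no contig reaches the b_min_hits / b_best_hits thresholds.
    """
    p = index.params
    if len(read.seq) < p.k_mh:
        return []
    F = read_fingerprint(read, index)
    if not F.valid:
        return []
    buckets = index.lookup(F)
    if buckets is None:
        return []

    W = p.W
    # (start, length, table id) tuples, merged across tables by start
    def _stream(bucket, t):
        for s, ln in bucket:
            yield int(s), int(ln), t

    streams = [
        _stream(bucket, t)
        for t, bucket in enumerate(buckets)
        if bucket.shape[0]
    ]
    merged = heapq.merge(*streams)

    raw: list[Candidate] = []
    cur_start = cur_end = None
    cur_tables: set[int] = set()
    for start, length, t in merged:
        end = start + length - 1 + W  # union of the entry's merged windows
        if cur_end is not None and start <= cur_end + W:
            cur_end = max(cur_end, end)
            cur_tables.add(t)
        else:
            if cur_end is not None:
                raw.append(Candidate(cur_start, cur_end, len(cur_tables)))
            cur_start, cur_end = start, end
            cur_tables = {t}
    if cur_end is not None:
        raw.append(Candidate(cur_start, cur_end, len(cur_tables)))
    if not raw:
        return []

    b_best = max(c.b_hits for c in raw)
    threshold = max(p.b_min_hits, ceil(b_best / 2))
    out = [c for c in raw if c.b_hits >= threshold]
    for c in out:
        c.b_best_hits = b_best
        # candidate must be able to hold the whole read
        if c.gend - c.gstart < len(read.seq):
            c.gend = c.gstart + len(read.seq)
    out.sort(key=lambda c: (-c.b_hits, c.gstart))
    return out[: p.max_candidates]
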