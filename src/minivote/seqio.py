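"""FASTA/FASTQ input and the reference coordinate space.

All internal coordinates are 0-based, half-open, on the concatenation of
the reference sequences in file order; SAM output converts to 1-based.
"""

from __future__ import annotations

import gzip
from bisect import bisect_right
from dataclasses import dataclass
from typing import IO, Iterator

from Bio import SeqIO

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_ALLOWED = frozenset("ACGTN")


@dataclass
class ReferenceSequence:
    """One reference record placed in the global coordinate space."""

    name: str
    seq: str
    offset: int  # 0-based global coordinate of the first base

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class ReadRecord:
    id: str
    seq: str
    qual: str

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.qual):
            raise ValueError(
                f"read {self.id!r}: sequence length {len(self.seq)} != "
                f"quality length {len(self.qual)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _open_text(path: str) -> IO[str]:
    """Open plain or gzip-compressed text transparently."""
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path)


def _normalize(seq: str) -> str:
    """Uppercase and collapse IUPAC ambiguity codes to N."""
    s = seq.upper()
    if set(s) <= _ALLOWED:
        return s
    return "".join(c if c in _ALLOWED else "N" for c in s)


def load_reference(path: str) -> list[ReferenceSequence]:
    """Load a (possibly multi-record, line-wrapped, gzipped) FASTA.

    Sequences are uppercased, ambiguity codes map to N, and consecutive
    records receive non-overlapping global offsets covering the
    concatenated reference exactly.
    """
    refs: list[ReferenceSequence] = []
    offset = 0
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            seq = _normalize(str(rec.seq))
            if not seq:
                raise ValueError(f"empty sequence record {rec.id!r} in {path}")
            refs.append(ReferenceSequence(name=rec.id, seq=seq, offset=offset))
            offset += len(seq)
    if not refs:
        raise ValueError(f"no FASTA records found in {path}")
    return refs


def load_reads(path: str) -> Iterator[ReadRecord]:
    """Stream single-end reads from a (possibly gzipped) 4-line FASTQ."""
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            quals = rec.letter_annotations["phred_quality"]
            yield ReadRecord(
                id=rec.id,
                seq=_normalize(str(rec.seq)),
                qual="".join(chr(q + 33) for q in quals),
            )


class GenomeCoordinates:
    """Map between global coordinates and (reference name, local pos)."""

    def __init__(self, refs: list[ReferenceSequence]):
        self.refs = refs
        self.offsets = [r.offset for r in refs]
        self.total = refs[-1].offset + len(refs[-1]) if refs else 0

    def locate(self, gpos: int) -> tuple[ReferenceSequence, int]:
        """Return the record containing ``gpos`` and the local offset."""
        if not (0 <= gpos < self.total):
            raise ValueError(f"global position {gpos} outside reference")
        i = bisect_right(self.offsets, gpos) - 1
        ref = self.refs[i]
        return ref, gpos - ref.offset

    def clip_to_record(self, gstart: int, gend: int) -> list[tuple[int, int]]:
        """Split [gstart, gend) at record boundaries, clipped to the genome."""
        gstart = max(0, gstart)
        gend = min(self.total, gend)
        pieces = []
        for ref in self.refs:
            lo = max(gstart, ref.offset)
            hi = min(gend, ref.offset + len(ref))
            if lo < hi:
                pieces.append((lo, hi))
        return pieces
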