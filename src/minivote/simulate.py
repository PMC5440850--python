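"""wgsim-style synthetic genome and read-set generator.

A uniform random ACGT genome is copied with point mutations at a fixed
per-base rate (a configurable fraction of which are short indels with
geometrically distributed lengths); single-end reads are drawn
uniformly from both strands of the mutated copy and corrupted with
uniform per-base substitution sequencing errors. Ground truth records
the read's leftmost coordinate on the *original* genome, so alignment
accuracy can be scored against the reference actually indexed.

The defaults mirror common whole-genome-simulation practice: mutation
rate 0.001, indel fraction 0.15, 1 bp indels extended with probability
0.3, base error rate 0.01.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .seqio import ReadRecord, revcomp

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class TruthRecord:
    read_id: str
    pos: int  # leftmost 0-based position on the original genome
    strand: str  # "+" or "-"


@dataclass
class SimulatedData:
    genome: str
    reads: list[ReadRecord]
    truth: list[TruthRecord]


def random_genome(length: int, rng: np.random.Generator) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode()


def _mutate(
    genome: np.ndarray,
    mutation_rate: float,
    indel_frac: float,
    indel_ext: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Mutated base-code array plus the mutated->original coordinate map."""
    n = genome.size
    mut_pos = np.flatnonzero(rng.random(n) < mutation_rate)
    pieces: list[np.ndarray] = []
    maps: list[np.ndarray] = []
    prev = 0
    for p in mut_pos:
        if p < prev:
            continue  # swallowed by a previous deletion
        pieces.append(genome[prev:p])
        maps.append(np.arange(prev, p))
        if rng.random() >= indel_frac:
            # substitution to a uniformly different base
            base = (genome[p] + rng.integers(1, 4)) % 4
            pieces.append(np.array([base], dtype=genome.dtype))
            maps.append(np.array([p]))
            prev = p + 1
        else:
            length = int(rng.geometric(1.0 - indel_ext))
            if rng.random() < 0.5:  # insertion before p
                ins = rng.integers(0, 4, size=length).astype(genome.dtype)
                pieces.append(ins)
                maps.append(np.full(length, p))
                prev = p
            else:  # deletion of [p, p+length)
                prev = min(n, p + length)
    pieces.append(genome[prev:])
    maps.append(np.arange(prev, n))
    return np.concatenate(pieces), np.concatenate(maps)


def simulate_reads(
    genome_length: int,
    n_reads: int,
    read_length: int,
    error_rate: float = 0.01,
    mutation_rate: float = 0.001,
    indel_frac: float = 0.15,
    indel_ext: float = 0.3,
    seed: int = 7,
) -> SimulatedData:
    """Generate a genome, a mutated-copy read set and ground truth."""
    for name, rate in (
        ("error_rate", error_rate),
        ("mutation_rate", mutation_rate),
        ("indel_frac", indel_frac),
        ("indel_ext", indel_ext),
    ):
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"{name}={rate} outside [0, 1]")
    if read_length > genome_length:
        raise ValueError("read length exceeds genome length")
    rng = np.random.Generator(
        np.random.PCG64(np.random.SeedSequence([seed, 0x73696D]))
    )
    genome = rng.integers(0, 4, size=genome_length).astype(np.uint8)
    if mutation_rate > 0:
        mutated, orig_of = _mutate(genome, mutation_rate, indel_frac, indel_ext, rng)
    else:
        mutated, orig_of = genome, np.arange(genome_length)

    nm = mutated.size
    starts = rng.integers(0, nm - read_length + 1, size=n_reads)
    strands = rng.random(n_reads) < 0.5  # True = reverse
    qual_char = (
        "I" if error_rate == 0 else chr(33 + min(40, round(-10 * np.log10(error_rate))))
    )
    qual = qual_char * read_length

    reads: list[ReadRecord] = []
    truth: list[TruthRecord] = []
    for i in range(n_reads):
        s = int(starts[i])
        frag = mutated[s : s + read_length].copy()
        errs = np.flatnonzero(rng.random(read_length) < error_rate)
        if errs.size:
            frag[errs] = (frag[errs] + rng.integers(1, 4, size=errs.size)) % 4
        seq = _BASES[frag].tobytes().decode()
        strand = "-" if strands[i] else "+"
        if strand == "-":
            seq = revcomp(seq)
        rid = f"r{i:06d}"
        reads.append(ReadRecord(id=rid, seq=seq, qual=qual))
        truth.append(TruthRecord(read_id=rid, pos=int(orig_of[s]), strand=strand))
    return SimulatedData(
        genome=_BASES[genome].tobytes().decode(), reads=reads, truth=truth
    )


def write_fasta(genome: str, path: str, name: str = "sim1", width: int = 80) -> None:
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for i in range(0, len(genome), width):
            fh.write(genome[i : i + width] + "\n")


def write_fastq(reads: list[ReadRecord], path: str) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.seq}\n+\n{r.qual}\n")


def write_truth(truth: list[TruthRecord], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tpos\tstrand\n")
        for t in truth:
            fh.write(f"{t.read_id}\t{t.pos}\t{t.strand}\n")


def load_truth(path: str) -> list[TruthRecord]:
    truth = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("read_id"):
            raise ValueError(f"{path} is not a truth table")
        for line in fh:
            rid, pos, strand = line.rstrip("\n").split("\t")
            truth.append(TruthRecord(rid, int(pos), strand))
    return truth
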