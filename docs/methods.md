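# Methods

## Overview

minivote aligns single-end short reads in two phases. Phase 1 runs on
the trusted client: every reference window of length W (one per
genome position) is MinHash-fingerprinted and stored in an LSH index;
fingerprinting a read and merging its T bucket lists yields candidate
contigs ranked by how many tables support them. Phase 2 may run on an
untrusted machine: each read/candidate pair is reduced to two lists
of keyed-hashed kmers with bin-level position information, matches
between the lists vote for alignment displacements, and the best
convolved vote count becomes the alignment score. The client converts
the winning displacement back to a genome coordinate and derives a
mapping quality from the best and second-best scores.

The untrusted side is simulated in-process, but behind a hard
serialization boundary: voting consumes only the serialized task
bytes (hashes, bin ids, counts) — never sequences, coordinates or
keys — so the privacy constraints hold by construction, and the byte
counts of the two streams are the bandwidth report.

## MinHash fingerprinting

Sequences are represented as sets of overlapping k_mh-mers (default
20 bp), 2-bit packed and *canonical* (the smaller of a kmer's code
and its reverse complement's), so a fingerprint is strand-insensitive
and reverse-strand reads retrieve the same candidates as their
forward images. Kmers overlapping an N are dropped everywhere, and a
genome-wide filter drops "repetitive" canonical kmers occurring more
than C_max times (default 1000; the cutoff exists to keep
high-copy-number kmers from gluing unrelated windows together, and
the default is deliberately permissive for desk-scale genomes).

Each surviving code is scrambled by a fixed 64-bit mixer H
(splitmix64 finalizer) and pushed through L universal hash functions
h_i(x) = a_i·x + b_i over Z_2^64 with a_i odd; fingerprint entry i is
the minimum of h_i over the set. The fraction of equal entries
between two fingerprints is an unbiased estimator of Jaccard
similarity with standard error sqrt(J(1−J)/L); L = 128 keeps that
error under ~0.05 everywhere.

A fingerprint is *valid* when at least `min_kmers` kmers survive
filtering; the default is 80% of the nominal complement W − k_mh + 1.
Validity is a configurable judgement call: windows dominated by Ns or
repetitive kmers carry too little evidence to index or map.

Per-window fingerprints of a long sequence are produced by a rolling
computation: the affine-transformed hash values are laid out once per
hash function and each window minimum is taken with a two-pass block
(prefix/suffix) sliding minimum — O(n) per hash function and
bit-identical to recomputing every window from scratch, which the
test suite verifies directly. The incremental structure is free to
change as long as that contract holds.

## The reference index (MHG)

The index holds T = 78 tables of 2^M buckets (M = 18). For each
window, table t receives the multiply-shift hash
h = (Σ_i A[i]·F[P[t][i]] mod 2⁶⁴) >> (64 − M) of a fixed
b-dimensional projection P[t] of the fingerprint (b = 2, indices
drawn without replacement per table, A odd 64-bit). Two windows land
in the same bucket of table t exactly when they agree on those b
fingerprint entries, so a bucket collects windows sharing at least b
entries with any query that hashes there.

Runs of consecutive window positions falling in the same (table,
bucket) are stored as single (start, length) contig entries. The
compression is lossless — expanding all entries reproduces the
per-window assignment exactly — and entries within a bucket stay
sorted by start and maximally merged. Buckets that accumulate more
than `bucket_cap` entries (default 5000) are treated as
high-frequency junk and skipped at lookup time, mirroring the
repetitive-kmer suppression at a coarser scale.

For voting purposes a contig entry spans [start, start + len − 1 + W):
the union of its merged windows, the smallest interval guaranteed to
contain every one of them in full.

The index serializes to a versioned little-endian binary file with a
JSON parameter header; a round trip is bit-identical.

## Candidate selection

The read is fingerprinted over its own kmer set (reads of any length
≥ k_mh are accepted; `min_kmers` scales with read length). Its T
bucket lists — pre-sorted by start — are merged with a min-priority
heap, and entries whose genomic extents overlap or abut within W bp
collapse into one candidate; the number of *distinct tables*
contributing is the candidate's b_hits. Cross-table identity of
"the same contig" is not well defined once windows merge differently
per table, so interval merging is the natural completion, and W is
the natural slack (two entries farther apart cannot be explained by
one read).

Candidates need b_hits ≥ b_min_hits (default 2, i.e. at least two
independent projections agree) and b_hits ≥ ⌈b_best_hits/2⌉ — the
"within range of the best" rule, with the factor ½ chosen as a
configurable midpoint. Survivors are ranked by descending b_hits and
capped at `max_candidates` (default 30).

## Kmer voting

Voting kmers (v = 20 bp, stride 1) are deliberately *not* canonical:
each read spawns one task per candidate for its forward sequence and
one for its reverse complement, and the higher-scoring orientation
wins and sets the SAM strand flag. With canonical kmers the two
orientations would be indistinguishable and a read's own locus would
self-match along an anti-diagonal (φ = φ₀ + rlen − v − 2i),
inflating the second-best score at spurious loci and depressing
mapping quality even for perfect reads; strand-specific kmers make
the wrong orientation score like random noise.

A match between read kmer position p^R and contig position p^C votes
for φ = p^C − p^R. Votes are collected by V_conv[j] = Σ_{|i−j|≤n} V[i]
with n = 10, a plain window sum — wide enough to pool votes split by
small indels, narrow enough not to blur distinct loci. The maximum of
V_conv is the task score; a plateau of tied maxima resolves to its
middle position (lower median), and an all-zero vector means "no
evidence" (score 0).

r₁ is the best score over all of a read's tasks, r₂ the best among
tasks whose implied genome position lies more than W bp away from
r₁'s — the runner-up must be a genuinely alternative locus, not the
same peak seen through an overlapping chunk or the opposite-strand
task of the same candidate. mapq = round(α·(r₁−r₂)/r₁) clamped to
[0, α], α = 60 to match the conventional mapq ceiling; r₁ = 0 or
r₁ = r₂ gives mapq 0.

## The secure transform

Per task, kmer s is shipped as ((h_K(s) ⊕ k₁) · k₂) mod 2⁶⁴ where
h_K is the first 64 bits of HMAC-SHA1 under a 256-bit session secret
K, and (k₁, k₂) are fresh per-task 64-bit keys with k₂ odd (the map
x → (x⊕k₁)·k₂ is then a bijection of Z_2^64). Matches are detectable
within a task but values are incomparable across tasks, which removes
global repeat structure (GRS). Reference h_K values are precomputed
once per session — rekeying is two vectorized integer ops — which is
what makes the scheme fast.

Local repeat structure (LRS) is removed by masking: every kmer
occurring more than once within the read (resp. contig), and every
N-containing kmer, has its hash replaced by a random 64-bit value,
together with its neighbours so that each repeat sits inside a
maximal masked run of at least v kmers. The dilation radius is v−1 on
each side; runs clipped below v by a sequence boundary are extended
inward. Without the neighbourhood rule, a lone mismatch flanked by
matches on both sides would be recognizable as a masked repeat.

Positions are disclosed only as bins of β = 20 consecutive kmers,
shuffled within each bin. A matched pair with read bin [l^R, h^R) and
contig bin [l^C, h^C) votes once for every φ in
[l^C − h^R + 1, h^C − l^R) — precisely the displacements the hidden
positions could realize (the half-open upper bound is what direct
enumeration of p^C − p^R gives). β = 1 degenerates to exact-position
voting; vanilla mode uses β = 1, the plain mixer hash and no masking.
Binning caps position resolution: final positions are accurate to
about ±β/2, which is why accuracy is assessed with the standard
20 bp correctness tolerance and why secure and vanilla placements are
compared within ±β.

Contig kmers are sampled at rate ρ per bin: a full bin ships
max(1, ⌊β·ρ⌋) kmers; a partial tail bin of m < β positions ships
max(1, ⌊m·ρ⌋) (a flat ⌊β·ρ⌋ quota would force-mask every tail bin
even at ρ = 1). A bin that cannot supply its quota of unique unmasked
kmers — because repeats were masked inside it — is masked entirely
and ships random values instead, so payload sizes never betray where
masking happened. Read kmers are never sampled.

Candidate contigs longer than twice the read length are split into
chunks of exactly that cap, overlapping by one read length so every
alignment lies fully inside some chunk; each chunk is its own task
with its own keys, and payloads are padded with random kmers to the
uniform full-chunk length so the cloud cannot infer true contig
lengths. Padding and splitting are neutral for the final placement
(verified by test).

All per-task randomness (keys, masks, shuffles, padding) derives from
a per-read generator seeded by (master seed, read index), so an
alignment run is byte-reproducible.

## Read simulator

The generator emulates whole-genome resequencing the way wgsim does:
a uniform random ACGT genome; a mutated copy with point mutations at
rate 0.001 of which 15% are indels (length 1 + Geometric(0.7),
insertions and deletions equally likely); reads drawn uniformly from
both strands of the mutated copy; uniform substitution sequencing
errors at the configured rate (default 1%). Truth records the read's
leftmost coordinate mapped back to the *original* genome, which is
what gets indexed.

What it does **not** emulate: real base-composition bias, repeat
families and segmental duplications, coverage bias, quality-score
structure, or long indels. A uniform random 100 kb genome is almost
repeat-free at 20 bp kmer scale, so the accuracy figures the tests
certify (≥99% Q10, ≤1% Q10 error at 1% base error) demonstrate the
machinery works as designed — not that it matches production aligners
on a real human genome, where repetitive regions would lower mapq
through the r₂ term and stress the candidate thresholds.

## Validation problem sizes

The test suite and acceptance script run entirely on generated data:
rolling-vs-direct on 1,000 windows of a 2 kb sequence; estimator
calibration on 200 set pairs; the voting brute-force oracle on 500
read/contig pairs up to 1 kb; index losslessness and self-retrieval
on a 100 kb genome; end-to-end accuracy on 100 kb / 10,000 reads in
both modes; no-leak invariants over 10⁴ freshly keyed tasks. These
sizes make the whole suite run in a couple of minutes on one CPU
while keeping every estimate's sampling error well below the margins
being asserted.

## Numerical and degenerate-input choices

- All hashing is uint64 with wrap-around; Python-level scalars are
  masked to 64 bits explicitly.
- Windows with zero surviving kmers carry the sentinel minimum
  2⁶⁴ − 1 and are invalid; invalid read fingerprints make the read
  unmappable (reported with the SAM unmapped flag, never dropped).
- Tie-breaks are deterministic everywhere: heap merge by (start,
  table id); equal-score tasks by (score, position, strand); vote
  plateaus by lower median.
- Coordinates are 0-based half-open internally; SAM output is
  1-based, with reverse-strand reads stored as their reverse
  complement per convention. CIGARs are full-length matches — the
  method scores placements, it does not produce base-level
  alignments.
- Displacements that would push an alignment past a reference edge
  (possible for junk votes near contig boundaries) are clamped into
  the containing reference.

## Known limitations

Single-end reads only; base qualities are carried through but ignored
by scoring; no gapped CIGAR or local realignment; phase 1 always runs
on the client; the privacy properties are enforced and *observably*
tested (no within-task repeats, no cross-task collisions beyond the
birthday bound, uniform payload sizes) but not formally proven; and
index construction is single-threaded.
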