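# minivote

A privacy-preserving two-phase short-read aligner for hybrid clouds,
built around MinHash locality-sensitive hashing and secure kmer voting.

Read alignment is usually the first and most expensive step of a
genomics pipeline, and institutions would like to push it onto cheap
public clouds — but raw reads identify the person they came from, so
shipping them to an untrusted machine is not acceptable. minivote
splits the work so that the sensitive part stays on the trusted
client and the heavy part runs on an untrusted side that only ever
sees keyed hashes:

1. **Candidate selection (client).** Reference genome windows are
   fingerprinted with MinHash and stored in an LSH index (the MHG);
   fingerprinting a read and merging its index buckets yields a
   handful of candidate contigs per read.
2. **Kmer voting (untrusted side).** Each read/contig pair becomes a
   *voting task*: every kmer shared by read and contig votes for the
   displacement φ = p^C − p^R; votes are convolved to absorb indels
   and the best displacement wins. Before leaving the client, each
   task is keyed-hashed with per-task keys, local repeats are masked,
   and kmer positions are coarsened to shuffled bins, so the voting
   side can count matches without learning sequence content.

## The model in brief

A sequence is the set of its overlapping kmers. For sets *A*, *B* the
Jaccard coefficient *J(A,B) = |A∩B| / |A∪B|* is estimated by MinHash:
with *L* universal hash functions *h&#8336;(x) = a&#8336;x + b&#8336;* (mod 2⁶⁴,
a&#8336; odd), the fingerprint entry *f&#8336;* is the minimum of *h&#8336;* over the
set, and P(*f&#8336;ᴬ = f&#8336;ᴮ*) = *J(A,B)*. The MHG stores each genome window
in *T* tables under *b*-dimensional fingerprint projections hashed by
multiply-shift into 2^M buckets; runs of consecutive windows in the
same bucket compress to single (start, length) contig entries. At
query time a contig supported by `b_hits` distinct tables survives if
`b_hits ≥ max(b_min_hits, ⌈b_best_hits/2⌉)`.

Voting scores are convolved window sums of radius *n*; the mapping
quality is `mapq = α·(r₁−r₂)/r₁` with `r₁`/`r₂` the best and
second-best task scores at genuinely different loci (> W bp apart).
The secure transform hashes kmer *s* as `((h_K(s) ⊕ k₁) · k₂) mod 2⁶⁴`
(`h_K` = first 64 bits of HMAC-SHA1 under a 256-bit session secret,
`(k₁,k₂)` fresh per task, `k₂` odd), masks every repeated kmer inside
a run of ≥ *v* masked neighbours, reveals positions only as shuffled
bins of β kmers (a match then votes for the displacement range
`[l^C−h^R+1, h^C−l^R)`), and samples contig kmers at rate ρ per bin.

## Worked example

Everything below is generated on the fly — no downloads. Simulate a
100 kb genome with 10,000 150 bp reads at 1% base error, index it,
align in secure mode, and score against ground truth:

```
$ minivote simulate --genome-length 100000 --n-reads 10000 \
    --read-length 150 --error-rate 0.01 --seed 7 --out-prefix sim
wrote sim.fa (100000 bp), sim.fq (10000 reads), sim.truth.tsv

$ minivote index --ref sim.fa --out sim.mhg --seed 7
indexed 99851 windows into 78 tables -> sim.mhg

$ minivote align --reads sim.fq --index sim.mhg --ref sim.fa \
    --out sim.sam --mode secure
{"n_reads": 10000, "n_mapped": 9995, "n_tasks": 38878,
 "bandwidth": {"tasks_bytes": 192898896, "results_bytes": 777560}, ...}

$ minivote evaluate --sam sim.sam --truth sim.truth.tsv
{
  "pct_q10": 99.95,
  "err_q10": 0.0,
  "n_reads": 10000,
  "n_q10": 9995,
  "n_wrong": 0
}
```

`pct_q10` is the percentage of reads mapped with mapping quality ≥ 10;
`err_q10` the percentage of those placed more than 20 bp from their
true position. The align step also reports the exact client→cloud
traffic: ~193 MB of serialized voting tasks for these 10,000 reads
(about 38,900 tasks), and 0.8 MB of results coming back — the voting
side received nothing but per-task keyed hashes and bin indices.

The same objects are available as a library (`minivote.build_index`,
`minivote.align`, `minivote.simulate_reads`, ...); the CLI is a thin
wrapper.

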