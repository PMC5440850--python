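"""Kmer voting: keyed hashing, masking, binning, vote casting, scoring."""

import collections

import numpy as np
import pytest

from minivote.params import Params
from minivote.seqio import revcomp
from minivote.voting import (
    TaskKeys,
    TaskResult,
    VoteVector,
    VotingTask,
    build_task,
    cast_votes,
    compute_mapq,
    contig_chunks,
    convolve_votes,
    deserialize_result,
    deserialize_task,
    finalize_alignment,
    keyed_base_hash,
    keyed_kmer_hash,
    mask_repeats,
    prepare_voting_tasks,
    process_task_bytes,
    score_task,
    serialize_task,
    voting_kmers,
)

from conftest import random_dna

KEY = bytes(range(32))


def make_keys(k1=0x1234, k2=0x9D7F3B5CE2A1F0B1):
    return TaskKeys(K=KEY, k1=k1, k2=k2 | 1)


def vanilla_params(**kw):
    kw.setdefault("mode", "vanilla")
    kw.setdefault("W", 100)
    kw.setdefault("k_mh", 10)
    kw.setdefault("v", 10)
    return Params(**kw)


def secure_params(**kw):
    kw.setdefault("mode", "secure")
    kw.setdefault("W", 100)
    kw.setdefault("k_mh", 10)
    kw.setdefault("v", 10)
    return Params(**kw)


def brute_force_alignment(read, contig, v, n_conv):
    """Independent voting oracle: dictionary match counting, explicit
    window sums, explicit lower-median tie rule."""
    cpos = collections.defaultdict(list)
    for j in range(len(contig) - v + 1):
        cpos[contig[j : j + v]].append(j)
    votes = collections.Counter()
    for i in range(len(read) - v + 1):
        for j in cpos.get(read[i : i + v], ()):
            votes[j - i] += 1
    if not votes:
        return 0, 0
    lo, hi = min(votes) - n_conv, max(votes) + n_conv
    conv = {
        d: sum(votes.get(t, 0) for t in range(d - n_conv, d + n_conv + 1))
        for d in range(lo, hi + 1)
    }
    best = max(conv.values())
    ties = sorted(d for d, s in conv.items() if s == best)
    return ties[(len(ties) - 1) // 2], best


def run_vanilla(read, contig, params, rng):
    codes_r, valid_r = voting_kmers(read, params.v)
    codes_c, valid_c = voting_kmers(contig, params.v)
    task = build_task(
        0, codes_r, valid_r, codes_c, valid_c, params, make_keys(), rng, 0, "+"
    )
    votes = convolve_votes(cast_votes(task), params.n_conv)
    return score_task(votes)


class TestKeyedHash:
    def test_deterministic(self):
        keys = make_keys()
        assert keyed_kmer_hash(42, keys) == keyed_kmer_hash(42, keys)

    def test_rekeying_changes_values(self):
        a = keyed_kmer_hash(42, make_keys(k1=1, k2=3))
        b = keyed_kmer_hash(42, make_keys(k1=2, k2=5))
        assert a != b

    def test_even_k2_rejected(self):
        with pytest.raises(ValueError):
            TaskKeys(K=KEY, k1=0, k2=2)

    def test_rekeying_is_bijective(self, rng):
        """x -> (x ^ k1) * k2 mod 2^64 collides never for odd k2."""
        keys = make_keys()
        xs = np.unique(rng.integers(0, 2**63, size=100_000, dtype=np.uint64))
        out = {((int(x) ^ keys.k1) * keys.k2) & ((1 << 64) - 1) for x in xs}
        assert len(out) == xs.size


class TestMasking:
    def test_repeat_free_unmasked(self, rng):
        seq = "ACGTTGCAACGGATCTAGCT"  # all 4-mers distinct? ensured below
        codes, valid = voting_kmers(random_dna(rng, 50), 10)
        masked = mask_repeats(codes, valid, 10)
        if len(np.unique(codes)) == codes.size:
            assert not masked.any()

    def test_homopolymer_fully_masked(self):
        codes, valid = voting_kmers("A" * 40, 20)
        assert mask_repeats(codes, valid, 20).all()

    def test_repeat_neighbourhood_runs_at_least_v(self, rng):
        v = 20
        core = random_dna(rng, 120)
        # plant the same 20-mer at kmer positions 5 and 50
        kmer = random_dna(rng, v)
        seq = core[:5] + kmer + core[5 + v : 50] + kmer + core[50 + v :]
        codes, valid = voting_kmers(seq, v)
        masked = mask_repeats(codes, valid, v)
        assert masked[5] and masked[50]
        # every maximal masked run has length >= v
        idx = np.flatnonzero(masked)
        runs = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
        assert all(len(r) >= v for r in runs)


class TestPrepareTask:
    def test_vanilla_reveals_exact_positions(self, rng):
        p = vanilla_params()
        contig = random_dna(rng, 200)
        tasks = prepare_voting_tasks(
            contig[40:140], contig, 0, "+", p, KEY, rng
        )
        assert len(tasks) == 1
        t = tasks[0]
        assert t.beta == 1
        assert np.array_equal(t.read_bins, np.arange(91))
        assert not t.read_payload_masked.any()

    def test_repeat_free_beta1_rho1_unmasked(self, rng):
        p = secure_params(beta=1, rho=1.0)
        contig = random_dna(rng, 200)
        tasks = prepare_voting_tasks(contig[40:140], contig, 0, "+", p, KEY, rng)
        t = tasks[0]
        assert not t.read_pos_masked.any()
        assert not t.contig_pos_masked.any()

    def test_all_repeat_read_fully_masked(self, rng):
        p = secure_params(v=20, W=150)
        contig = random_dna(rng, 300)
        tasks = prepare_voting_tasks("A" * 40, contig, 0, "+", p, KEY, rng)
        assert tasks[0].read_pos_masked.all()
        assert tasks[0].read_payload_masked.all()

    def test_lrs_invariant_unmasked_values_unique(self, rng):
        p = secure_params(v=10, beta=5, rho=1.0)
        for _ in range(10):
            contig = random_dna(rng, 250)
            read = contig[30:130]
            t = prepare_voting_tasks(read, contig, 0, "+", p, KEY, rng)[0]
            for hv, m in (
                (t.read_hvals, t.read_payload_masked),
                (t.contig_hvals, t.contig_payload_masked),
            ):
                clear = hv[~m]
                assert np.unique(clear).size == clear.size

    def test_bins_hide_in_bin_order(self, rng):
        p = secure_params(beta=20)
        contig = random_dna(rng, 250)
        t = prepare_voting_tasks(contig[30:130], contig, 0, "+", p, KEY, rng)[0]
        assert np.all(np.diff(t.read_bins) >= 0)  # grouped by bin
        assert t.read_bins.max() == (91 - 1) // 20

    def test_sampling_rate_halves_payload(self, rng):
        contig = random_dna(rng, 300)
        read = contig[50:150]
        sizes = {}
        for rho in (0.5, 1.0):
            p = secure_params(beta=20, rho=rho, v=20, W=150, k_mh=20)
            t = prepare_voting_tasks(read, contig, 0, "+", p, KEY, rng)[0]
            sizes[rho] = t.contig_hvals.size
        assert 1.8 <= sizes[1.0] / sizes[0.5] <= 2.2

    def test_underfilled_bin_masked_entirely(self, rng):
        # a bin containing a repeat cannot supply its full quota at rho=1
        v = 10
        p = secure_params(beta=10, rho=1.0, v=v)
        kmer = random_dna(rng, v)
        contig = kmer + random_dna(rng, 40) + kmer + random_dna(rng, 150)
        read = random_dna(rng, 100)
        t = prepare_voting_tasks(read, contig, 0, "+", p, KEY, rng)[0]
        # repeats occupy early bins: those bins are all-masked in payload
        for b in range(3):
            sel = t.contig_bins == b
            m = t.contig_payload_masked[sel]
            assert m.all() or not m.any()

    def test_read_shorter_than_v_errors(self, rng):
        p = secure_params(v=20, W=150)
        with pytest.raises(ValueError):
            prepare_voting_tasks("ACGT", random_dna(rng, 200), 0, "+", p, KEY, rng)


class TestCastVotes:
    def _manual_task(self, r_h, r_b, c_h, c_b, beta):
        return VotingTask(
            task_id=0,
            beta=beta,
            n_conv=0,
            read_hvals=np.array(r_h, dtype=np.uint64),
            read_bins=np.array(r_b, dtype=np.int64),
            contig_hvals=np.array(c_h, dtype=np.uint64),
            contig_bins=np.array(c_b, dtype=np.int64),
            pad=0,
        )

    def test_perfect_match_single_peak(self, rng):
        p = vanilla_params()
        contig = random_dna(rng, 100)
        codes, valid = voting_kmers(contig, p.v)
        task = build_task(
            0, codes, valid, codes, valid, p, make_keys(), rng, 0, "+"
        )
        votes = cast_votes(task)
        n = codes.size
        assert votes.V.max() == n
        assert votes.V[np.argmax(votes.V)] == n
        assert (votes.V > 0).sum() == 1
        assert votes.phi_min + int(np.argmax(votes.V)) == 0

    def test_binned_match_votes_exact_interval(self):
        # read bin [0,20), contig bin [40,60): phi in [21, 60)
        v = self._manual_task([7], [0], [7], [2], beta=20)
        votes = cast_votes(v)
        hit = np.flatnonzero(votes.V > 0) + votes.phi_min
        assert hit.min() == 21 and hit.max() == 59
        assert np.all(votes.V[votes.V > 0] == 1)

    def test_no_shared_kmers_zero_votes(self):
        v = self._manual_task([1, 2], [0, 1], [3, 4], [0, 1], beta=1)
        assert not cast_votes(v).V.any()


class TestConvolution:
    def test_zero_radius_identity(self):
        vv = VoteVector(V=np.array([0, 3, 1, 0]), phi_min=-1)
        out = convolve_votes(vv, 0)
        assert np.array_equal(out.Vconv, vv.V)
        assert out.conv_phi_min == -1

    def test_impulse_response(self):
        V = np.zeros(41, dtype=np.int64)
        V[20] = 1
        out = convolve_votes(VoteVector(V=V, phi_min=0), 10)
        hit = np.flatnonzero(out.Vconv == 1) + out.conv_phi_min
        assert hit.tolist() == list(range(10, 31))

    def test_two_votes_window_sum_oracle(self):
        V = np.zeros(30, dtype=np.int64)
        V[10] = 1
        V[15] = 1
        out = convolve_votes(VoteVector(V=V, phi_min=0), 10)
        for j in range(out.Vconv.size):
            d = out.conv_phi_min + j
            expect = sum(
                V[t] for t in range(d - 10, d + 11) if 0 <= t < 30
            )
            assert out.Vconv[j] == expect
        assert out.Vconv.max() == 2


class TestScoring:
    def _score(self, arr, phi_min=0):
        return score_task(VoteVector(V=None, phi_min=0, Vconv=np.array(arr), conv_phi_min=phi_min))

    def test_single_peak(self):
        disp, score = self._score([0, 1, 5, 1], phi_min=-2)
        assert (disp, score) == (0, 5)

    def test_plateau_takes_middle(self):
        vconv = np.zeros(20, dtype=np.int64)
        vconv[10:15] = 7  # plateau on displacements [10, 14]
        disp, score = self._score(vconv)
        assert (disp, score) == (12, 7)

    def test_matches_brute_force_argmax(self, rng):
        for _ in range(50):
            vconv = rng.integers(0, 10, size=60)
            disp, score = self._score(vconv)
            best = vconv.max()
            ties = [i for i, x in enumerate(vconv) if x == best]
            assert score == best
            assert disp == ties[(len(ties) - 1) // 2]

    def test_all_zero_no_evidence(self):
        disp, score = self._score([0, 0, 0])
        assert score == 0


class TestVanillaOracle:
    def test_matches_brute_force_on_random_pairs(self, rng):
        p = vanilla_params(v=12, n_conv=10)
        for _ in range(30):
            contig = random_dna(rng, int(rng.integers(150, 600)))
            if rng.random() < 0.7:
                start = int(rng.integers(0, len(contig) - 100))
                read = list(contig[start : start + 100])
                for e in rng.integers(0, 100, size=2):
                    read[e] = "ACGT"[(("ACGT".index(read[e])) + 1) % 4]
                read = "".join(read)
            else:
                read = random_dna(rng, 100)
            disp, score = run_vanilla(read, contig, p, rng)
            o_disp, o_score = brute_force_alignment(read, contig, p.v, p.n_conv)
            assert score == o_score
            if o_score > 0:
                assert disp == o_disp


class TestSecureVanillaConcordance:
    def test_beta1_identical(self, rng):
        contig = random_dna(rng, 300)
        read = contig[100:200]
        pv = vanilla_params()
        ps = secure_params(beta=1, rho=1.0)
        dv, sv = run_vanilla(read, contig, pv, rng)
        ts = prepare_voting_tasks(read, contig, 0, "+", ps, KEY, rng)[0]
        ds, ss = score_task(convolve_votes(cast_votes(ts), ps.n_conv))
        assert (dv, sv) == (ds, ss)

    def test_beta20_within_beta(self, rng):
        for _ in range(10):
            contig = random_dna(rng, 300)
            read = contig[100:200]
            pv = vanilla_params(v=20, W=150, k_mh=20)
            ps = secure_params(beta=20, rho=1.0, v=20, W=150, k_mh=20)
            dv, _ = run_vanilla(read, contig, pv, rng)
            ts = prepare_voting_tasks(read, contig, 0, "+", ps, KEY, rng)[0]
            ds, ss = score_task(convolve_votes(cast_votes(ts), ps.n_conv))
            assert ss > 0
            assert abs(ds - dv) <= 20


class TestChunkingAndPadding:
    def test_chunks_cover_and_overlap(self):
        for clen in (200, 500, 1000, 1234):
            chunks = contig_chunks(clen, 100)
            assert chunks[0][0] == 0 and chunks[-1][1] == clen
            for (s1, e1), (s2, e2) in zip(chunks, chunks[1:]):
                assert e1 - s2 >= 100  # overlap holds a whole read
                assert e1 - s1 == 200

    def test_uniform_payload_lengths(self, rng):
        p = secure_params(beta=10, rho=1.0, v=10)
        contig = random_dna(rng, 900)
        tasks = prepare_voting_tasks(contig[200:300], contig, 0, "+", p, KEY, rng)
        sizes = {t.contig_hvals.size for t in tasks}
        assert len(sizes) == 1

    def test_splitting_neutral_for_final_position(self, rng):
        """Chunked+padded alignment equals whole-contig alignment."""
        p = secure_params(beta=10, rho=1.0, v=10)
        contig = random_dna(rng, 800)
        read = contig[350:450]
        # whole contig in a single task (vanilla=exact reference point)
        pv = vanilla_params(v=10)
        dv, sv = run_vanilla(read, contig, pv, rng)
        tasks = prepare_voting_tasks(read, contig, 0, "+", p, KEY, rng)
        assert len(tasks) > 1
        results = []
        for t in tasks:
            d, s = score_task(convolve_votes(cast_votes(t), p.n_conv))
            if s > 0:
                results.append(TaskResult(gpos=t.chunk_gstart + d, strand="+", score=s))
        res = finalize_alignment("r", results, alpha=60, W=100)
        assert abs(res.gpos - dv) <= p.beta
        assert res.mapq == 60


class TestSerialization:
    def test_round_trip(self, rng):
        p = secure_params(beta=5)
        contig = random_dna(rng, 250)
        t = prepare_voting_tasks(contig[30:130], contig, 0, "+", p, KEY, rng)[0]
        buf = serialize_task(t)
        t2 = deserialize_task(buf)
        assert t2.task_id == t.task_id and t2.beta == t.beta
        assert np.array_equal(t2.read_hvals, t.read_hvals)
        assert np.array_equal(t2.contig_bins, t.contig_bins)
        # payload length identity: header + fixed-size kmer records
        expect = 24 + 12 * (t.read_hvals.size + t.contig_hvals.size)
        assert len(buf) == expect

    def test_cloud_round_trip_scores(self, rng):
        p = vanilla_params()
        contig = random_dna(rng, 200)
        t = prepare_voting_tasks(contig[50:150], contig, 0, "+", p, KEY, rng)[0]
        task_id, disp, score = deserialize_result(
            process_task_bytes(serialize_task(t))
        )
        assert task_id == t.task_id
        assert disp == 50
        assert score == 91  # all 91 10-mers vote for phi=50


class TestFinalize:
    def test_single_candidate_max_mapq(self):
        res = finalize_alignment(
            "r", [TaskResult(1000, "+", 50)], alpha=60, W=150
        )
        assert res.mapq == 60 and res.r2 == 0

    def test_ambiguous_zero_mapq(self):
        res = finalize_alignment(
            "r",
            [TaskResult(1000, "+", 50), TaskResult(5000, "+", 50)],
            alpha=60,
            W=150,
        )
        assert res.mapq == 0

    def test_mapq_formula(self):
        assert compute_mapq(50, 25, 60) == 30
        assert compute_mapq(0, 0, 60) == 0
        assert compute_mapq(131, 0, 60) == 60

    def test_nearby_runner_up_ignored(self):
        res = finalize_alignment(
            "r",
            [TaskResult(1000, "+", 50), TaskResult(1050, "-", 48)],
            alpha=60,
            W=150,
        )
        assert res.mapq == 60  # same locus, not a genuine alternative

    def test_no_evidence_unmapped(self):
        res = finalize_alignment("r", [TaskResult(0, "+", 0)], alpha=60, W=150)
        assert not res.mapped
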