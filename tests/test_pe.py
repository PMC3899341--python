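"""Paired-end pipeline: weighted seed pairing, insert estimation,
alignment-pair constraints and mate rescuing."""

import heapq
from dataclasses import replace

import numpy as np
import pytest

from hybridaln import (
    AlignerConfig,
    align_pair,
    align_single,
    estimate_insert_size,
    pair_seeds,
    pair_weight,
    rescue_mate,
    revcomp,
    simulate_pe_reads,
)
from hybridaln.index import Seed
from hybridaln.pe import InsertEstimateError, _pair_ok, _seeds_compatible, pop_pair
from hybridaln.se import score_and_rank_seeds

CFG = AlignerConfig()
INSERT = (300.0, 20.0)


def _random_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def _mutate(seq, rate, rng):
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = "ACGT"[("ACGT".index(out[i]) + 1 + int(rng.integers(3))) % 4]
    return "".join(out)


class TestPairWeight:
    def test_perfect_pair_has_weight_one(self):
        assert pair_weight(100, 100, 1, 100, 100) == 1.0

    def test_arithmetic(self):
        assert pair_weight(60, 40, 1, 100, 100) == 0.5

    def test_scale_invariance(self):
        w1 = pair_weight(60, 40, 1, 100, 100)
        w5 = pair_weight(300, 200, 5, 100, 100)
        assert w1 == w5

    def test_monotone_in_each_score(self):
        base = pair_weight(50, 50, 1, 100, 100)
        assert pair_weight(51, 50, 1, 100, 100) > base
        assert pair_weight(50, 51, 1, 100, 100) > base


def _seed(pos, strand, score, offset=0, length=20):
    s = Seed(offset, pos, length, strand, score_q=float(score))
    return s


class TestPairSeeds:
    def test_unique_perfect_pair(self):
        s1 = [_seed(1000, "+", 100)]
        s2 = [_seed(1400, "-", 100)]
        heap = pair_seeds(s1, s2, 100, 100, (500, 50), CFG)
        assert len(heap) == 1
        assert pop_pair(heap).weight_w == 1.0

    def test_insert_outside_window_excluded(self):
        s1 = [_seed(1000, "+", 100)]
        s2 = [_seed(1800, "-", 100)]  # implied insert 900
        cfg = replace(CFG, insert_nsd=2.0)  # window 500 +/- 100
        assert pair_seeds(s1, s2, 100, 100, (500, 50), cfg) == []

    def test_orientation_must_be_fr(self):
        s1 = [_seed(1000, "+", 100)]
        s2 = [_seed(1400, "+", 100)]
        assert pair_seeds(s1, s2, 100, 100, (500, 50), CFG) == []

    def test_low_scoring_seeds_filtered(self):
        s1 = [_seed(1000, "+", 29)]  # below the default floor of 30
        s2 = [_seed(1400, "-", 100)]
        assert pair_seeds(s1, s2, 100, 100, (500, 50), CFG) == []

    def test_heap_equals_brute_force_enumeration(self, rng):
        """5x5 random candidates: heap contents equal an exhaustive
        enumerate-and-filter oracle, and pops are non-increasing in w."""
        for _ in range(60):
            ends = []
            for _e in range(2):
                ends.append([
                    _seed(
                        int(rng.integers(0, 2000)),
                        "+-"[int(rng.integers(2))],
                        int(rng.integers(0, 101)),
                    )
                    for _ in range(5)
                ])
            heap = pair_seeds(ends[0], ends[1], 100, 100, (500, 200), CFG)
            brute = {
                (id(a), id(b))
                for a in ends[0]
                for b in ends[1]
                if a.score_q >= 30 and b.score_q >= 30
                and _seeds_compatible(a, b, 100, 100, (500, 200), 4.0, "fr")
            }
            got = []
            while heap:
                got.append(pop_pair(heap))
            assert {(id(p.seed1), id(p.seed2)) for p in got} == brute
            ws = [p.weight_w for p in got]
            assert ws == sorted(ws, reverse=True)


class TestInsertEstimation:
    def test_recovers_simulated_distribution(self, small_index, small_genome):
        pairs, _ = simulate_pe_reads(
            small_genome, 450, err_rate=0.0, insert_mean=300, insert_sd=20, seed=21
        )
        mean, sd = estimate_insert_size(
            small_index, [(a.sequence, b.sequence) for a, b in pairs]
        )
        assert 295 <= mean <= 305
        assert 16 <= sd <= 24

    def test_constant_insert_gives_zero_sd(self, small_index, small_seq):
        pairs = []
        for p in range(1000, 13000, 100):  # 120 exact pairs, insert 300
            pairs.append(
                (small_seq[p : p + 80], revcomp(small_seq[p + 220 : p + 300]))
            )
        mean, sd = estimate_insert_size(small_index, pairs)
        assert mean == 300.0 and sd == 0.0

    def test_unalignable_sample_raises(self, small_index, rng):
        pairs = [
            (_random_seq(rng, 80), _random_seq(rng, 80)) for _ in range(120)
        ]
        with pytest.raises(InsertEstimateError):
            estimate_insert_size(small_index, pairs)


class TestAlignPair:
    def test_error_free_pair_at_truth(self, small_index, small_genome):
        pairs, _ = simulate_pe_reads(
            small_genome, 10, err_rate=0.0, insert_mean=300, insert_sd=20, seed=3
        )
        for r1, r2 in pairs:
            ps, fb = align_pair(
                small_index, r1.sequence, r2.sequence, CFG, INSERT, r1.pair_id
            )
            assert len(ps) == 1 and fb == ([], [])
            assert abs(ps[0].aln1.ref_pos - r1.true_pos) <= 10
            assert abs(ps[0].aln2.ref_pos - r2.true_pos) <= 10

    def test_reported_pairs_satisfy_constraints(self, small_index, small_genome):
        pairs, _ = simulate_pe_reads(
            small_genome, 30, err_rate=0.04, insert_mean=300, insert_sd=20, seed=13
        )
        for r1, r2 in pairs:
            ps, _ = align_pair(
                small_index, r1.sequence, r2.sequence, CFG, INSERT
            )
            for p in ps:
                assert _pair_ok(p.aln1, p.aln2, INSERT, CFG, small_index)
                lo = INSERT[0] - CFG.insert_nsd * INSERT[1]
                hi = INSERT[0] + CFG.insert_nsd * INSERT[1]
                assert lo <= p.insert <= hi

    def test_noisy_mate_recovered_through_the_pair(self, small_index, small_genome, rng):
        """End-2 reads at 16% error are often unalignable alone; pairing
        with a clean end-1 recovers them."""
        pairs, _ = simulate_pe_reads(
            small_genome, 80, err_rate=0.0, insert_mean=300, insert_sd=20, seed=31
        )
        noisy = [
            (r1.sequence, _mutate(r2.sequence, 0.16, rng), r2.true_pos)
            for r1, r2 in pairs
        ]
        se_hits = sum(
            bool(align_single(small_index, s2)) for _, s2, _ in noisy
        )
        paired = 0
        for s1, s2, t2 in noisy:
            ps, _ = align_pair(small_index, s1, s2, CFG, INSERT)
            if ps and abs(ps[0].aln2.ref_pos - t2) <= 10:
                paired += 1
        assert paired > se_hits

    def test_junk_pair_reports_nothing(self, small_index, rng):
        ps, (f1, f2) = align_pair(
            small_index, _random_seq(rng, 100), _random_seq(rng, 100), CFG, INSERT
        )
        assert ps == [] and f1 == [] and f2 == []

    def test_one_alignable_end_falls_back_to_se(self, small_index, small_seq, rng):
        cfg = replace(CFG, enable_mate_rescue=False)
        ps, (f1, f2) = align_pair(
            small_index, small_seq[900:1000], _random_seq(rng, 100), cfg, INSERT
        )
        assert ps == []
        assert f1 and f1[0].ref_pos == 900
        assert f2 == []

    def test_pe_sensitivity_at_least_se(self, small_index, small_genome):
        pairs, _ = simulate_pe_reads(
            small_genome, 60, err_rate=0.06, insert_mean=300, insert_sd=20, seed=41
        )
        se_aligned = pe_aligned = 0
        for r1, r2 in pairs:
            se_aligned += bool(align_single(small_index, r1.sequence))
            se_aligned += bool(align_single(small_index, r2.sequence))
            ps, (f1, f2) = align_pair(
                small_index, r1.sequence, r2.sequence, CFG, INSERT
            )
            pe_aligned += 2 * bool(ps) or (bool(f1) + bool(f2))
        assert pe_aligned >= se_aligned


class TestMateRescue:
    def _anchor(self, small_index, small_seq, pos=5000):
        alns = align_single(small_index, small_seq[pos : pos + 100])
        assert alns and alns[0].mapq >= 20
        return alns[0]

    def test_rescues_mate_at_true_position(self, small_index, small_seq):
        anchor = self._anchor(small_index, small_seq)
        mate = revcomp(small_seq[5200:5300])  # insert 300, FR
        a = rescue_mate(small_index, anchor, mate, INSERT, CFG)
        assert a is not None and a.strand == "-"
        assert abs(a.ref_pos - 5200) <= 10

    def test_low_mapq_anchor_is_ignored(self, small_index, small_seq):
        anchor = self._anchor(small_index, small_seq)
        anchor.mapq = 10
        mate = revcomp(small_seq[5200:5300])
        assert rescue_mate(small_index, anchor, mate, INSERT, CFG) is None

    def test_junk_mate_fails_qualification(self, small_index, small_seq, rng):
        anchor = self._anchor(small_index, small_seq)
        assert rescue_mate(
            small_index, anchor, _random_seq(rng, 100), INSERT, CFG
        ) is None

    def test_disabling_rescue_strictly_reduces_pairing(
        self, small_index, small_genome, rng
    ):
        """Second ends at 20% error rarely keep a seed above the pairing
        score floor; only mate rescuing pairs them."""
        pairs, _ = simulate_pe_reads(
            small_genome, 50, err_rate=0.0, insert_mean=300, insert_sd=20, seed=77
        )
        noisy = [
            (r1.sequence, _mutate(r2.sequence, 0.20, rng)) for r1, r2 in pairs
        ]
        off = replace(CFG, enable_mate_rescue=False)

        def paired(cfg):
            return sum(
                bool(align_pair(small_index, s1, s2, cfg, INSERT)[0])
                for s1, s2 in noisy
            )

        assert paired(CFG) > paired(off)
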