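"""FM-index construction, backward search and seed extraction."""

import numpy as np
import pytest

from hybridaln import ReferenceIndex, build_index, revcomp
from hybridaln.index import InputError, decode_seq
from hybridaln.io_formats import SeqRecord

from oracles import brute_mems, count_occurrences


def _idx(seq, rate=1, name="c1"):
    return ReferenceIndex.from_records([SeqRecord(name, seq)], sa_sample_rate=rate)


def _random_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def _brute_bwt(s):
    """BWT by sorting all rotations of s+'$' ('$' smallest)."""
    t = s + "$"
    rots = sorted(
        t[i:] + t[:i] for i in range(len(t))
    )
    return "".join(r[-1] for r in rots)


class TestBWT:
    def test_example_genome_acgt(self):
        idx = _idx("ACGT")
        assert decode_seq(idx.bwt) == _brute_bwt("ACGT")

    def test_bwt_matches_rotation_sort_on_random_genomes(self, rng):
        for _ in range(25):
            s = _random_seq(rng, int(rng.integers(2, 60)))
            assert decode_seq(_idx(s).bwt) == _brute_bwt(s)

    def test_homopolymer_locate_full_interval(self):
        idx = _idx("AAAA")
        lo, hi = idx.backward_search("A")
        assert sorted(idx.locate(lo, hi).tolist()) == [0, 1, 2, 3]

    @pytest.mark.parametrize("rate", [1, 3, 8])
    def test_locate_exact_for_every_row(self, rng, rate):
        s = _random_seq(rng, 300)
        idx = _idx(s, rate=rate)
        # locate() on the full interval of each short pattern recovers the
        # exact naive position set
        for _ in range(40):
            i = int(rng.integers(0, 295))
            pat = s[i : i + 5]
            lo, hi = idx.backward_search(pat)
            got = sorted(idx.locate(lo, hi).tolist())
            want = [
                j for j in range(len(s) - 4) if s[j : j + 5] == pat
            ]
            assert got == want


class TestBackwardSearch:
    def test_interval_size_equals_occurrence_count(self):
        idx = _idx("ACGTACGT")
        lo, hi = idx.backward_search("ACG")
        assert hi - lo == 2

    def test_whole_genome_and_absent_pattern(self):
        idx = _idx("ACGTACGT")
        assert idx.count("ACGTACGT") == 1
        assert idx.count("GGGG") == 0

    def test_pattern_with_n_matches_nothing(self):
        idx = _idx("ANGT")
        assert idx.count("ANG") == 0
        assert idx.count("N") == 0

    def test_counts_match_naive_scan(self, rng):
        """Random (genome, pattern) pairs against a naive substring count."""
        for _ in range(300):
            s = _random_seq(rng, int(rng.integers(10, 400)))
            idx = _idx(s, rate=4)
            k = int(rng.integers(1, 8))
            if rng.random() < 0.7 and len(s) > k:
                i = int(rng.integers(0, len(s) - k))
                pat = s[i : i + k]
            else:
                pat = _random_seq(rng, k)
            assert idx.count(pat) == count_occurrences(pat, s)


class TestMEMSeeds:
    def test_fixed_example_against_brute_force(self):
        genome = "ACGTACGTTT"
        idx = _idx(genome)
        seeds = idx.find_mem_seeds("CGTAC", min_mem_len=3, max_occ=100)
        fwd = {(s.read_offset, s.genome_pos, s.length)
               for s in seeds if s.strand == "+"}
        assert fwd == brute_mems("CGTAC", genome, 3)
        rev = {(s.read_offset, s.genome_pos, s.length)
               for s in seeds if s.strand == "-"}
        assert rev == brute_mems(revcomp("CGTAC"), genome, 3)

    def test_unique_substring_gives_one_spanning_mem(self, small_seq, small_index):
        read = small_seq[5000:5080]
        fwd = [s for s in small_index.find_mem_seeds(read, 17) if s.strand == "+"]
        assert len(fwd) == 1
        assert (fwd[0].read_offset, fwd[0].genome_pos, fwd[0].length) == (
            0, 5000, 80,
        )

    def test_all_n_read_yields_nothing(self, small_index):
        assert small_index.find_mem_seeds("N" * 30, 5) == []

    def test_matches_quadratic_enumerator_on_random_cases(self, rng):
        """Oracle equivalence on random genomes/reads, both strands."""
        for _ in range(30):
            g = _random_seq(rng, int(rng.integers(200, 1500)))
            idx = _idx(g, rate=4)
            if rng.random() < 0.5:
                i = int(rng.integers(0, len(g) - 60))
                read = g[i : i + 50]
            else:
                read = _random_seq(rng, int(rng.integers(20, 80)))
            min_len = int(rng.integers(6, 12))
            seeds = idx.find_mem_seeds(read, min_len, max_occ=10**6)
            got_f = {(s.read_offset, s.genome_pos, s.length)
                     for s in seeds if s.strand == "+"}
            got_r = {(s.read_offset, s.genome_pos, s.length)
                     for s in seeds if s.strand == "-"}
            assert got_f == brute_mems(read, g, min_len)
            assert got_r == brute_mems(revcomp(read), g, min_len)

    def test_strand_symmetry(self, rng):
        """MEMs of R map 1:1 onto MEMs of revcomp(R) with strands swapped."""
        g = _random_seq(rng, 800)
        idx = _idx(g)
        read = g[100:160]
        a = idx.find_mem_seeds(read, 8, max_occ=10**6)
        b = idx.find_mem_seeds(revcomp(read), 8, max_occ=10**6)
        flip = {"+": "-", "-": "+"}
        key = lambda s: (s.read_offset, s.genome_pos, s.length, s.strand)
        mirrored = {
            (s.read_offset, s.genome_pos, s.length, flip[s.strand]) for s in b
        }
        assert {key(s) for s in a} == mirrored

    def test_seeds_never_cross_contig_boundary(self, two_contig_index):
        idx = two_contig_index
        # read spans the junction of the two concatenated contigs
        junction = idx.fetch(int(idx.lengths[0]) - 10, int(idx.lengths[0]) + 11)
        seeds = idx.find_mem_seeds(junction.replace("N", "A"), 5, max_occ=10**6)
        for s in seeds:
            lo, hi = idx.contig_bounds(s.genome_pos)
            assert lo <= s.genome_pos and s.genome_pos + s.length <= hi


class TestKmerSeeds:
    def test_window_count_bound(self, small_index, small_seq):
        read = small_seq[100:200]
        seeds = small_index.find_kmer_seeds(read, k=13, max_occ=10**6)
        fwd_offsets = {s.read_offset for s in seeds if s.strand == "+"}
        assert fwd_offsets <= {13 * i for i in range(7)}

    def test_fixed_example_all_positions(self):
        idx = _idx("ACGTACGT")
        seeds = idx.find_kmer_seeds("ACGTACGT", k=4, max_occ=100)
        fwd = {(s.read_offset, s.genome_pos) for s in seeds if s.strand == "+"}
        assert fwd == {(0, 0), (0, 4), (4, 0), (4, 4)}

    def test_window_with_n_contributes_nothing(self):
        idx = _idx("ACGTACGTACGT")
        seeds = idx.find_kmer_seeds("ACGN" + "ACGT", k=4, max_occ=100)
        assert all(s.read_offset != 0 for s in seeds if s.strand == "+")
        assert any(s.strand == "+" and s.read_offset == 4 for s in seeds)


class TestIndexLifecycle:
    def test_errors_on_empty_and_bad_input(self, tmp_path):
        empty = tmp_path / "e.fa"
        empty.write_text("")
        with pytest.raises(InputError):
            build_index(empty)
        bad = tmp_path / "b.fa"
        bad.write_text(">weird\nAC#T\n")
        with pytest.raises(InputError, match="weird"):
            build_index(bad)

    def test_save_load_roundtrip(self, tmp_path, small_index, small_seq):
        p = tmp_path / "ref.idx"
        small_index.save(p)
        loaded = ReferenceIndex.load(p)
        assert loaded.names == small_index.names
        read = small_seq[700:780]
        a = small_index.find_mem_seeds(read, 17)
        b = loaded.find_mem_seeds(read, 17)
        assert [(s.read_offset, s.genome_pos, s.length, s.strand) for s in a] == [
            (s.read_offset, s.genome_pos, s.length, s.strand) for s in b
        ]

    def test_max_occ_caps_report_deterministically(self):
        idx = _idx("AC" * 200)
        seeds = idx.find_kmer_seeds("ACACACAC", k=4, max_occ=5)
        per_window = {}
        for s in seeds:
            per_window.setdefault((s.strand, s.read_offset), []).append(s)
        for group in per_window.values():
            assert len(group) <= 5
        again = idx.find_kmer_seeds("ACACACAC", k=4, max_occ=5)
        assert [
            (s.read_offset, s.genome_pos, s.strand) for s in seeds
        ] == [(s.read_offset, s.genome_pos, s.strand) for s in again]
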