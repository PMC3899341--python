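import numpy as np
import pytest

from hybridaln import ReferenceIndex, simulate_genome
from hybridaln.io_formats import SeqRecord


@pytest.fixture(scope="session")
def small_genome():
    """60-kb single-contig random genome shared by pipeline tests."""
    return simulate_genome(60_000, seed=7)


@pytest.fixture(scope="session")
def small_index(small_genome):
    return ReferenceIndex.from_records(small_genome)


@pytest.fixture(scope="session")
def small_seq(small_genome):
    return small_genome[0].sequence


@pytest.fixture()
def rng():
    return np.random.default_rng(20260922)


def random_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


@pytest.fixture(scope="session")
def two_contig_index():
    recs = [
        SeqRecord("ctgA", "ACGTACGTTTGACCA" * 4),
        SeqRecord("ctgB", "TTGCAGGCATCAGAT" * 4),
    ]
    return ReferenceIndex.from_records(recs)
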