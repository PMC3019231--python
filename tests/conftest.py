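import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from nrcis.io_formats import GeneRecord, PeakRecord

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(20121547)


@pytest.fixture
def plus_gene():
    """3-exon '+' gene: TSS at 10000, exons [10000,11000) [12000,13000) [15000,16000)."""
    return GeneRecord(
        gene_id="GPLUS",
        symbol="PLUS1",
        chrom="chr1",
        strand="+",
        tx_start=10_000,
        tx_end=16_000,
        exon_starts=(10_000, 12_000, 15_000),
        exon_ends=(11_000, 13_000, 16_000),
    )


@pytest.fixture
def minus_gene():
    """3-exon '-' gene: TSS at 16000; first exon in transcription order is
    the highest-coordinate exon [15000,16000)."""
    return GeneRecord(
        gene_id="GMINUS",
        symbol="MINUS1",
        chrom="chr1",
        strand="-",
        tx_start=10_000,
        tx_end=16_000,
        exon_starts=(10_000, 12_000, 15_000),
        exon_ends=(11_000, 13_000, 16_000),
    )


def make_peak(chrom="chr1", start=0, end=100, height=0.0, name=None):
    return PeakRecord(chrom, start, end, height, name)


def random_peaks(rng, n, chroms=("chr1", "chr2"), span=100_000, max_width=500):
    """Uniform random peak set for oracle comparisons."""
    out = []
    for i in range(n):
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(0, span))
        width = int(rng.integers(1, max_width))
        out.append(PeakRecord(chrom, start, start + width, float(rng.integers(0, 200)), f"p{i}"))
    return out


def brute_force_set_overlap(a, b, tolerance):
    """All-pairs oracle for set_overlap: n_a_hit, n_b_hit, pairs."""
    pairs = []
    for i, pa in enumerate(a):
        for j, pb in enumerate(b):
            if pa.chrom != pb.chrom:
                continue
            g = max(0, max(pa.start, pb.start) - min(pa.end, pb.end))
            if g <= tolerance:
                pairs.append((i, j))
    return len({i for i, _ in pairs}), len({j for _, j in pairs}), sorted(pairs)
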