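import numpy as np
import pysam
import pytest

from hicdesk import GenomeIndex, bin_genome


@pytest.fixture
def toy_genome():
    return GenomeIndex(["chr1", "chr2"], [10_000, 6_000])


@pytest.fixture
def toy_bins(toy_genome):
    return bin_genome(toy_genome, 1_000)


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_901)


def write_sam(path, genome, ends, mapq=60):
    """Minimal single-end SAM: ends = [(name, chrom, five_prime_pos, strand), ...]."""
    header = {
        "HD": {"VN": "1.6"},
        "SQ": [{"SN": n, "LN": genome.lengths[n]} for n in genome.names],
    }
    ref = {n: i for i, n in enumerate(genome.names)}
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for name, chrom, pos, strand, *rest in ends:
            a = pysam.AlignedSegment()
            a.query_name = name
            a.reference_id = ref[chrom]
            a.mapping_quality = rest[0] if rest else mapq
            if strand == "+":
                a.reference_start = pos
            else:
                a.flag = 16
                a.reference_start = pos  # 1M read: 5' base == leftmost base
            a.cigarstring = "1M"
            fh.write(a)
    return str(path)
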