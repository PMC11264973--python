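import numpy as np
import pysam
import pytest

from astruct.alignment_io import ReadObs

REF_NAME = "chr1"
REF_LEN = 1000


def write_bam(path, reads, ref_name=REF_NAME, ref_len=REF_LEN):
    """Write a tiny coordinate-sorted, indexed BAM.

    ``reads`` is a list of (start, sequence) tuples; alignments are gapless,
    forward-strand, MAPQ 60, base quality 40.
    """
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": ref_name, "LN": ref_len}],
    }
    path = str(path)
    with pysam.AlignmentFile(path, "wb", header=header) as bam:
        for i, (start, seq) in enumerate(sorted(reads, key=lambda r: r[0])):
            a = pysam.AlignedSegment(bam.header)
            a.query_name = f"r{i}"
            a.query_sequence = seq
            a.flag = 0
            a.reference_id = 0
            a.reference_start = start
            a.mapping_quality = 60
            a.cigarstring = f"{len(seq)}M"
            a.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
            bam.write(a)
    pysam.index(path)
    return path


def spanning_read(start, length, snp_pos, base):
    """Sequence of A's carrying ``base`` at the SNP position."""
    seq = ["A"] * length
    if start <= snp_pos < start + length:
        seq[snp_pos - start] = base
    return (start, "".join(seq))


def mk_read(start, end, snp_base=None):
    """Forward-strand gapless ReadObs (RT-stop one base before the start)."""
    return ReadObs(start, end, start - 1, ((start, end),), snp_base)


@pytest.fixture
def bam_factory(tmp_path):
    def factory(name, reads, **kw):
        return write_bam(tmp_path / name, reads, **kw)

    return factory


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
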