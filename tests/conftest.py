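import pysam
import pytest


@pytest.fixture
def make_sam(tmp_path):
    """Write a small SAM from (qname, flag, chrom, pos0, cigar) tuples."""

    def _make(records, chroms=None, name="reads.sam"):
        chroms = chroms or {"chr1": 1_000_000, "chr15": 100_000_000}
        header = pysam.AlignmentHeader.from_dict(
            {
                "HD": {"VN": "1.6", "SO": "coordinate"},
                "SQ": [{"SN": c, "LN": ln} for c, ln in chroms.items()],
            }
        )
        path = tmp_path / name
        with pysam.AlignmentFile(str(path), "wh", header=header) as fh:
            for qname, flag, chrom, pos0, cigar in records:
                seg = pysam.AlignedSegment(header)
                seg.query_name = qname
                seg.flag = flag
                seg.reference_id = list(chroms).index(chrom)
                seg.reference_start = pos0
                seg.cigarstring = cigar
                seg.mapping_quality = 60
                fh.write(seg)
        return str(path)

    return _make
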