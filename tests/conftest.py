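import pysam
import pytest

from epitracks.genome_io import GenomeSequence, reverse_complement


@pytest.fixture
def toy_genome() -> GenomeSequence:
    genome = GenomeSequence()
    genome.add("chr1", "ACGTACGTCAGCTTNCGG")
    genome.add("chr2", "CCGG")
    return genome


def make_header(chrom_sizes: dict[str, int] | None = None) -> pysam.AlignmentHeader:
    chrom_sizes = chrom_sizes or {"chr1": 100_000}
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": name, "LN": size} for name, size in chrom_sizes.items()],
        }
    )


def make_read(
    header: pysam.AlignmentHeader,
    name: str = "read",
    start: int = 0,
    length: int = 21,
    strand: str = "+",
    cigar: str | None = None,
    nh: int | None = 1,
    mapq: int = 42,
    seq: str | None = None,
) -> pysam.AlignedSegment:
    """Construct a mapped single-end alignment for tests."""
    a = pysam.AlignedSegment(header)
    a.query_name = name
    a.reference_id = 0
    a.reference_start = start
    a.flag = 16 if strand == "-" else 0
    a.cigarstring = cigar or f"{length}M"
    if seq is None:
        seq = "A" * a.infer_read_length()
    a.query_sequence = seq
    a.mapping_quality = mapq
    if nh is not None:
        a.set_tag("NH", nh)
    return a


def write_sam(path, reads, header) -> None:
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for read in sorted(reads, key=lambda r: (r.reference_id, r.reference_start)):
            out.write(read)


@pytest.fixture
def sam_factory(tmp_path):
    """Write a list of (start, length, strand, nh, mapq) specs to a SAM file."""

    def build(read_specs, chrom_sizes=None, cigars=None):
        header = make_header(chrom_sizes)
        reads = []
        for i, spec in enumerate(read_specs):
            start, length, strand, nh, mapq = spec
            cigar = cigars[i] if cigars else None
            reads.append(
                make_read(header, f"r{i}", start, length, strand, cigar, nh, mapq)
            )
        path = tmp_path / "reads.sam"
        write_sam(path, reads, header)
        return path

    return build
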