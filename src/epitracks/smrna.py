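"""Small-RNA read classification, filtering, locus clustering and typing.

Small non-coding RNAs are typically 18-30 nt, and their size together with
strandedness hints at function: in plants, 21 nt reads from a single strand
suggest microRNAs, 24 nt reads from both strands suggest heterochromatic
small interfering RNAs, while RNA degradation products show a spread of
sizes from one strand. Reads are classified by query length (the molecule's
size, not its reference span), strand, mapping quality and uniqueness —
multimapped reads (NH tag > 1, or MAPQ 0 when NH is absent) are drawn
unfilled in track renders so unique placements stand out.

Locus typing is an explicit extension: it operationalizes the size/strand
rules above at locus level with configurable thresholds, which display
tracks leave qualitative.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import pysam

from .coverage import iter_region_reads
from .genome_io import Region

logger = logging.getLogger(__name__)

CATEGORIES = ("miRNA_like", "siRNA_like", "degradation_like", "ambiguous")

MIRNA_LENGTH = 21  # nt, single-strand microRNA class
SIRNA_LENGTH = 24  # nt, both-strand siRNA class


@dataclass(frozen=True)
class SmRNARead:
    """One aligned small-RNA read."""

    region: Region
    strand: str
    length: int  # nt, query length
    multimapped: bool
    mapq: int

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("read length must be >= 1 nt")


@dataclass(frozen=True)
class SmRNAFilter:
    """Size / strand / quality / uniqueness read filter.

    Defaults keep the conventional small-RNA size range 18-30 nt, both
    strands, any mapping quality, multimapped reads included.
    """

    min_len: int = 18
    max_len: int = 30
    strand: str = "both"
    min_mapq: int = 0
    unique_only: bool = False

    def __post_init__(self) -> None:
        if self.min_len > self.max_len:
            raise ValueError("min_len must be <= max_len")
        if self.strand not in ("+", "-", "both"):
            raise ValueError(f"invalid strand filter {self.strand!r}")

    def keep(self, read: SmRNARead) -> bool:
        return (
            self.min_len <= read.length <= self.max_len
            and (self.strand == "both" or read.strand == self.strand)
            and read.mapq >= self.min_mapq
            and (not self.unique_only or not read.multimapped)
        )


@dataclass
class SmRNALocus:
    """A cluster of overlapping/nearby reads with summary statistics."""

    region: Region
    reads: list[SmRNARead] = field(default_factory=list)
    modal_length: int = 0
    modal_fraction: float = 0.0
    minor_strand_fraction: float = 0.0
    category: str = "ambiguous"


def classify_read(alignment: pysam.AlignedSegment) -> SmRNARead:
    """Extract length / strand / uniqueness from a mapped primary alignment.

    Length is the query sequence length (the sequenced molecule). A read is
    multimapped when its NH tag exceeds 1; without an NH tag, MAPQ 0 is the
    common aligner signal for multiple placements and is used as fallback.
    """
    length = alignment.infer_read_length() or alignment.query_length
    if not length:
        raise ValueError(
            f"read {alignment.query_name}: no query sequence and no "
            "length-bearing CIGAR"
        )
    if alignment.has_tag("NH"):
        multimapped = alignment.get_tag("NH") > 1
    else:
        multimapped = alignment.mapping_quality == 0
    region = Region(
        alignment.reference_name,
        alignment.reference_start,
        alignment.reference_end,
        "-" if alignment.is_reverse else "+",
    )
    return SmRNARead(
        region=region,
        strand="-" if alignment.is_reverse else "+",
        length=int(length),
        multimapped=bool(multimapped),
        mapq=alignment.mapping_quality,
    )


def read_sam(
    path: str | Path, region: Region | None = None
) -> list[SmRNARead]:
    """Classify every mapped primary alignment in a SAM/BAM file."""
    return [classify_read(a) for a in iter_region_reads(path, region)]


def filter_reads(
    reads: Iterable[SmRNARead], flt: SmRNAFilter | None = None
) -> list[SmRNARead]:
    """Apply a size/strand/quality/uniqueness filter; idempotent."""
    flt = flt or SmRNAFilter()
    return [r for r in reads if flt.keep(r)]


def cluster_loci(
    reads: Sequence[SmRNARead],
    max_gap: int = 50,
    min_reads: int = 5,
    modal_fraction_min: float = 0.8,
    minor_strand_min: float = 0.2,
) -> list[SmRNALocus]:
    """Single-linkage clustering of read spans into loci, then typing.

    Reads whose spans are separated by at most *max_gap* bp on the same
    chromosome merge into one locus (the union span); each locus is then
    categorized by :func:`classify_locus`.
    """
    ordered = sorted(reads, key=lambda r: (r.region.chrom, r.region.start, r.region.end))
    loci: list[SmRNALocus] = []
    current: list[SmRNARead] = []
    cur_chrom, cur_end = None, None
    for read in ordered:
        if (
            current
            and read.region.chrom == cur_chrom
            and read.region.start - cur_end <= max_gap
        ):
            current.append(read)
            cur_end = max(cur_end, read.region.end)
        else:
            if current:
                loci.append(_build_locus(current))
            current = [read]
            cur_chrom, cur_end = read.region.chrom, read.region.end
    if current:
        loci.append(_build_locus(current))
    for locus in loci:
        locus.category = classify_locus(
            locus,
            min_reads=min_reads,
            modal_fraction_min=modal_fraction_min,
            minor_strand_min=minor_strand_min,
        )
    return loci


def _build_locus(members: list[SmRNARead]) -> SmRNALocus:
    start = min(r.region.start for r in members)
    end = max(r.region.end for r in members)
    locus = SmRNALocus(Region(members[0].region.chrom, start, end), members)
    lengths = Counter(r.length for r in members)
    locus.modal_length, modal_n = max(lengths.items(), key=lambda kv: (kv[1], -kv[0]))
    locus.modal_fraction = modal_n / len(members)
    n_plus = sum(1 for r in members if r.strand == "+")
    locus.minor_strand_fraction = min(n_plus, len(members) - n_plus) / len(members)
    return locus


def classify_locus(
    locus: SmRNALocus,
    min_reads: int = 5,
    modal_fraction_min: float = 0.8,
    minor_strand_min: float = 0.2,
) -> str:
    """Type a locus from its size uniformity and strand distribution.

    uniform := modal_fraction >= modal_fraction_min (default 0.8);
    both_strands := minor_strand_fraction >= minor_strand_min (default 0.2).
    uniform 21 nt single-strand -> miRNA_like; uniform 24 nt both-strand ->
    siRNA_like; non-uniform single-strand -> degradation_like; anything
    else -> ambiguous. Loci with fewer than *min_reads* members are
    ambiguous (insufficient evidence).
    """
    if len(locus.reads) < min_reads:
        logger.debug(
            "locus %s: %d reads < min_reads=%d, ambiguous",
            locus.region, len(locus.reads), min_reads,
        )
        return "ambiguous"
    uniform = locus.modal_fraction >= modal_fraction_min
    both_strands = locus.minor_strand_fraction >= minor_strand_min
    if uniform and locus.modal_length == MIRNA_LENGTH and not both_strands:
        return "miRNA_like"
    if uniform and locus.modal_length == SIRNA_LENGTH and both_strands:
        return "siRNA_like"
    if not uniform and not both_strands:
        return "degradation_like"
    return "ambiguous"


def layout_reads(
    reads: Sequence[SmRNARead], region: Region | None = None
) -> list[tuple[SmRNARead, int]]:
    """Greedy interval packing into signed rows for track display.

    Plus-strand reads occupy rows +1, +2, ... and minus-strand reads rows
    -1, -2, ..., each read taking the first row where it overlaps nothing
    (overlap on [start, end)). Row sign encodes strand: above vs below the
    y-axis origin.
    """
    rows: dict[int, int] = {}  # row -> right edge of last placed read
    placements: list[tuple[SmRNARead, int]] = []
    ordered = sorted(reads, key=lambda r: (r.region.start, r.region.end))
    for read in ordered:
        if region is not None and not region.overlaps(read.region):
            continue
        direction = 1 if read.strand == "+" else -1
        row = direction
        while row in rows and rows[row] > read.region.start:
            row += direction
        rows[row] = read.region.end
        placements.append((read, row))
    return placements


def loci_table(loci: Sequence[SmRNALocus]) -> pd.DataFrame:
    """Locus summary table (chrom, start0, end, n_reads, modal stats, category)."""
    return pd.DataFrame(
        [
            {
                "chrom": loc.region.chrom,
                "start0": loc.region.start,
                "end": loc.region.end,
                "n_reads": len(loc.reads),
                "modal_length": loc.modal_length,
                "modal_fraction": round(loc.modal_fraction, 6),
                "minor_strand_fraction": round(loc.minor_strand_fraction, 6),
                "category": loc.category,
            }
            for loc in loci
        ],
        columns=[
            "chrom", "start0", "end", "n_reads", "modal_length",
            "modal_fraction", "minor_strand_fraction", "category",
        ],
    )
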