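"""Stranded and unstranded per-base read coverage from alignments.

Strand-dependent assays (WGBS, small RNAs, mRNAs) can have very different
read depth on the two strands, and averaging them hides that — e.g. uneven
strand coverage can make only one strand of a site look methylated. The
stranded track therefore counts forward- and reverse-strand alignments
separately; the minus profile is written as negative values so one signed
track shows both. The unstranded track (ChIP-seq / ATAC-seq style) is the
per-base sum of the two.

Each aligned base (CIGAR M/=/X) increments coverage; deletions and intron
skips (D/N) consume reference without incrementing; insertions and clips
consume none. Read strand comes from the alignment flag; secondary and
supplementary alignments are excluded by default and duplicates are
counted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pysam

from ._bedgraph import read_bedgraph, write_bedgraph
from .genome_io import Region

logger = logging.getLogger(__name__)

# CIGAR ops that consume reference and represent aligned bases
_ALIGNED_OPS = {0, 7, 8}  # M, =, X
# CIGAR ops that consume reference but are not aligned bases
_GAP_OPS = {2, 3}  # D, N


@dataclass
class StrandedCoverage:
    """Per-base counts over a region, one non-negative array per strand."""

    region: Region
    plus: np.ndarray
    minus: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.region)
        if len(self.plus) != n or len(self.minus) != n:
            raise ValueError("coverage arrays must match region length")

    @property
    def total(self) -> np.ndarray:
        return self.plus + self.minus


def _aligned_blocks(read: pysam.AlignedSegment) -> Iterable[tuple[int, int]]:
    """Reference blocks of aligned (M/=/X) bases, walking the CIGAR."""
    pos = read.reference_start
    for op, length in read.cigartuples or ():
        if op in _ALIGNED_OPS:
            yield pos, pos + length
            pos += length
        elif op in _GAP_OPS:
            pos += length
        # I/S/H/P consume no reference


def iter_region_reads(
    alignments: str | Path | pysam.AlignmentFile | Iterable[pysam.AlignedSegment],
    region: Region | None = None,
    include_secondary: bool = False,
):
    """Yield mapped primary reads overlapping *region* from SAM/BAM or iterable."""
    if isinstance(alignments, (str, Path)):
        with pysam.AlignmentFile(str(alignments), check_sq=False) as af:
            yield from iter_region_reads(af, region, include_secondary)
        return
    if isinstance(alignments, pysam.AlignmentFile):
        reads: Iterable[pysam.AlignedSegment] = alignments.fetch(until_eof=True)
    else:
        reads = alignments
    for read in reads:
        if read.is_unmapped:
            logger.debug("skipping unmapped read %s", read.query_name)
            continue
        if not include_secondary and (read.is_secondary or read.is_supplementary):
            continue
        if region is not None:
            if read.reference_name != region.chrom:
                continue
            if read.reference_end <= region.start or read.reference_start >= region.end:
                continue
        yield read


def stranded_coverage(alignments, region: Region) -> StrandedCoverage:
    """Per-base forward/reverse coverage over *region*."""
    plus = np.zeros(len(region), dtype=np.int64)
    minus = np.zeros(len(region), dtype=np.int64)
    for read in iter_region_reads(alignments, region):
        target = minus if read.is_reverse else plus
        for start, end in _aligned_blocks(read):
            lo = max(start, region.start) - region.start
            hi = min(end, region.end) - region.start
            if lo < hi:
                target[lo:hi] += 1
    return StrandedCoverage(region, plus, minus)


def unstranded_coverage(alignments, region: Region) -> np.ndarray:
    """Strand-independent per-base coverage; equals plus + minus everywhere."""
    return stranded_coverage(alignments, region).total


def _rle_intervals(values: np.ndarray, region: Region, keep_zero: bool = False):
    """Merge equal adjacent per-base values into bedGraph intervals."""
    if len(values) == 0:
        return
    boundaries = np.flatnonzero(np.diff(values)) + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [len(values)]))
    for start, end in zip(starts, ends):
        value = values[start]
        if value != 0 or keep_zero:
            yield region.chrom, region.start + int(start), region.start + int(end), value


def write_coverage(
    cov: StrandedCoverage | np.ndarray,
    path: str | Path,
    signed: bool = True,
    region: Region | None = None,
) -> None:
    """Write coverage as run-length-merged bedGraph (zero runs omitted).

    A :class:`StrandedCoverage` with ``signed=True`` writes one file with
    minus-strand values negated; ``signed=False`` writes the unstranded
    sum. A bare array (with *region*) writes as-is.
    """
    if isinstance(cov, StrandedCoverage):
        if signed:
            rows = list(_rle_intervals(cov.plus, cov.region))
            rows += [
                (chrom, start, end, -value)
                for chrom, start, end, value in _rle_intervals(cov.minus, cov.region)
            ]
            # plus rows first at equal starts; opposite-sign rows may overlap,
            # mirroring the single-track display of both strands at once
            rows.sort(key=lambda r: (r[0], r[1], -r[3]))
            write_bedgraph(rows, path)
        else:
            write_bedgraph(list(_rle_intervals(cov.total, cov.region)), path)
    else:
        if region is None:
            raise ValueError("region required when writing a bare array")
        write_bedgraph(list(_rle_intervals(np.asarray(cov), region)), path)


def read_stranded_coverage(path: str | Path, region: Region) -> StrandedCoverage:
    """Inverse of the signed :func:`write_coverage`: sign assigns the strand."""
    plus = np.zeros(len(region), dtype=np.int64)
    minus = np.zeros(len(region), dtype=np.int64)
    for chrom, start, end, value in read_bedgraph(path, allow_overlap=True):
        if chrom != region.chrom:
            continue
        lo = max(start, region.start) - region.start
        hi = min(end, region.end) - region.start
        if lo < hi:
            target = plus if value >= 0 else minus
            target[lo:hi] = abs(int(value))
    return StrandedCoverage(region, plus, minus)


def write_coverage_split(
    cov: StrandedCoverage, plus_path: str | Path, minus_path: str | Path,
    signed_minus: bool = True,
) -> None:
    """Write plus and minus profiles to separate files (lossless)."""
    write_bedgraph(list(_rle_intervals(cov.plus, cov.region)), plus_path)
    minus_rows = [
        (chrom, start, end, -value if signed_minus else value)
        for chrom, start, end, value in _rle_intervals(cov.minus, cov.region)
    ]
    write_bedgraph(minus_rows, minus_path)


def read_coverage(path: str | Path, region: Region) -> np.ndarray:
    """Read a bedGraph back into a per-base array over *region* (zeros filled)."""
    values = np.zeros(len(region), dtype=np.float64)
    for chrom, start, end, value in read_bedgraph(path):
        if chrom != region.chrom:
            continue
        lo = max(start, region.start) - region.start
        hi = min(end, region.end) - region.start
        if lo < hi:
            values[lo:hi] = value
    if np.all(values == np.round(values)):
        return values.astype(np.int64)
    return values
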