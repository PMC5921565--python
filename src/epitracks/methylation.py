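"""Per-position base-modification levels as strand-signed tracks.

Input is the allc-style table common WGBS pipelines emit: one row per
covered cytosine (or adenine for 6mA) with chromosome, 1-based position,
strand, strand-local trinucleotide context, modified-read count and total
read count. The methylation level at a site is mc/total in [0, 1]; it is
written *signed* — positive for plus-strand sites, negative for minus — so
a single track carries both strands, with bar height giving the level and
bar direction the strand.

Tracks are partitioned by (context class, modification type), and can be
filtered by context, modification and a minimum coverage floor before
writing. Output is single-base-interval signed bedGraph; a minus-strand
cytosine occupies its own genomic coordinate (the complementary G's
position), so plus and minus sites never collide at one coordinate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from . import contexts
from ._bedgraph import read_bedgraph, write_bedgraph
from .genome_io import GenomeSequence

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MethylationRecord:
    """One allc row, position stored 0-based."""

    chrom: str
    pos: int  # 0-based
    strand: str
    context_3mer: str
    mod: str
    mc_count: int
    total_count: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"malformed strand {self.strand!r}")
        if not 0 <= self.mc_count <= self.total_count:
            raise ValueError(
                f"{self.chrom}:{self.pos}: mc_count {self.mc_count} outside "
                f"[0, total_count={self.total_count}]"
            )

    @property
    def level(self) -> float:
        return self.mc_count / self.total_count


@dataclass
class SignedLevelTrack:
    """Signed per-site modification levels for one (context class, mod)."""

    context_class: str
    mod: str
    # (chrom, pos0, strand, signed level)
    sites: list[tuple[str, int, str, float]] = field(default_factory=list)

    def add(self, chrom: str, pos: int, strand: str, level: float) -> None:
        signed = level if strand == "+" else -level
        if not -1.0 <= signed <= 1.0:
            raise ValueError(f"level {level} outside [0,1]")
        self.sites.append((chrom, pos, strand, signed))

    def mean_abs_level(self) -> float:
        if not self.sites:
            return float("nan")
        return sum(abs(s[3]) for s in self.sites) / len(self.sites)

    def __len__(self) -> int:
        return len(self.sites)


def parse_allc(
    path: str | Path, mod_default: str = "5mC"
) -> Iterator[MethylationRecord]:
    """Stream allc-style rows as :class:`MethylationRecord`.

    Columns: chrom, pos (1-based), strand, context 3-mer, mc_count,
    total_count, plus an optional trailing binary-call column which is
    ignored. mc_count > total_count or a malformed strand is a hard error
    naming the line.
    """
    n = 0
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}:{lineno}: expected >=6 columns, got {len(fields)}")
            chrom, pos1, strand, mer = fields[0], fields[1], fields[2], fields[3]
            try:
                mc, total = int(fields[4]), int(fields[5])
                if mc < 0 or total < 0:
                    raise ValueError
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: counts must be non-negative integers"
                ) from None
            try:
                record = MethylationRecord(
                    chrom, int(pos1) - 1, strand, mer.upper(), mod_default, mc, total
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            n += 1
            yield record
    if n == 0:
        logger.warning("no records in %s", path)


def validate_against_genome(
    records: Iterable[MethylationRecord], genome: GenomeSequence, mode: str
) -> Iterator[MethylationRecord]:
    """Opt-in check that each record's 3-mer matches the supplied genome."""
    for rec in records:
        expected = contexts.local_trinucleotide(genome, rec.chrom, rec.pos, rec.strand)
        got = rec.context_3mer[: len(expected)]
        if expected != got:
            raise ValueError(
                f"{rec.chrom}:{rec.pos}({rec.strand}): context {rec.context_3mer!r} "
                f"disagrees with genome 3-mer {expected!r}"
            )
        yield rec


def compute_levels(
    records: Iterable[MethylationRecord],
    mode: str = "plant",
    context_filter: Iterable[str] | None = None,
    mod_filter: Iterable[str] | None = None,
    min_coverage: int = 1,
) -> dict[tuple[str, str], SignedLevelTrack]:
    """Turn records into signed level tracks keyed by (context class, mod).

    Sites with total_count below *min_coverage* are dropped. With no
    filters, every retained input site lands in exactly one output track
    (tracks partition the sites). *context_filter* must name classes valid
    for *mode* (``unknown`` and the 6mA class ``A`` are always acceptable).
    """
    if min_coverage < 1:
        raise ValueError("min_coverage must be >= 1")
    valid = set(contexts.classes_for_mode(mode)) | {contexts.UNKNOWN, contexts.ADENINE_CLASS}
    if context_filter is not None:
        context_filter = set(context_filter)
        bad = context_filter - valid
        if bad:
            raise ValueError(
                f"context filter {sorted(bad)} invalid for mode {mode!r}; "
                f"valid classes: {sorted(valid)}"
            )
    if mod_filter is not None:
        mod_filter = set(mod_filter)
    tracks: dict[tuple[str, str], SignedLevelTrack] = {}
    for rec in records:
        if rec.total_count < min_coverage:
            continue
        if mod_filter is not None and rec.mod not in mod_filter:
            continue
        target = contexts.MOD_TARGET_BASE[rec.mod]
        label = contexts.classify_trinucleotide(rec.context_3mer, mode, target)
        if context_filter is not None and label not in context_filter:
            continue
        key = (label, rec.mod)
        if key not in tracks:
            tracks[key] = SignedLevelTrack(label, rec.mod)
        tracks[key].add(rec.chrom, rec.pos, rec.strand, rec.level)
    return tracks


def write_signed_bedgraph(track: SignedLevelTrack, path: str | Path) -> None:
    """Write one signed level track as single-base bedGraph intervals."""
    rows = sorted(
        ((chrom, pos, pos + 1, level) for chrom, pos, _, level in track.sites),
        key=lambda r: (r[0], r[1]),
    )
    write_bedgraph(rows, path)


def read_signed_bedgraph(
    path: str | Path, context_class: str = "unknown", mod: str = "5mC"
) -> SignedLevelTrack:
    """Exact inverse of :func:`write_signed_bedgraph` (strand from sign)."""
    track = SignedLevelTrack(context_class, mod)
    for chrom, start, end, value in read_bedgraph(path):
        if end != start + 1:
            raise ValueError(f"{path}: expected single-base intervals, got {start}-{end}")
        track.sites.append((chrom, start, "+" if value >= 0 else "-", value))
    return track
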