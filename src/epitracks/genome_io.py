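"""Genome, region and annotation I/O shared by every track module.

Internal coordinates are 0-based half-open everywhere. Conversion to and
from 1-based inclusive conventions (GFF3, allc, ``chrom:start-end`` region
strings) happens only at format boundaries.

A *genome* sequence is restricted to the unambiguous alphabet {A,C,G,T,N}:
cytosine-context classification (CG vs CHG vs CHH) is undefined on
degenerate bases, so degenerate IUPAC codes are permitted only in motif
queries, never in a reference sequence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import gffutils
from Bio import SeqIO

logger = logging.getLogger(__name__)

GENOME_ALPHABET = frozenset("ACGTN")

#: IUPAC nucleotide code -> set of concrete bases it stands for.
IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

#: IUPAC complement table: the complement of a code is the code whose base
#: set is the base-wise complement (R<->Y, H<->D, N<->N, ...).
IUPAC_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}


class GenomeSequence(dict):
    """Ordered name -> uppercase sequence mapping over {A,C,G,T,N}.

    Insertion order is the chromosome order (file order when read from
    FASTA). Behaves as a plain dict of strings plus a length helper.
    """

    def length(self, chrom: str) -> int:
        return len(self[chrom])

    def add(self, name: str, seq: str) -> None:
        if not name:
            raise ValueError("chromosome name must be non-empty")
        if name in self:
            raise ValueError(f"duplicate chromosome name {name!r}")
        seq = seq.upper()
        if not seq:
            raise ValueError(f"chromosome {name!r} has empty sequence")
        for i, base in enumerate(seq):
            if base not in GENOME_ALPHABET:
                raise ValueError(
                    f"disallowed letter {base!r} in chromosome {name!r} "
                    f"at position {i} (0-based); genomes must use A,C,G,T,N"
                )
        self[name] = seq


@dataclass(frozen=True)
class Region:
    """Genomic interval, 0-based half-open, with optional strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid region {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Region") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "Region") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


FEATURE_KINDS = ("gene", "transposable_element", "other")


@dataclass
class Annotation:
    """A top-level genomic feature (gene / TE / other) with optional exons."""

    region: Region
    feature_kind: str
    identifier: str
    children: list[Region] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.feature_kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.feature_kind!r}")
        for child in self.children:
            if not self.region.contains(child):
                raise ValueError(
                    f"child {child} of {self.identifier} extends outside "
                    f"parent region {self.region}"
                )


def parse_region(text: str, genome: GenomeSequence | None = None) -> Region:
    """Parse a browser-style ``chrom:start-end`` string (1-based inclusive).

    ``chrom`` alone selects the whole chromosome (requires *genome*).
    """
    if ":" not in text:
        if genome is None or text not in genome:
            raise ValueError(f"cannot resolve region {text!r} without a genome")
        return Region(text, 0, genome.length(text))
    chrom, _, span = text.partition(":")
    lo, _, hi = span.partition("-")
    start1, end1 = int(lo.replace(",", "")), int(hi.replace(",", ""))
    region = Region(chrom, start1 - 1, end1)
    if genome is not None:
        if chrom not in genome:
            raise ValueError(f"unknown chromosome {chrom!r}")
        if region.end > genome.length(chrom):
            raise ValueError(
                f"region {text} extends past end of {chrom} "
                f"({genome.length(chrom)} bp)"
            )
    return region


def read_fasta(path: str | Path) -> GenomeSequence:
    """Load a multi-record FASTA into a :class:`GenomeSequence`.

    Sequences are uppercased; chromosome order is file order. Duplicate
    headers, empty sequences and letters outside {A,C,G,T,N} are hard
    errors.
    """
    genome = GenomeSequence()
    for record in SeqIO.parse(str(path), "fasta"):
        genome.add(record.id, str(record.seq))
    if not genome:
        raise ValueError(f"no FASTA records found in {path}")
    return genome


def write_fasta(genome: GenomeSequence, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as handle:
        for name, seq in genome.items():
            handle.write(f">{name}\n")
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")


def reverse_complement(seq: str) -> str:
    """Reverse-complement a sequence over the full IUPAC alphabet.

    Degenerate codes complement to the code of the complemented base set
    (R<->Y, H<->D, N<->N, ...). Non-IUPAC letters are an error.
    """
    out = []
    for base in reversed(seq.upper()):
        try:
            out.append(IUPAC_COMPLEMENT[base])
        except KeyError:
            raise ValueError(f"non-IUPAC letter {base!r} in sequence") from None
    return "".join(out)


_KIND_BY_GFF_TYPE = {"gene": "gene", "transposable_element": "transposable_element"}


def read_gff3(path: str | Path, genome: GenomeSequence | None = None) -> list[Annotation]:
    """Read GFF3 (1-based inclusive) into 0-based half-open annotations.

    Feature types ``gene`` and ``transposable_element`` map to their own
    kinds; every other top-level type maps to ``other``. Children (exons)
    are attached to their parent. Features on chromosomes missing from
    *genome* are kept but logged, since annotations may outrun a toy genome.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        keep_order=True,
        merge_strategy="create_unique",
        sort_attribute_values=False,
    )
    annotations: list[Annotation] = []
    for feat in db.all_features():
        if "Parent" in feat.attributes:
            continue  # children are collected through their parent
        if feat.end < feat.start:
            raise ValueError(f"feature {feat.id}: end < start")
        kind = _KIND_BY_GFF_TYPE.get(feat.featuretype, "other")
        if genome is not None and feat.seqid not in genome:
            logger.warning(
                "annotation %s on chromosome %s absent from genome",
                feat.id, feat.seqid,
            )
        region = Region(feat.seqid, feat.start - 1, feat.end, feat.strand or ".")
        children = [
            Region(c.seqid, c.start - 1, c.end, c.strand or ".")
            for c in sorted(db.children(feat), key=lambda c: c.start)
        ]
        annotations.append(Annotation(region, kind, feat.id, children))
    return annotations


def write_gff3(annotations: Iterable[Annotation], path: str | Path) -> None:
    """Write annotations back out as GFF3 (inverse of :func:`read_gff3`)."""
    kind_to_type = {"gene": "gene", "transposable_element": "transposable_element",
                    "other": "region"}
    with open(path, "w") as handle:
        handle.write("##gff-version 3\n")
        for anno in annotations:
            r = anno.region
            handle.write(
                "\t".join(
                    [r.chrom, "epitracks", kind_to_type[anno.feature_kind],
                     str(r.start + 1), str(r.end), ".", r.strand, ".",
                     f"ID={anno.identifier}"]
                )
                + "\n"
            )
            for i, child in enumerate(anno.children, 1):
                handle.write(
                    "\t".join(
                        [child.chrom, "epitracks", "exon",
                         str(child.start + 1), str(child.end), ".",
                         child.strand, ".",
                         f"ID={anno.identifier}.exon{i};Parent={anno.identifier}"]
                    )
                    + "\n"
                )
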