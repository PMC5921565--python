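"""Cytosine (and adenine) sequence-context classification.

5mC methylation is read in the local trinucleotide context of each cytosine
on its own strand: plants distinguish CG, CHG and CHH (H = A, C or T),
animals collapse the non-CG classes into a single CH class, because the
contexts are established and maintained by different pathways. 6mA sits on
adenines and carries no sub-context here; it is tracked as its own class
``A`` and kept separate from the cytosine modifications by modification
type.

Strand handling: for a minus-strand site the 3-mer is read 5'->3' on the
reverse complement. Any N inside the strand-local 3-mer, or a site with
fewer than two downstream bases (chromosome end), classifies as
``unknown`` — context is never fabricated at sequence boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

from .genome_io import GenomeSequence, reverse_complement

PLANT_CLASSES = ("CG", "CHG", "CHH")
ANIMAL_CLASSES = ("CG", "CH")
UNKNOWN = "unknown"
ADENINE_CLASS = "A"

MODES = ("plant", "animal")

#: modification -> strand-local target base
MOD_TARGET_BASE = {"4mC": "C", "5mC": "C", "5hmC": "C", "6mA": "A"}
BASE_MOD_TYPES = tuple(MOD_TARGET_BASE)


def classes_for_mode(mode: str) -> tuple[str, ...]:
    if mode == "plant":
        return PLANT_CLASSES
    if mode == "animal":
        return ANIMAL_CLASSES
    raise ValueError(f"unknown context mode {mode!r}; expected one of {MODES}")


@dataclass(frozen=True)
class ContextClass:
    """A context label together with the strand-local 3-mer producing it."""

    label: str
    trinucleotide: str


def classify_trinucleotide(mer: str, mode: str, target_base: str = "C") -> str:
    """Classify a strand-local 5'->3' 3-mer into a context class label.

    *mer* may be shorter than 3 characters (chromosome end) or contain N;
    both yield ``unknown``. Adenine targets (6mA) always classify as ``A``.
    """
    classes_for_mode(mode)  # validate mode
    if target_base == "A":
        return ADENINE_CLASS
    mer = mer.upper()
    if len(mer) < 3 or "N" in mer:
        return UNKNOWN
    if mer[1] == "G":
        return "CG"
    if mode == "plant":
        return "CHG" if mer[2] == "G" else "CHH"
    return "CH"


def local_trinucleotide(genome: GenomeSequence, chrom: str, pos: int, strand: str) -> str:
    """Strand-local 3-mer starting at *pos* (plus-strand 0-based coordinate).

    For the minus strand, the 3-mer runs 5'->3' on the reverse complement,
    i.e. it covers plus-coordinates [pos-2, pos]. Truncated at chromosome
    boundaries (the caller treats short mers as unknown context).
    """
    seq = genome[chrom]
    if strand == "+":
        return seq[pos : pos + 3]
    if strand == "-":
        return reverse_complement(seq[max(pos - 2, 0) : pos + 1])
    raise ValueError(f"invalid strand {strand!r}")


def assign_context(
    genome: GenomeSequence,
    chrom: str,
    pos: int,
    strand: str,
    mode: str,
    mod: str = "5mC",
) -> ContextClass:
    """Classify the site at (*chrom*, *pos*, *strand*) into a context class.

    *pos* is the plus-strand 0-based coordinate of the base. The base on
    the given strand must be the modification's target base (C for 4mC /
    5mC / 5hmC, A for 6mA); anything else is an error, not ``unknown``.
    """
    target = MOD_TARGET_BASE[mod]
    seq = genome[chrom]
    if not 0 <= pos < len(seq):
        raise IndexError(f"position {pos} outside chromosome {chrom}")
    plus_base = seq[pos]
    local_base = plus_base if strand == "+" else reverse_complement(plus_base)
    if local_base != target:
        raise ValueError(
            f"{chrom}:{pos}({strand}) is {local_base!r}, expected {target!r} for {mod}"
        )
    mer = local_trinucleotide(genome, chrom, pos, strand)
    return ContextClass(classify_trinucleotide(mer, mode, target), mer)


def enumerate_targets(
    genome: GenomeSequence, mode: str, mod: str = "5mC"
) -> Iterator[tuple[str, int, str, ContextClass]]:
    """Yield every potential modification site on both strands.

    Emits (chrom, pos0, strand, ContextClass) for every C (cytosine mods)
    or A (6mA) on either strand, sorted by chromosome (genome order), then
    position, with + before - at equal positions. Reference N bases are
    never emitted as sites.
    """
    target = MOD_TARGET_BASE[mod]
    complement_target = reverse_complement(target)
    for chrom, seq in genome.items():
        for pos, base in enumerate(seq):
            if base == target:
                yield chrom, pos, "+", assign_context(genome, chrom, pos, "+", mode, mod)
            elif base == complement_target:
                yield chrom, pos, "-", assign_context(genome, chrom, pos, "-", mode, mod)
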