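"""Deterministic synthetic data emulating desk-scale epigenomics inputs.

Generates, from one seed, everything the track modules consume: a random
genome (FASTA), gene/TE annotations (GFF3), a per-cytosine methylome in
allc format, and a small-RNA alignment file (SAM). The shapes emulate an
A. thaliana-like setting: ~36% GC, plant cytosine contexts with high CG
(0.8), intermediate CHG (0.3) and low CHH (0.05) mean methylation,
small-RNA loci of the three canonical kinds (21 nt single-strand, 24 nt
both-strand, mixed-size single-strand degradation), read depths 1+Poisson.

What this does *not* emulate: real chromatin spatial structure, bisulfite
conversion errors, sequencing error, hairpin precursors, and locus-length
distributions — tests passing on these fixtures validate the computations,
not biological discovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pysam

from . import contexts
from .genome_io import GenomeSequence, reverse_complement, write_fasta

DEGRADATION_MIN, DEGRADATION_MAX = 18, 30  # nt


@dataclass(frozen=True)
class LocusPlan:
    """One planned small-RNA locus."""

    lengths: tuple[int, ...]  # drawn uniformly when more than one
    strands: str  # "+", "-", or "both" (reads alternate strands)
    n_reads: int = 20
    multimapped_fraction: float = 0.0


def mirna_locus(n_reads: int = 20, strand: str = "+", multimapped_fraction: float = 0.0):
    return LocusPlan((21,), strand, n_reads, multimapped_fraction)


def sirna_locus(n_reads: int = 20, multimapped_fraction: float = 0.0):
    return LocusPlan((24,), "both", n_reads, multimapped_fraction)


def degradation_locus(n_reads: int = 20, strand: str = "+", multimapped_fraction: float = 0.0):
    return LocusPlan(
        tuple(range(DEGRADATION_MIN, DEGRADATION_MAX + 1)), strand, n_reads,
        multimapped_fraction,
    )


@dataclass
class FixtureSpec:
    """Study conditions for the synthetic data set (all seeded)."""

    seed: int = 42
    genome_length: int = 30_000
    gc_fraction: float = 0.36  # A. thaliana-like
    mode: str = "plant"
    # mean methylation level per context class
    context_means: dict[str, float] = field(
        default_factory=lambda: {"CG": 0.8, "CHG": 0.3, "CHH": 0.05, "unknown": 0.05}
    )
    coverage_mean: float = 6.0  # total_count ~ 1 + Poisson(mean - 1)
    n_mirna_loci: int = 3
    n_sirna_loci: int = 3
    n_degradation_loci: int = 3
    reads_per_locus: int = 20
    multimapped_fraction: float = 0.2
    n_genes: int = 5
    n_te: int = 3

    def __post_init__(self) -> None:
        contexts.classes_for_mode(self.mode)
        for cls, mean in self.context_means.items():
            if not 0.0 <= mean <= 1.0:
                raise ValueError(f"context mean for {cls} outside [0,1]: {mean}")
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ValueError("GC fraction must lie in [0,1]")

    def smrna_plans(self) -> list[LocusPlan]:
        plans = [mirna_locus(self.reads_per_locus, "+", self.multimapped_fraction)
                 for _ in range(self.n_mirna_loci)]
        plans += [sirna_locus(self.reads_per_locus, self.multimapped_fraction)
                  for _ in range(self.n_sirna_loci)]
        plans += [degradation_locus(self.reads_per_locus, "-", self.multimapped_fraction)
                  for _ in range(self.n_degradation_loci)]
        return plans


def simulate_genome(spec: FixtureSpec, chrom_name: str = "chr1") -> GenomeSequence:
    """Random genome at the requested GC fraction; deterministic under seed."""
    if spec.genome_length < 1:
        raise ValueError("genome length must be >= 1")
    rng = np.random.default_rng(spec.seed)
    gc = spec.gc_fraction
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    bases = rng.choice(np.array(list("ACGT")), size=spec.genome_length, p=probs)
    genome = GenomeSequence()
    genome.add(chrom_name, "".join(bases))
    return genome


def simulate_methylome(
    genome: GenomeSequence, spec: FixtureSpec, path: str | Path
) -> None:
    """allc-style table over every cytosine site on both strands.

    total_count ~ 1 + Poisson(coverage_mean - 1); mc_count ~
    Binomial(total, mean level of the site's true context class).
    Rows are sorted by chromosome, position, strand.
    """
    rng = np.random.default_rng(spec.seed + 1)
    with open(path, "w") as handle:
        for chrom, pos, strand, ctx in contexts.enumerate_targets(genome, spec.mode):
            mean = spec.context_means.get(ctx.label, 0.05)
            total = 1 + rng.poisson(max(spec.coverage_mean - 1, 0))
            mc = rng.binomial(total, mean)
            mer = (ctx.trinucleotide + "NNN")[:3]
            handle.write(
                f"{chrom}\t{pos + 1}\t{strand}\t{mer}\t{mc}\t{total}\t"
                f"{1 if mc > 0 else 0}\n"
            )


def _random_read_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(np.array(list("ACGT")), size=length))


def simulate_smrna(
    genome: GenomeSequence,
    plans: list[LocusPlan],
    path: str | Path,
    seed: int = 42,
    locus_spacing: int = 500,
    locus_start: int = 200,
) -> None:
    """SAM file with one cluster of reads per plan, well separated.

    Reads are ungapped perfect matches to the genome (CIGAR ``<L>M``),
    jittered a few bases around the locus anchor so they overlap. Unique
    reads carry NH=1 and MAPQ 42; multimapped reads NH=3 and MAPQ 0.
    Output is coordinate sorted with a valid header.
    """
    rng = np.random.default_rng(seed)
    chrom = next(iter(genome))
    needed = locus_start + len(plans) * locus_spacing
    if needed > genome.length(chrom):
        raise ValueError(
            f"locus plan needs {needed} bp but {chrom} is "
            f"{genome.length(chrom)} bp"
        )
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": name, "LN": genome.length(name)} for name in genome],
        }
    )
    reads = []
    for locus_i, plan in enumerate(plans):
        anchor = locus_start + locus_i * locus_spacing
        for read_i in range(plan.n_reads):
            length = int(plan.lengths[0] if len(plan.lengths) == 1
                         else rng.choice(plan.lengths))
            if plan.strands == "both":
                strand = "+" if read_i % 2 == 0 else "-"
            else:
                strand = plan.strands
            start = anchor + int(rng.integers(0, 8))
            seq = genome[chrom][start : start + length]
            multi = bool(rng.random() < plan.multimapped_fraction)
            a = pysam.AlignedSegment(header)
            a.query_name = f"locus{locus_i}_read{read_i}"
            a.reference_id = 0
            a.reference_start = start
            a.cigarstring = f"{length}M"
            a.flag = 16 if strand == "-" else 0
            a.query_sequence = seq if strand == "+" else reverse_complement(seq)
            a.query_qualities = pysam.qualitystring_to_array("I" * length)
            a.mapping_quality = 0 if multi else 42
            a.set_tag("NH", 3 if multi else 1)
            reads.append(a)
    reads.sort(key=lambda a: a.reference_start)
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for a in reads:
            out.write(a)


def simulate_annotations(
    genome: GenomeSequence, spec: FixtureSpec, path: str | Path
) -> None:
    """Non-overlapping gene and transposable_element features as GFF3."""
    rng = np.random.default_rng(spec.seed + 2)
    chrom = next(iter(genome))
    length = genome.length(chrom)
    n_features = spec.n_genes + spec.n_te
    slot = length // max(n_features, 1)
    kinds = ["gene"] * spec.n_genes + ["transposable_element"] * spec.n_te
    rng.shuffle(kinds)
    counters = {"gene": 0, "transposable_element": 0}
    with open(path, "w") as handle:
        handle.write("##gff-version 3\n")
        for i, kind in enumerate(kinds):
            counters[kind] += 1
            slot_start = i * slot
            feat_len = int(rng.integers(max(slot // 4, 2), max(slot // 2, 3)))
            start0 = slot_start + int(rng.integers(0, max(slot - feat_len, 1)))
            strand = "+" if rng.random() < 0.5 else "-"
            prefix = "AT" if kind == "gene" else "TE"
            ident = f"{prefix}{counters[kind]:03d}"
            handle.write(
                "\t".join(
                    [chrom, "epitracks_sim", kind, str(start0 + 1),
                     str(start0 + feat_len), ".", strand, ".", f"ID={ident}"]
                )
                + "\n"
            )


def simulate_all(spec: FixtureSpec, out_dir: str | Path) -> dict[str, Path]:
    """Write genome.fa, anno.gff3, sample.allc.tsv and smrna.sam to *out_dir*."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": out_dir / "genome.fa",
        "annotations": out_dir / "anno.gff3",
        "methylome": out_dir / "sample.allc.tsv",
        "smrna": out_dir / "smrna.sam",
    }
    genome = simulate_genome(spec)
    write_fasta(genome, paths["genome"])
    simulate_annotations(genome, spec, paths["annotations"])
    simulate_methylome(genome, spec, paths["methylome"])
    simulate_smrna(genome, spec.smrna_plans(), paths["smrna"], seed=spec.seed + 3)
    return paths
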