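"""IUPAC motif scanning and sliding-window density tracks.

Sequence motifs (protein-binding sites, chromatin-influencing elements,
recombination-associated repeats) are most usefully viewed as a density
over windows rather than single-base hits. A motif is a string over the
IUPAC degenerate alphabet; a genome substring matches when each of its
bases belongs to the corresponding code's base set. A reference N matches
nothing except an explicit query N. Both strands are scanned: a
minus-strand match is recorded at the plus-strand coordinate where the
substring's reverse complement matches the motif.

Window density is the fraction of possible start positions (both strands
counted separately) that begin a match:

    density = n_match_starts_in_window / (2 * (w - m + 1))

with m the motif length (the smallest motif length for pooled multi-motif
tracks, clamped at 1.0). Overlapping matches all count. Defaults: 500 bp
tiling windows (step = width).
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from ._bedgraph import read_bedgraph, write_bedgraph
from .genome_io import IUPAC_CODES, GenomeSequence, reverse_complement

DEFAULT_WINDOW = 500  # bp
DEFAULT_STEP = 500  # bp (tiling)


@dataclass
class DensityTrack:
    """Per-window motif-match densities in [0,1] for one chromosome."""

    chrom: str
    chrom_length: int
    window: int
    step: int
    motifs: tuple[str, ...]
    densities: list[float] = field(default_factory=list)
    start_offset: int = 0  # first window start (non-zero for clipped tracks)

    def window_start(self, i: int) -> int:
        return self.start_offset + i * self.step

    def clip(self, start: int, end: int) -> "DensityTrack":
        """Sub-track of windows fully inside [start, end)."""
        sub = DensityTrack(self.chrom, self.chrom_length, self.window,
                           self.step, self.motifs)
        for i, density in enumerate(self.densities):
            s = self.window_start(i)
            if s >= start and s + self.window <= end:
                if not sub.densities:
                    sub.start_offset = s
                sub.densities.append(density)
        return sub

    def __len__(self) -> int:
        return len(self.densities)


def iupac_matcher(motif: str):
    """Compile a motif into a position-wise base-set matcher.

    Returns a callable accepting a genome substring of the motif's length.
    Genome N matches only a query N (an ambiguous reference base is never
    assumed to satisfy a concrete query code).
    """
    motif = motif.upper()
    if not motif:
        raise ValueError("motif must be non-empty")
    sets = []
    for i, code in enumerate(motif):
        if code not in IUPAC_CODES:
            raise ValueError(f"invalid IUPAC letter {code!r} at motif position {i}")
        allowed = set(IUPAC_CODES[code])
        if code == "N":
            allowed.add("N")
        sets.append(frozenset(allowed))

    def match(substring: str) -> bool:
        if len(substring) != len(sets):
            return False
        return all(base in allowed for base, allowed in zip(substring, sets))

    match.motif = motif  # type: ignore[attr-defined]
    match.length = len(motif)  # type: ignore[attr-defined]
    return match


def scan_matches(
    genome: GenomeSequence | str, motif: str, chrom: str | None = None
) -> dict[str, tuple[list[int], list[int]]]:
    """All motif match start positions per chromosome, per strand.

    Returns {chrom: (plus_starts, minus_starts)}; minus-strand starts are
    plus-strand coordinates of substrings whose reverse complement matches
    the motif. Lists are sorted and deduplicated within strand.
    """
    if isinstance(genome, str):
        genome_map = {chrom or "seq": genome.upper()}
    else:
        genome_map = genome
    fwd = iupac_matcher(motif)
    rev = iupac_matcher(reverse_complement(motif))
    m = fwd.length
    out: dict[str, tuple[list[int], list[int]]] = {}
    for name, seq in genome_map.items():
        plus, minus = [], []
        for i in range(len(seq) - m + 1):
            sub = seq[i : i + m]
            if fwd(sub):
                plus.append(i)
            # substring's reverse complement matches motif <=> substring
            # matches the motif's reverse complement
            if rev(sub):
                minus.append(i)
        out[name] = (plus, minus)
    return out


def window_density(
    matches: dict[str, tuple[list[int], list[int]]],
    chrom_lengths: dict[str, int],
    window: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
    motifs: Sequence[str] = (),
) -> list[DensityTrack]:
    """Summarize match starts into per-window densities.

    Pooled multi-motif tracks use the smallest motif length in the
    denominator and clamp at 1.0. Windows tile from 0 with the given step;
    a trailing stretch shorter than the window is omitted (window count =
    floor((L - w)/s) + 1 for L >= w).
    """
    if not motifs:
        raise ValueError("at least one motif required")
    if step < 1:
        raise ValueError("step must be >= 1")
    m_min = min(len(m) for m in motifs)
    if window < max(len(m) for m in motifs):
        raise ValueError(
            f"window {window} smaller than longest motif "
            f"({max(len(m) for m in motifs)} bp)"
        )
    starts_per_window = window - m_min + 1
    tracks = []
    for chrom, length in chrom_lengths.items():
        plus, minus = matches.get(chrom, ([], []))
        plus, minus = sorted(plus), sorted(minus)  # strands counted separately
        track = DensityTrack(chrom, length, window, step, tuple(motifs))
        if length >= window:
            n_windows = (length - window) // step + 1
            for w_i in range(n_windows):
                win_start = w_i * step
                win_stop = win_start + starts_per_window  # exclusive start bound
                n = sum(
                    bisect_left(starts, win_stop) - bisect_left(starts, win_start)
                    for starts in (plus, minus)
                )
                track.densities.append(min(n / (2 * starts_per_window), 1.0))
        tracks.append(track)
    return tracks


def density_tracks(
    genome: GenomeSequence,
    motifs: Sequence[str],
    window: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
) -> list[DensityTrack]:
    """Scan *motifs* over *genome* and pool them into one density track set."""
    pooled: dict[str, tuple[list[int], list[int]]] = {
        chrom: ([], []) for chrom in genome
    }
    for motif in motifs:
        for chrom, (plus, minus) in scan_matches(genome, motif).items():
            pooled[chrom][0].extend(plus)
            pooled[chrom][1].extend(minus)
    lengths = {chrom: genome.length(chrom) for chrom in genome}
    return window_density(pooled, lengths, window, step, motifs)


def write_density(tracks: Sequence[DensityTrack], path: str | Path) -> None:
    """bedGraph rows, one per window: (start0, start0 + w, density)."""
    rows = []
    for track in tracks:
        for i, density in enumerate(track.densities):
            start = track.window_start(i)
            rows.append((track.chrom, start, start + track.window, density))
    write_bedgraph(rows, path)


def read_density(
    path: str | Path, window: int, step: int, motifs: Sequence[str] = ()
) -> list[DensityTrack]:
    """Inverse of :func:`write_density` for tiling or overlap-free tracks."""
    by_chrom: dict[str, list[tuple[int, float]]] = {}
    for chrom, start, end, value in read_bedgraph(path, allow_overlap=step < window):
        if end - start != window:
            raise ValueError(f"{path}: interval {start}-{end} is not window-sized")
        by_chrom.setdefault(chrom, []).append((start, value))
    tracks = []
    for chrom, rows in by_chrom.items():
        rows.sort()
        length = rows[-1][0] + window if rows else window
        track = DensityTrack(chrom, length, window, step, tuple(motifs))
        track.densities = [v for _, v in rows]
        tracks.append(track)
    return tracks
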