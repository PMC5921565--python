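"""Minimal bedGraph text I/O shared by the track modules.

bedGraph is the text precursor of BigWig: 0-based half-open intervals with
one numeric value each. Values are written with ``repr`` so that floats
round-trip bit-exactly through write -> read.
"""

from __future__ import annotations

from pathlib import Path


def format_value(value: float) -> str:
    if float(value) == int(value):
        return str(int(value))
    return repr(float(value))


def write_bedgraph(
    intervals, path: str | Path, track_name: str | None = None
) -> None:
    """Write (chrom, start0, end, value) rows; caller supplies sorted input."""
    with open(path, "w") as handle:
        if track_name:
            handle.write(f'track type=bedGraph name="{track_name}"\n')
        for chrom, start, end, value in intervals:
            handle.write(f"{chrom}\t{start}\t{end}\t{format_value(value)}\n")


def read_bedgraph(
    path: str | Path, allow_overlap: bool = False
) -> list[tuple[str, int, int, float]]:
    """Read bedGraph rows; overlapping intervals on a chromosome are an error.

    ``allow_overlap=True`` disables the check for signed stranded-coverage
    files, where opposite-sign rows legitimately share coordinates.
    """
    rows: list[tuple[str, int, int, float]] = []
    last_end: dict[str, int] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns, got {len(fields)}")
            chrom, start, end, value = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
            if not allow_overlap and start < last_end.get(chrom, 0):
                raise ValueError(
                    f"{path}:{lineno}: overlapping or unsorted interval on {chrom}"
                )
            last_end[chrom] = max(last_end.get(chrom, 0), end)
            rows.append((chrom, start, end, value))
    return rows


def write_bigwig(
    intervals, chrom_sizes: dict[str, int], path: str | Path
) -> None:
    """Optional BigWig emission (the browser container; bedGraph stays canonical)."""
    import pyBigWig

    bw = pyBigWig.open(str(path), "w")
    try:
        bw.addHeader(list(chrom_sizes.items()))
        by_chrom: dict[str, list] = {}
        for chrom, start, end, value in intervals:
            by_chrom.setdefault(chrom, []).append((start, end, float(value)))
        for chrom in chrom_sizes:
            rows = sorted(by_chrom.get(chrom, []))
            if rows:
                bw.addEntries(
                    [chrom] * len(rows),
                    [r[0] for r in rows],
                    ends=[r[1] for r in rows],
                    values=[r[2] for r in rows],
                )
    finally:
        bw.close()
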