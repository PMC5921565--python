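"""Static multi-track figures of a genomic region, SVG-first.

The renderer composes an ordered stack of tracks (annotations, strand-signed
base-modification levels, small-RNA read layouts, stranded coverage, motif
density heatmaps) over one region into a publication-quality vector figure.
Every data item becomes exactly one glyph, so tests can parse the SVG and
count elements. Conventions mirror the browser-track semantics:

* signed tracks (methylation, coverage) draw bars up for + strand, down
  for -; the y-range is symmetric about the axis when auto-scaled;
* small-RNA reads are boxes at their packed row (above/below the origin by
  strand), colored by read length, filled when uniquely mapped and
  outline-only when multimapped;
* motif density windows are rectangles whose fill darkens with density;
* gene models render gold, transposable elements purple.

PNG export replays the same draw list through matplotlib, so vector and
raster output contain identical glyph sets.
"""

from __future__ import annotations

import tomllib
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Sequence

from .coverage import StrandedCoverage
from .genome_io import Annotation, Region
from .methylation import SignedLevelTrack
from .motif_density import DensityTrack
from .smrna import SmRNARead, layout_reads

TRACK_KINDS = ("annotation", "methylation", "smrna", "coverage", "density")

#: SVG class names for countable data glyphs, per track kind
DATA_GLYPH_CLASS = {
    "annotation": "feature",
    "methylation": "bar",
    "smrna": "read",
    "coverage": "covbar",
    "density": "window",
}

_PALETTES: dict[str, Any] | None = None


def _load_palettes() -> dict[str, Any]:
    global _PALETTES
    if _PALETTES is None:
        data = resources.files("epitracks").joinpath("palettes.toml").read_bytes()
        _PALETTES = tomllib.loads(data.decode())
    return _PALETTES


def palette(kind: str) -> dict[str, str]:
    """Role -> color mapping for a track kind; stable across runs.

    ``smrna`` maps each read length in the default 18-30 nt range to its
    own color (plus ``other`` for lengths outside the range); ``density``
    returns the two ends of the heat ramp.
    """
    palettes = _load_palettes()
    if kind not in palettes:
        raise ValueError(f"no palette for track kind {kind!r}")
    entry = palettes[kind]
    if kind == "smrna":
        lengths = entry["lengths"]
        mapping = {
            str(n): lengths[i]
            for i, n in enumerate(range(entry["min_length"], entry["max_length"] + 1))
        }
        mapping["other"] = entry["other_length"]
        return mapping
    return dict(entry)


def _lerp_color(low: str, high: str, t: float) -> str:
    """Linear hex-color interpolation; t=1 is the dark (high-density) end."""
    t = min(max(t, 0.0), 1.0)
    lo = [int(low[i : i + 2], 16) for i in (1, 3, 5)]
    hi = [int(high[i : i + 2], 16) for i in (1, 3, 5)]
    rgb = [round(a + (b - a) * t) for a, b in zip(lo, hi)]
    return "#{:02X}{:02X}{:02X}".format(*rgb)


def density_color(density: float, pal: dict[str, str] | None = None) -> str:
    pal = pal or palette("density")
    return _lerp_color(pal["low"], pal["high"], density)


@dataclass
class TrackStyle:
    kind: str
    label: str = ""
    height: int = 80  # px
    y_range: tuple[float, float] | None = None  # None = auto (symmetric if signed)
    palette: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if self.kind not in TRACK_KINDS:
            raise ValueError(f"unknown track kind {self.kind!r}")

    def colors(self) -> dict[str, str]:
        return self.palette or palette(self.kind)


@dataclass
class FigureLayout:
    region: Region
    tracks: list[tuple[Any, TrackStyle]]
    width: int = 1000  # px
    track_gap: int = 12  # px

    def __post_init__(self) -> None:
        if not self.tracks:
            raise ValueError("figure needs at least one track")


@dataclass
class Glyph:
    """One drawable rectangle in figure pixel coordinates."""

    cls: str  # SVG class; data glyphs use DATA_GLYPH_CLASS values
    x: float
    y: float
    width: float
    height: float
    fill: str
    stroke: str = "none"


@dataclass
class RenderResult:
    path: Path
    glyphs: list[Glyph]
    fmt: str

    def data_glyph_count(self, cls: str) -> int:
        return sum(1 for g in self.glyphs if g.cls == cls)


def _x(layout: FigureLayout, pos: int | float) -> float:
    span = len(layout.region)
    return (pos - layout.region.start) / span * layout.width


def _check_within(region: Region, item_region: Region, what: str) -> None:
    if not region.contains(item_region):
        raise ValueError(f"{what} {item_region} outside figure region {region}")


def _draw_annotation(
    data: Sequence[Annotation], style: TrackStyle, layout: FigureLayout, y0: float
) -> list[Glyph]:
    colors = style.colors()
    glyphs = []
    mid = y0 + style.height / 2
    for anno in data:
        _check_within(layout.region, anno.region, f"annotation {anno.identifier}")
        x = _x(layout, anno.region.start)
        w = _x(layout, anno.region.end) - x
        glyphs.append(
            Glyph("feature", x, mid - 4, w, 8, colors[anno.feature_kind])
        )
        for child in anno.children:
            cx = _x(layout, child.start)
            glyphs.append(
                Glyph(
                    "exon", cx, mid - 8, _x(layout, child.end) - cx, 16,
                    colors[anno.feature_kind],
                )
            )
    return glyphs


def _signed_axis(style: TrackStyle, y0: float, max_abs: float):
    if style.y_range is not None:
        lo, hi = style.y_range
    else:
        hi = max_abs if max_abs > 0 else 1.0
        lo = -hi  # auto range symmetric about 0 for signed data
    axis_y = y0 + style.height * hi / (hi - lo)
    scale = style.height / (hi - lo)  # px per data unit
    return axis_y, scale


def _draw_methylation(
    data: Sequence[SignedLevelTrack] | SignedLevelTrack,
    style: TrackStyle,
    layout: FigureLayout,
    y0: float,
) -> list[Glyph]:
    tracks = [data] if isinstance(data, SignedLevelTrack) else list(data)
    colors = style.colors()
    max_abs = 1.0  # methylation levels live in [-1, 1]
    axis_y, scale = _signed_axis(style, y0, max_abs)
    base_w = max(layout.width / len(layout.region), 1.0)
    glyphs = []
    for track in tracks:
        color = colors.get(track.context_class, colors.get(track.mod, "#999999"))
        for chrom, pos, _strand, level in track.sites:
            _check_within(layout.region, Region(chrom, pos, pos + 1), "methylation site")
            x = _x(layout, pos)
            h = abs(level) * scale
            y = axis_y - h if level >= 0 else axis_y
            glyphs.append(Glyph("bar", x, y, base_w, h, color))
    glyphs.append(Glyph("axis", 0, axis_y - 0.5, layout.width, 1, "#000000"))
    return glyphs


def _draw_smrna(
    data: Sequence[SmRNARead], style: TrackStyle, layout: FigureLayout, y0: float
) -> list[Glyph]:
    colors = style.colors()
    placements = layout_reads(data)
    for read, _ in placements:
        _check_within(layout.region, read.region, "smRNA read")
    max_row = max((abs(row) for _, row in placements), default=1)
    row_h = style.height / (2 * max_row + 1)
    axis_y = y0 + style.height / 2
    glyphs = []
    for read, row in placements:
        x = _x(layout, read.region.start)
        w = _x(layout, read.region.end) - x
        y = axis_y - row * row_h if row > 0 else axis_y - (row + 1) * row_h
        color = colors.get(str(read.length), colors["other"])
        if read.multimapped:
            # unfilled: read maps to multiple genomic locations
            glyphs.append(Glyph("read", x, y, w, row_h * 0.8, "none", stroke=color))
        else:
            glyphs.append(Glyph("read", x, y, w, row_h * 0.8, color))
    glyphs.append(Glyph("axis", 0, axis_y - 0.5, layout.width, 1, "#000000"))
    return glyphs


def _draw_coverage(
    data: StrandedCoverage, style: TrackStyle, layout: FigureLayout, y0: float
) -> list[Glyph]:
    _check_within(layout.region, data.region, "coverage block")
    colors = style.colors()
    max_abs = float(max(data.plus.max(initial=0), data.minus.max(initial=0)))
    axis_y, scale = _signed_axis(style, y0, max_abs)
    base_w = max(layout.width / len(layout.region), 1.0)
    glyphs = []
    for i in range(len(data.region)):
        pos = data.region.start + i
        x = _x(layout, pos)
        if data.plus[i] > 0:
            h = data.plus[i] * scale
            glyphs.append(Glyph("covbar", x, axis_y - h, base_w, h, colors["plus"]))
        if data.minus[i] > 0:
            h = data.minus[i] * scale
            glyphs.append(Glyph("covbar", x, axis_y, base_w, h, colors["minus"]))
    glyphs.append(Glyph("axis", 0, axis_y - 0.5, layout.width, 1, "#000000"))
    return glyphs


def _draw_density(
    data: Sequence[DensityTrack] | DensityTrack,
    style: TrackStyle,
    layout: FigureLayout,
    y0: float,
) -> list[Glyph]:
    tracks = [data] if isinstance(data, DensityTrack) else list(data)
    colors = style.colors()
    glyphs = []
    for track in tracks:
        for i, density in enumerate(track.densities):
            start = track.window_start(i)
            win = Region(track.chrom, start, start + track.window)
            _check_within(layout.region, win, "density window")
            x = _x(layout, start)
            w = _x(layout, start + track.window) - x
            fill = _lerp_color(colors["low"], colors["high"], density)
            glyphs.append(Glyph("window", x, y0, w, style.height, fill))
    return glyphs


_DRAWERS = {
    "annotation": _draw_annotation,
    "methylation": _draw_methylation,
    "smrna": _draw_smrna,
    "coverage": _draw_coverage,
    "density": _draw_density,
}


def build_glyphs(layout: FigureLayout) -> list[Glyph]:
    """Compose the full draw list for a layout (shared by SVG and PNG)."""
    glyphs: list[Glyph] = []
    y = 0.0
    for data, style in layout.tracks:
        glyphs.extend(_DRAWERS[style.kind](data, style, layout, y))
        y += style.height + layout.track_gap
    return glyphs


def figure_height(layout: FigureLayout) -> float:
    heights = [style.height for _, style in layout.tracks]
    return sum(heights) + layout.track_gap * (len(heights) - 1)


def _write_svg(layout: FigureLayout, glyphs: list[Glyph], path: Path) -> None:
    height = figure_height(layout)
    svg = ET.Element(
        "svg",
        xmlns="http://www.w3.org/2000/svg",
        width=str(layout.width),
        height=f"{height:g}",
        viewBox=f"0 0 {layout.width} {height:g}",
        version="1.1",
    )
    r = layout.region
    ET.SubElement(svg, "title").text = f"{r.chrom}:{r.start + 1}-{r.end}"
    for g in glyphs:
        attrs = {
            "class": g.cls,
            "x": f"{g.x:g}",
            "y": f"{g.y:g}",
            "width": f"{max(g.width, 0.1):g}",
            "height": f"{max(g.height, 0.0):g}",
            "fill": g.fill,
        }
        if g.stroke != "none":
            attrs["stroke"] = g.stroke
            attrs["stroke-width"] = "1"
        ET.SubElement(svg, "rect", attrs)
    ET.ElementTree(svg).write(path, xml_declaration=True, encoding="unicode")


def _write_png(layout: FigureLayout, glyphs: list[Glyph], path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Rectangle

    height = figure_height(layout)
    fig, ax = plt.subplots(figsize=(layout.width / 100, height / 100), dpi=100)
    ax.set_xlim(0, layout.width)
    ax.set_ylim(height, 0)  # image coordinates: y grows downward
    ax.axis("off")
    for g in glyphs:
        ax.add_patch(
            Rectangle(
                (g.x, g.y), max(g.width, 0.1), g.height,
                facecolor=g.fill if g.fill != "none" else "none",
                edgecolor=g.stroke if g.stroke != "none" else "none",
            )
        )
    fig.savefig(path, dpi=100)
    plt.close(fig)


def render_figure(layout: FigureLayout, path: str | Path) -> RenderResult:
    """Render a track stack to SVG (vector, primary) or PNG (raster replay).

    The format follows the file suffix. Returns the draw list alongside the
    path so callers (and tests) can audit glyph counts without parsing
    pixels.
    """
    path = Path(path)
    glyphs = build_glyphs(layout)
    fmt = path.suffix.lower().lstrip(".") or "svg"
    if fmt == "svg":
        _write_svg(layout, glyphs, path)
    elif fmt == "png":
        _write_png(layout, glyphs, path)
    else:
        raise ValueError(f"unsupported output format {fmt!r} (use svg or png)")
    return RenderResult(path, glyphs, fmt)
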