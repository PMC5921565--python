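import xml.etree.ElementTree as ET

import numpy as np
import pytest

from epitracks import render
from epitracks.coverage import StrandedCoverage
from epitracks.genome_io import Annotation, Region
from epitracks.methylation import SignedLevelTrack
from epitracks.motif_density import DensityTrack
from epitracks.smrna import SmRNARead

SVG_NS = "{http://www.w3.org/2000/svg}"


def svg_rects(path, cls=None):
    root = ET.parse(path).getroot()
    rects = root.findall(f"{SVG_NS}rect")
    if cls is not None:
        rects = [r for r in rects if r.get("class") == cls]
    return rects


def meth_track(sites):
    track = SignedLevelTrack("CG", "5mC")
    for pos, strand, level in sites:
        track.add("chr1", pos, strand, level)
    return track


def smrna_read(start, length=21, strand="+", multimapped=False):
    return SmRNARead(Region("chr1", start, start + length, strand), strand,
                     length, multimapped, 42)


REGION = Region("chr1", 0, 1000)


class TestRenderFigure:
    def test_svg_is_valid_xml_with_one_bar_per_site(self, tmp_path):
        track = meth_track([(10, "+", 0.5), (20, "-", 0.25), (30, "+", 1.0)])
        layout = render.FigureLayout(
            REGION, [(track, render.TrackStyle("methylation"))]
        )
        out = tmp_path / "fig.svg"
        result = render.render_figure(layout, out)
        assert len(svg_rects(out, "bar")) == 3
        assert result.data_glyph_count("bar") == 3

    def test_minus_strand_renders_below_axis(self, tmp_path):
        track = meth_track([(10, "+", 0.5), (20, "-", 0.5)])
        layout = render.FigureLayout(
            REGION, [(track, render.TrackStyle("methylation"))]
        )
        out = tmp_path / "fig.svg"
        render.render_figure(layout, out)
        (axis,) = svg_rects(out, "axis")
        axis_y = float(axis.get("y"))
        bars = svg_rects(out, "bar")
        ys = sorted(float(b.get("y")) for b in bars)
        assert ys[0] < axis_y < ys[1]  # one bar above, one below (image coords)

    def test_multimapped_read_is_unfilled(self, tmp_path):
        reads = [smrna_read(10, multimapped=True), smrna_read(100)]
        layout = render.FigureLayout(REGION, [(reads, render.TrackStyle("smrna"))])
        out = tmp_path / "fig.svg"
        render.render_figure(layout, out)
        fills = {r.get("fill"): r for r in svg_rects(out, "read")}
        assert "none" in fills  # outline-only multimapped glyph
        assert fills["none"].get("stroke") not in (None, "none")
        assert sum(1 for f in fills if f != "none") == 1

    def test_density_extremes_use_ramp_ends_darker_high(self, tmp_path):
        track = DensityTrack("chr1", 1000, 500, 500, ("CG",), [0.0, 1.0])
        layout = render.FigureLayout(REGION, [(track, render.TrackStyle("density"))])
        out = tmp_path / "fig.svg"
        render.render_figure(layout, out)
        windows = svg_rects(out, "window")
        pal = render.palette("density")
        fills = [w.get("fill") for w in windows]
        assert fills == [pal["low"].upper(), pal["high"].upper()]

        def luminance(hexcolor):
            return sum(int(hexcolor[i : i + 2], 16) for i in (1, 3, 5))

        assert luminance(fills[1]) < luminance(fills[0])  # high density darker

    def test_annotation_colors_by_kind(self, tmp_path):
        annos = [
            Annotation(Region("chr1", 10, 200, "+"), "gene", "g1"),
            Annotation(Region("chr1", 300, 500, "-"), "transposable_element", "te1"),
        ]
        layout = render.FigureLayout(REGION, [(annos, render.TrackStyle("annotation"))])
        out = tmp_path / "fig.svg"
        render.render_figure(layout, out)
        pal = render.palette("annotation")
        fills = [r.get("fill") for r in svg_rects(out, "feature")]
        assert fills == [pal["gene"], pal["transposable_element"]]

    def test_data_outside_region_is_an_error(self, tmp_path):
        track = meth_track([(5000, "+", 0.5)])
        layout = render.FigureLayout(REGION, [(track, render.TrackStyle("methylation"))])
        with pytest.raises(ValueError, match="outside"):
            render.render_figure(layout, tmp_path / "fig.svg")

    def test_empty_track_stack_rejected(self):
        with pytest.raises(ValueError, match="at least one track"):
            render.FigureLayout(REGION, [])

    def test_png_and_svg_share_glyph_counts(self, tmp_path):
        reads = [smrna_read(i * 40, 18 + i % 13, "+" if i % 2 else "-")
                 for i in range(12)]
        cov = StrandedCoverage(
            Region("chr1", 0, 50), np.arange(50) % 3, np.ones(50, dtype=int)
        )
        layout = render.FigureLayout(
            REGION,
            [
                (reads, render.TrackStyle("smrna")),
                (cov, render.TrackStyle("coverage")),
            ],
        )
        svg_result = render.render_figure(layout, tmp_path / "fig.svg")
        png_result = render.render_figure(layout, tmp_path / "fig.png")
        assert (tmp_path / "fig.png").stat().st_size > 0
        for cls in ("read", "covbar"):
            assert svg_result.data_glyph_count(cls) == png_result.data_glyph_count(cls)
        assert svg_result.data_glyph_count("read") == len(
            svg_rects(tmp_path / "fig.svg", "read")
        )

    def test_stacked_tracks_do_not_share_vertical_space(self, tmp_path):
        track = meth_track([(10, "+", 1.0)])
        annos = [Annotation(Region("chr1", 10, 200, "+"), "gene", "g1")]
        layout = render.FigureLayout(
            REGION,
            [
                (annos, render.TrackStyle("annotation", height=40)),
                (track, render.TrackStyle("methylation", height=80)),
            ],
        )
        render.render_figure(layout, tmp_path / "fig.svg")
        feature = svg_rects(tmp_path / "fig.svg", "feature")[0]
        bar = svg_rects(tmp_path / "fig.svg", "bar")[0]
        assert float(feature.get("y")) + float(feature.get("height")) <= float(
            bar.get("y")
        ) + 1e-6


class TestPalette:
    def test_plant_contexts_and_extra_mods_distinct(self):
        pal = render.palette("methylation")
        contexts = [pal["CG"], pal["CHG"], pal["CHH"]]
        mods = [pal["4mC"], pal["5hmC"], pal["6mA"]]
        assert len(set(contexts)) == 3
        assert len(set(contexts + mods)) == 6

    def test_smrna_palette_has_13_distinct_length_colors(self):
        pal = render.palette("smrna")
        lengths = [pal[str(n)] for n in range(18, 31)]
        assert len(lengths) == 13
        assert len(set(lengths)) == 13

    def test_palette_stable_across_calls(self):
        for kind in ("annotation", "methylation", "smrna", "coverage", "density"):
            assert render.palette(kind) == render.palette(kind)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="no palette"):
            render.palette("histogram")
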