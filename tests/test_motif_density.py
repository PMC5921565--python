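import numpy as np
import pytest

from epitracks import motif_density as md
from epitracks.genome_io import IUPAC_CODES, GenomeSequence, reverse_complement


def naive_scan(seq: str, motif: str):
    """Independent all-positions matcher used as the scanning oracle."""

    def char_match(qcode: str, gbase: str) -> bool:
        if gbase == "N":
            return qcode == "N"
        return gbase in IUPAC_CODES[qcode]

    def matches_at(s: str, i: int, m: str) -> bool:
        return all(char_match(q, s[i + j]) for j, q in enumerate(m))

    mlen = len(motif)
    plus, minus = [], []
    for i in range(len(seq) - mlen + 1):
        if matches_at(seq, i, motif):
            plus.append(i)
        rc = reverse_complement(seq[i : i + mlen])
        if matches_at(rc, 0, motif):
            minus.append(i)
    return plus, minus


class TestIupacMatcher:
    def test_concrete_motif_matches_itself_only(self):
        match = md.iupac_matcher("CG")
        assert match("CG")
        assert not any(match(a + b) for a in "ACGT" for b in "ACGT" if a + b != "CG")

    def test_degenerate_expansion_count(self):
        match = md.iupac_matcher("CHH")
        accepted = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
                    if match(a + b + c)]
        assert len(accepted) == 9  # |H| squared

    def test_query_n_vs_reference_n(self):
        n_query = md.iupac_matcher("N")
        assert all(n_query(b) for b in "ACGTN")
        concrete = md.iupac_matcher("A")
        assert not concrete("N")  # reference N satisfies no concrete code
        degenerate = md.iupac_matcher("H")
        assert not degenerate("N")

    def test_invalid_letter_named(self):
        with pytest.raises(ValueError, match="'X'"):
            md.iupac_matcher("ACXG")


class TestScanMatches:
    def test_cg_tandem_repeat(self):
        plus, minus = md.scan_matches("CGCGCGCGCG", "CG")["seq"]
        assert plus == [0, 2, 4, 6, 8]
        assert minus == [0, 2, 4, 6, 8]  # CG is palindromic

    def test_no_matches(self):
        plus, minus = md.scan_matches("AAAA", "CG")["seq"]
        assert plus == [] and minus == []

    def test_motif_longer_than_sequence(self):
        plus, minus = md.scan_matches("AC", "ACGT")["seq"]
        assert plus == [] and minus == []

    def test_minus_strand_coordinates(self):
        # CAT at 0; its reverse complement ATG appears nowhere forward
        plus, minus = md.scan_matches("CATAA", "CAT")["seq"]
        assert plus == [0]
        rc_plus, rc_minus = md.scan_matches("CATAA", "ATG")["seq"]
        assert rc_plus == [] and rc_minus == [0]

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_equal_naive_oracle_on_random_genomes(self, seed):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGTN"), size=500,
                                 p=[0.24, 0.24, 0.24, 0.24, 0.04]))
        codes = sorted(IUPAC_CODES)
        for _ in range(10):  # 5 seeds x 10 motifs = 50 random motifs
            m = int(rng.integers(1, 7))
            motif = "".join(rng.choice(codes, size=m))
            plus, minus = md.scan_matches(seq, motif)["seq"]
            assert (plus, minus) == naive_scan(seq, motif), motif

    def test_palindromic_motif_strand_symmetry(self):
        rng = np.random.default_rng(1)
        seq = "".join(rng.choice(list("ACGT"), size=400))
        for motif in ["CG", "GC", "ACGT", "CATG", "RY"]:
            assert reverse_complement(motif) == motif or motif in ("RY",)
            plus, minus = md.scan_matches(seq, motif)["seq"]
            if reverse_complement(motif) == motif:
                assert plus == minus


class TestWindowDensity:
    def test_documented_cg_density(self):
        genome = GenomeSequence()
        genome.add("chr1", "CGCGCGCGCG")
        (track,) = md.density_tracks(genome, ["CG"], window=10, step=10)
        assert track.densities == [pytest.approx(10 / 18)]

    def test_n_motif_saturates_after_clamp(self):
        genome = GenomeSequence()
        genome.add("chr1", "ACGTACGTACGT")
        (track,) = md.density_tracks(genome, ["N"], window=12, step=12)
        assert track.densities == [1.0]

    def test_empty_window_is_zero(self):
        genome = GenomeSequence()
        genome.add("chr1", "A" * 20)
        (track,) = md.density_tracks(genome, ["CG"], window=10, step=10)
        assert track.densities == [0.0, 0.0]

    def test_window_count_formula_and_partial_window_omitted(self):
        genome = GenomeSequence()
        genome.add("chr1", "ACGT" * 30)  # 120 bp
        for w, s in [(50, 50), (50, 25), (120, 120), (121, 121)]:
            if w > 120:
                (track,) = md.density_tracks(genome, ["CG"], window=w, step=s)
                assert len(track) == 0
            else:
                (track,) = md.density_tracks(genome, ["CG"], window=w, step=s)
                assert len(track) == (120 - w) // s + 1

    def test_window_smaller_than_motif_rejected(self):
        genome = GenomeSequence()
        genome.add("chr1", "ACGT" * 10)
        with pytest.raises(ValueError, match="smaller than"):
            md.density_tracks(genome, ["ACGTACGT"], window=4)

    def test_densities_bounded_and_monotone_in_matches(self):
        rng = np.random.default_rng(2)
        seq = "".join(rng.choice(list("ACGT"), size=2000))
        genome = GenomeSequence()
        genome.add("chr1", seq)
        (track,) = md.density_tracks(genome, ["CG"], window=200, step=200)
        assert all(0.0 <= d <= 1.0 for d in track.densities)
        # recompute counts independently; density must order like counts
        plus, minus = md.scan_matches(seq, "CG")["seq"]
        counts = []
        for i in range(len(track)):
            lo, hi = i * 200, i * 200 + 199
            counts.append(sum(lo <= p < hi for p in plus)
                          + sum(lo <= p < hi for p in minus))
        order = np.argsort(counts)
        assert all(
            track.densities[a] <= track.densities[b]
            for a, b in zip(order, order[1:])
        )

    def test_multi_motif_pooling_uses_min_length_denominator(self):
        genome = GenomeSequence()
        genome.add("chr1", "CGCGCGCGCG")
        (single,) = md.density_tracks(genome, ["CG"], window=10, step=10)
        (pooled,) = md.density_tracks(genome, ["CG", "CGCG"], window=10, step=10)
        # pooled adds CGCG matches (4+4 starts) on the same denominator 2*9
        assert pooled.densities[0] == pytest.approx((10 + 8) / 18)
        assert pooled.densities[0] > single.densities[0]


class TestDensityIO:
    def test_round_trip(self, tmp_path):
        genome = GenomeSequence()
        rng = np.random.default_rng(4)
        genome.add("chr1", "".join(rng.choice(list("ACGT"), size=600)))
        tracks = md.density_tracks(genome, ["CWG"], window=100, step=100)
        path = tmp_path / "d.bedgraph"
        md.write_density(tracks, path)
        again = md.read_density(path, window=100, step=100, motifs=("CWG",))
        assert [t.densities for t in again] == [t.densities for t in tracks]

    def test_rows_tile_per_step(self, tmp_path):
        genome = GenomeSequence()
        genome.add("chr1", "ACGT" * 100)
        tracks = md.density_tracks(genome, ["CG"], window=100, step=100)
        path = tmp_path / "d.bedgraph"
        md.write_density(tracks, path)
        rows = [line.split("\t") for line in path.read_text().splitlines()]
        starts = [int(r[1]) for r in rows]
        assert starts == [0, 100, 200, 300]
        assert all(int(r[2]) - int(r[1]) == 100 for r in rows)
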