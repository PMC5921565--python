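# Methods

## Coordinate model

All internal coordinates are 0-based half-open; strand is `+`, `-` or `.`.
Conversion happens only at format boundaries: GFF3 and allc tables are
1-based inclusive on disk, bedGraph is 0-based half-open, and region
strings on the command line (`chr1:1-6000`) follow the browser's 1-based
inclusive convention. Keeping one internal convention removes a whole class
of off-by-one errors that arise when formats with different conventions are
mixed ad hoc.

Genome sequences are restricted to {A, C, G, T, N}. Degenerate IUPAC codes
are accepted only in motif queries: context classification is undefined on
an ambiguous reference base, so a genome containing, say, R is rejected at
load time rather than silently misclassified later.

## Sequence-context classification

A cytosine's context is the strand-local trinucleotide starting at the
site, read 5'→3' on its own strand (the reverse complement for
minus-strand sites). Classification:

* second base G → **CG** (both modes);
* otherwise, plant mode: third base G → **CHG**, else **CHH**;
* otherwise, animal mode: **CH**;

with H = {A, C, T}. Two deliberately conservative rules:

* **N anywhere in the 3-mer → `unknown`**, even when the class would be
  decidable from the first two bases (e.g. `CGN`). N is a gap in knowledge,
  not a nucleotide, and is never treated as H.
* **Chromosome ends**: a site with fewer than two downstream bases →
  `unknown`. Excluding end sites avoids fabricating context where the
  sequence runs out; they are still enumerated and can still carry calls,
  they just land in the `unknown` track.

6mA sits on adenines and is reported as a single class `A` without
sub-contexts; modification type (4mC / 5mC / 5hmC / 6mA) is carried
alongside the context so tracks stay separated per modification.

## Strand-signed methylation tracks

The level at a site is `mc_count / total_count ∈ [0, 1]`, written signed by
strand (`+` positive, `−` negative) as single-base bedGraph intervals. A
minus-strand cytosine occupies the coordinate of its complementary G, so
the two sites of a palindromic CG dinucleotide never collide at one
position and a single file holds both strands losslessly.

Parameters: `min_coverage` (default **1** — no coverage floor is imposed
unless asked for; any covered site is reported); context and modification
filters (subset of the mode's classes); opt-in `--validate` recomputes each
record's 3-mer against a supplied genome, off by default because allc files
often come from a genome build the user does not have at hand.

Text bedGraph is the canonical, bit-exact-testable output; BigWig (the
browser container) is an optional post-step (`--bigwig`) via pyBigWig.
Values are serialized with `repr` so write→read round-trips are exact.

## Stranded coverage

Coverage walks the CIGAR explicitly: M/=/X bases increment the strand's
counter, D and N consume reference silently, I/S/H/P consume none.
Secondary and supplementary alignments are excluded; duplicates count
(the browser default); read strand comes from the flag, with no
library-type (mate-orientation) inference — the motivating assays are
single-end and strand-direct. The unstranded track is defined as
`plus + minus` and tested as that identity.

The default signed output writes plus runs positive and minus runs negative
in one file; rows of opposite sign may overlap (a deliberate relaxation of
bedGraph for this file type, matching the single-track display). `--split`
writes two strictly standard files instead.

## Small-RNA classification

Read length is the **query** length — the sequenced molecule — not the
reference span, so a rare indel does not shift a 21 nt read out of its size
class. Uniqueness: NH > 1 when the tag is present, else MAPQ == 0 (the
common aligner convention for multi-placed reads). Filter defaults:
18–30 nt, both strands, MAPQ ≥ 0, multimapped included.

Loci are single-linkage clusters of read spans with inter-span gap
≤ `max_gap` (default **50 bp**, a compromise between splitting one
transcript's ragged ends and merging neighbouring loci). Typing uses two
explicit thresholds on locus composition:

* size-uniform: modal length fraction ≥ **0.8**;
* both-strand: minor strand fraction ≥ **0.2**;
* ≥ **5** reads required for any non-ambiguous call.

Rules: uniform 21 nt, single-strand → `miRNA_like`; uniform 24 nt,
both-strand → `siRNA_like`; non-uniform single-strand →
`degradation_like`; everything else `ambiguous`. The size/strand rules are
the canonical plant small-RNA signatures; the numeric thresholds are this
package's own operationalization (the underlying biology is qualitative)
and are all parameters.

Track layout packs reads greedily into rows: plus reads rows +1, +2, …,
minus reads −1, −2, …, each read taking the first row where it overlaps
nothing. Row sign therefore always encodes strand.

## Motif density

A motif is matched position-wise by IUPAC base sets; a reference N matches
only an explicit query N (an unknown base is never assumed to satisfy a
concrete code). Minus-strand matches are found by scanning the forward
sequence with the reverse-complemented motif, which is equivalent to
matching the motif against the reverse complement of each substring, and
are reported at plus-strand start coordinates.

Window density = match starts (both strands of all motifs in the track) /
`2 · (w − m + 1)` possible starts, clamped to [0, 1]. For pooled
multi-motif tracks the smallest motif length sets the denominator — the
count of "possible starts" is then an upper bound for longer motifs, hence
the clamp. Overlapping matches all count; there is no greedy consumption.
Defaults: window **500 bp**, step = window (tiling), a trailing partial
window is omitted (window count = ⌊(L − w)/s⌋ + 1). The normalization and
defaults are documented package choices rather than a reproduction of any
external tool's formula.

## Rendering

The draw list is the unit of truth: every data item becomes exactly one
rectangle glyph with an SVG class (`bar`, `read`, `covbar`, `window`,
`feature`), so tests parse the SVG and count elements instead of comparing
pixels. PNG export replays the identical draw list through matplotlib.
Signed tracks auto-scale symmetrically about the axis; minus-strand glyphs
always sit below it. Multimapped reads render outline-only; density windows
interpolate linearly between the ramp ends (darker = denser). Default
colors are an Okabe–Ito-style colorblind-safe set kept in
`palettes.toml` (package data), not in code; gene gold, TE purple, 13
distinct colors for the 18–30 nt length classes.

## Synthetic data

`FixtureSpec` defaults define the study conditions: plant mode, 30 kb
genome at GC 0.36 (A. thaliana-like), context mean levels CG 0.8, CHG 0.3,
CHH 0.05 (`unknown` sites use the CHH mean), per-site depth 1 + Poisson(5)
(mean 6, so the coverage filter has something to bite on), small-RNA plans
of 20 ungapped perfectly-matching reads per locus with multimapped fraction
0.2, loci spaced 500 bp apart (10 × the clustering gap). Everything is
byte-deterministic under the seed.

The generator emulates data *shapes*, not data-generating physics: no
bisulfite conversion error, no sequencing error, no hairpin precursors, no
realistic locus-length or expression distributions, and smRNA reads are
ungapped (CIGAR complexity is exercised separately in coverage tests).
Passing tests therefore validate the computations and conventions above,
not biological discovery performance on real libraries.

## Numerical and degenerate-input choices

* Levels and densities are exact rational arithmetic on small integers;
  no tolerance is needed anywhere except the statistical recovery tests,
  which use binomial-concentration bounds (±0.05 at ≥10⁴ sites; 3–4
  standard errors elsewhere).
* Ties in modal length (two lengths equally common) resolve to the
  *smaller* length, making locus typing deterministic.
* Empty inputs: empty allc → empty stream plus a warning; empty read set →
  empty locus list; region with no alignments → zero coverage.
* The acceptance script runs the same pipelines at desk scale (31-read
  length sweep; five 20-read loci per sweep), chosen so each quantity is
  recomputed from scratch in well under a second.

## Known limitations

No differential methylation or binomial methylation calling; no
normalization (CPM/RPKM), smoothing or peak calling on coverage; no PWM
scanning or motif discovery; no miRNA hairpin prediction or phasing
statistics; no streaming of chromosome-scale genomes (desk scale assumed);
rendering makes no claim of pixel fidelity to any browser's glyph geometry.
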