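# epitracks

Epigenomics data — DNA base modifications, small non-coding RNAs, stranded
read coverage, sequence motif density — needs track computations that
standard genome-browser tooling leaves implicit. `epitracks` is a small
library + CLI for researchers working with whole-genome bisulfite
sequencing (WGBS) and small-RNA sequencing who need those tracks as
testable, scriptable text files and publication-quality static figures:

* **Base modifications.** Per-site methylation level `m = mc / total` from
  allc-style call tables, classified into cytosine sequence contexts —
  CG / CHG / CHH in plants, CG / CH in animals, with H ∈ {A, C, T} — and
  written as *strand-signed* bedGraph: `+m` for plus-strand sites, `−m` for
  minus, so one track shows level (bar height) and strand (bar direction)
  at once. 4mC, 5mC, 5hmC and 6mA are carried as distinct modification
  types.
* **Small RNAs.** Reads classified by length (the molecule, 18–30 nt by
  default), strand, mapping quality and uniqueness (NH tag > 1 ⇒
  multimapped); loci built by single-linkage clustering and typed by the
  canonical plant size/strand rules — uniform 21 nt single-strand ⇒
  microRNA-like, uniform 24 nt both-strand ⇒ siRNA-like, mixed sizes on one
  strand ⇒ degradation-like.
* **Stranded coverage.** Per-base depth per strand from a CIGAR walk
  (M/=/X count, D/N don't), never averaged across strands — uneven strand
  coverage is exactly the signal worth seeing.
* **Motif density.** IUPAC-degenerate motif scanning on both strands,
  summarized per window as
  `density = matches / (2 · (w − m + 1))` ∈ [0, 1], heatmap-ready.
* **Rendering.** Stacked-track SVG (vector-first) or PNG figures with
  colorblind-safe palettes; gene models gold, transposable elements purple;
  multimapped reads drawn unfilled.

A seeded fixture generator (`epitracks simulate`) produces a complete
synthetic data set (FASTA, GFF3, allc, SAM), so everything here runs
without downloads.

## Worked example

```bash
epitracks simulate --seed 7 --out-dir demo
cd demo
epitracks smrna --alignments smrna.sam --loci loci.tsv
cat loci.tsv
```

```
chrom	start0	end	n_reads	modal_length	modal_fraction	minor_strand_fraction	category
chr1	201	228	20	21	1.0	0.0	miRNA_like
chr1	700	727	20	21	1.0	0.0	miRNA_like
chr1	1200	1228	20	21	1.0	0.0	miRNA_like
chr1	1700	1731	20	24	1.0	0.5	siRNA_like
chr1	2200	2231	20	24	1.0	0.5	siRNA_like
chr1	2700	2731	20	24	1.0	0.5	siRNA_like
chr1	3200	3233	20	21	0.2	0.0	degradation_like
chr1	3700	3733	20	22	0.2	0.0	degradation_like
chr1	4200	4235	20	28	0.15	0.0	degradation_like
```

Each row is one read cluster: `modal_length`/`modal_fraction` summarize the
size distribution (a fraction ≥ 0.8 counts as size-uniform),
`minor_strand_fraction` the strand balance (≥ 0.2 counts as both-strand),
and `category` applies the 21 nt / 24 nt rules above. The simulator planted
three loci of each kind; all nine are recovered.

Methylation tracks from the same data set:

```bash
epitracks allc2track --allc sample.allc.tsv --mode plant --out-prefix sample
# wrote sample.5mC.CG.bedgraph (1882 sites)
# wrote sample.5mC.CHG.bedgraph (1525 sites)
# wrote sample.5mC.CHH.bedgraph (7282 sites)
head -1 sample.5mC.CG.bedgraph
# chr1	13	14	0.875
```

— one line per cytosine, single-base interval, value = signed level (this
site: plus strand, 7 of 8 reads methylated). Coverage, motif density and figure
rendering follow the same pattern:

```bash
epitracks coverage --alignments smrna.sam --genome genome.fa \
    --region chr1:1-6000 --out cov.bedgraph
epitracks motif-density --genome genome.fa --motif CG --motif CWG \
    --window 500 --out dens.bedgraph
epitracks render --genome genome.fa --region chr1:1-6000 \
    --gff anno.gff3 --allc sample.allc.tsv --alignments smrna.sam \
    --motif CG --out fig.svg
```

See `docs/methods.md` for the exact conventions (coordinates, context
rules, density normalization, locus thresholds) and their rationale.

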