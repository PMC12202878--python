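# hsdkit

Duplicate-gene analysis for eukaryotic genomes: classify paralog pairs
into the five canonical duplication modes, estimate substitution rates
(Ka, Ks, Ka/Ks) for duplicate pairs, decompose the Ks distribution, and
detect and curate **highly similar duplicate genes (HSDs)** using both
sequence similarity and conserved protein domains.

## Who this is for

Comparative genomicists studying gene duplication — e.g. dosage-driven
gene retention in algae, or WGD history in plants — who start from a
standard NCBI-style annotation (GFF3 + protein FASTA + CDS FASTA), an
all-vs-all protein homology table (DIAMOND/BLAST `-outfmt 6`,
E-value ≤ 1e-10), and optional InterProScan and KEGG KO annotations.

## What it computes

**Duplication modes.** Every paralog pair receives exactly one label,
assigned in fixed priority order (a pair is tested for each mode only
after the previous modes are excluded):

1. **WGD** — the pair is an anchor of an intra-genome collinear
   (synteny) block. Blocks are maximal-scoring chains of homologous
   gene pairs in gene-rank space, score
   `S = m·|anchors| + g·(skipped genes)` with MCScanX-style defaults
   (match m = 50, gap g = −1, ≥ 5 anchors, per-step gap ≤ 25 genes).
2. **TD** (tandem) — same chromosome, rank distance 1.
3. **PD** (proximal) — same chromosome, rank distance 2..d (d = 10,
   the classic `-d` window).
4. **TRD** (transposed) — exactly one gene of the pair sits at an
   ancestral locus (an anchor in a synteny block against an outgroup
   genome, or in the intra-genome anchor set).
5. **DD** (dispersed) — everything that remains.

**Ka/Ks.** Proteins are globally aligned (BLOSUM62, affine gaps) and
back-translated to codons; synonymous and nonsynonymous sites and
differences are counted with the Nei–Gojobori (1986) method (multi-hit
codons averaged over minimal substitution paths, stop-passing paths
excluded) and corrected with Jukes–Cantor,
`d = −(3/4)·ln(1 − (4/3)p)`. The Ks distribution over synteny-block
anchors is decomposed with a Gaussian mixture fitted by EM, the
component count chosen by BIC.

**HSDs.** Two gene copies qualify as highly similar when a retained hit
between them has amino-acid identity ≥ the threshold, the full protein
lengths differ by at most the threshold (the `90%_10aa` notation), and
the two proteins carry the same multiset of Pfam signatures with
per-domain lengths within 10 aa. HSD groups are the connected
components of this graph; grids of thresholds are merged strict-first
with subset-redundancy pruning (`add_on` / `batch_run`), summarized
into statistics and copy-number categories {2, 3, >3}, and visualized
as a KO-sharing heatmap (cell = number of HSD groups under a label in
which ≥ 1 member carries that KO).

A deterministic simulator (`hsdkit simulate`) generates complete input
bundles with planted families of every mode — including a real
alignment-backed homology table — plus a truth ledger, so the whole
pipeline is testable at desk scale.

## Worked example

```bash
$ hsdkit simulate --seed 7 --out demo/sim
wrote bundle to demo/sim
planted pairs: WGD=12, TD=3, PD=3, TRD=2, DD=2

$ hsdkit classify --gff demo/sim/genome.gff3 --blast demo/sim/self.blast.tsv \
    --outgroup-gff demo/sim/outgroup.gff3 \
    --outgroup-blast demo/sim/outgroup.blast.tsv --out demo/cls
WGD=12, TD=3, PD=3, TRD=2, DD=2 (total 22)
```

The simulator planted two 6-anchor WGD blocks (12 anchor pairs), one
3-copy and one 2-copy tandem family (the 3-copy family contributes two
rank-adjacent TD pairs and one distance-2 PD pair), two proximal
families, two transposed pairs (one copy inside an outgroup-collinear
region) and two dispersed pairs; the classifier recovers every planted
label. Per-mode pair files are written alongside a summary:

```
$ head -4 demo/cls/tandem.pairs.tsv
gene_a	gene_b	evidence
chr1g0198	chr1g0199	rank_distance:1
chr1g0199	chr1g0200	rank_distance:1
chr2g0199	chr2g0200	rank_distance:1
```

The full pipeline (`hsdkit run --config config.yaml`) chains
preprocess → collinearity → classify → kaks → hsd and writes per-stage
TSVs, a Ks-distribution plot with the fitted mixture, HSD tables,
statistics, categories, a KO heatmap, and a markdown report.

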