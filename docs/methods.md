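# Methods

This note documents the models, algorithms and numerical choices behind
hsdkit, the defaults and why they were chosen, what the synthetic-data
generator does and does not emulate, and known limitations.

## Input model and preprocessing

Coordinates are 1-based inclusive (GFF3 convention) end to end.
Gene–protein linkage reads the `protein_id` attribute from CDS rows
(falling back to the mRNA row); the attribute name is configurable
because GFF dialects differ. Gene *rank* is the 1-based position among
a chromosome's genes ordered by ascending start (ties: end, then gene
id); strand never affects rank, because tandem/proximal detection is a
statement about gene order, not orientation.

Each gene is represented by one primary isoform: the longest encoded
protein, ties broken by lexicographically smallest protein id so runs
are reproducible. "Longest transcript" is operationalized as longest
encoded protein because the pipeline compares proteins and UTR lengths
are not recoverable from all GFF dialects.

Homology filtering keeps hits with E ≤ 1e-10 (the DIAMOND blastp
convention assumed upstream), drops self-hits — including hits between
two isoforms of one gene — and hits touching non-primary isoforms, then
keeps the 5 best hits per query gene (ascending E-value, ties by
descending bit score then subject id). The top-5 default follows
MCScanX practice; the upstream search's own candidate cap is unknown,
so both are exposed as configuration. Directed hits collapse into
unordered pairs carrying the best E-value and identity of either
direction.

## Collinearity

Chaining runs in rank space, not base-pair space (MCScanX convention;
robust to intergenic-length variation). For each chromosome pair,
anchors (rank_a, rank_b) are chained under: rank_a strictly
increasing; rank_b strictly increasing (same orientation) or strictly
decreasing (inverted, implemented by negating rank_b); per-step gaps of
at most `max_gap_genes` (25) on each chromosome. Chain score is
`match_score·|anchors| + gap_penalty·Σ skipped genes` (50 and −1).
The defaults mirror MCScanX's published parameters; all four are
configuration. The optimum over chains with ≥ `min_anchors` (5)
anchors is found by an exact dynamic program over (end anchor, chain
length) — quadratic-times-length, appropriate for the per-chromosome
anchor counts the package targets. Overlapping candidates are resolved
greedily: extract the best-scoring chain, remove its anchors, repeat;
ties break on (first anchor ranks, orientation) so output is
permutation-invariant. In intra-genome mode self pairs are excluded
and each unordered block is reported once.

## Duplication-mode classification

Modes are assigned per pair, in fixed priority order (WGD, TD, PD,
TRD, DD), so a gene may appear in pairs of different modes. Tandem
means rank distance exactly 1; an option admits up to k intervening
genes. Proximal is distance 2..d with d = 10. "Ancestral" for the
transposed test means the gene anchors a focal-vs-outgroup synteny
block, or is in the intra-genome anchor set; a configurable fallback
accepts any outgroup homolog, for fragmented outgroup assemblies, and
the evidence string records which criterion fired. When no outgroup
data are supplied the ancestral test never fires and candidate pairs
fall through to dispersed — by construction, removing the outgroup
converts exactly the TRD pairs to DD and changes nothing else. Pairs
touching unplaced scaffolds are never TD/PD (rank distance undefined
across sequences) but remain eligible for the other modes.

## Ka/Ks (NG86)

Protein pairs are aligned globally (Needleman–Wunsch, BLOSUM62, gap
open 10 / extend 0.5 — conventional, configurable) and back-translated
so each aligned residue column becomes its source codon; gap columns
are excluded, ambiguity-code columns are skipped and tallied.

Site counting: per codon position, the fraction of valid one-step
nucleotide changes that are synonymous contributes to S; changes that
create a stop codon are not valid, and the three positions are
renormalized so every codon contributes exactly 3 sites (hence
S + N = 3 × codons). Site totals are averaged over the two sequences.

Difference counting: codons differing at 2–3 positions are averaged
over all orderings of the minimal substitution paths; paths passing
through a stop codon are excluded, unless every path does, in which
case all are kept and the codon pair is flagged in the result (the
classic ambiguity of the counting method).

Proportions ps = Sd/S and pn = Nd/N get the Jukes–Cantor correction
d = −(3/4)·ln(1 − (4/3)p). A proportion ≥ 3/4 is saturated: the rate
is reported as undefined (None), and undefined values never reach the
mixture fit. Ka/Ks is reported only when Ks > 0. The counting model
is recorded in the output header. NG86 was chosen because it is the
convention of the MCScanX-protocol scripts this pipeline follows;
maximum-likelihood codon models are out of scope.

## Ks mixture

The Ks values of synteny-block anchor pairs, restricted to
(0, ks_ceiling] with ceiling 3.0 to exclude saturation noise, are fit
with Gaussian mixtures for k = 1..4 by EM (three initializations,
fixed seed, so the selected fit is deterministic); the reported fit
minimizes BIC. At least 20 usable values are required; fewer is an
error advising a larger pair set. Degenerate inputs (all values
identical) are guarded by the EM implementation's covariance floor
(sd ≥ ~1e-3) rather than crashing. Per-block Ks is summarized as the
median over anchors with defined Ks; blocks with none are omitted.

## HSD detection and curation

An edge joins two genes when a retained hit reaches the identity
threshold, full primary-protein lengths differ by at most the aa
threshold, and domain content is consistent. Length difference uses
full protein lengths, not aligned lengths — reproducible from the
FASTA alone and matching the "aa difference" notation; an
aligned-length option exists. Domain consistency means the same
multiset of signature accessions (Pfam rows by default) with matching
domain lengths within 10 aa; two genes with no annotation are
consistent with each other but not with a domain-bearing gene, and a
lenient mode ignores domains entirely. Groups are single-linkage
connected components (≥ 2 members) — matching the "group of copies"
semantics rather than clique detection; the caveat is that large
relaxed-threshold components can absorb distinct subfamilies
(ribosomal proteins, histones), which is why curation is threshold-
driven. Detection runs per duplication mode by default.

Curation: `add_on(strict, relaxed)` keeps all strict groups and adds a
relaxed group only if its member set is neither equal to nor a subset
of an already-kept set; `batch_run` folds this over a strict→relaxed
grid and ledgers the contribution of each threshold. Statistics count
groups, gene copies with multiplicity, and distinct genes; categories
bucket groups by copy number into {2, 3, >3}. The KO heatmap counts,
per (KO, label), the groups with ≥ 1 member carrying that KO; a group
with several KOs increments each once, and groups with none are
tallied in an `unannotated` row.

## Synthetic-data generator

The generator is first-class, tested code; its defaults are the
package's study conditions: 2 chromosomes × 200 genes and two planted
families per mode (two 6-anchor WGD runs at Ks 0.8, tandem families of
3 and 2 copies at 94–95% identity, proximal pairs at rank distance 5,
transposed pairs with one copy inside an 8-gene outgroup-collinear
region at 80% outgroup identity, dispersed cross-chromosome pairs),
sizes chosen so every mode's defining geometry appears at least twice
while the whole bundle generates in under a second.

Placement guarantees identifiability: features whose pairs fall on the
same chromosome-pair anchor grid are separated by more than
`max_gap_genes` ranks, so no chain can bridge two features and planted
collinearity is exactly what the detector should find.

Divergence is codon-exact. Each family copy mutates codons inside its
own disjoint pool of positions: the planted number of single-nucleotide
amino-acid-changing substitutions (half the target pairwise divergence
per copy) and of synonymous substitutions (half the target Sd, derived
by inverting the Jukes–Cantor correction against the ancestor's
synonymous site count). Pairwise divergence is therefore additive and
hits targets up to rounding; HSD families get no indels, keeping
length variance at zero. The homology table is not faked: every
candidate pair sharing a 6-mer seed (BLAST-style prescreen; random
background proteins essentially never share one) is globally aligned
and the table's identity/length/mismatch columns come from that
alignment. E-values follow a deterministic length-and-score formula
`E = len_a·len_b·2^(−score/2)` — monotone in alignment quality, so the
1e-10 cutoff separates planted families from background exactly as a
real search would at these divergences.

What the simulator does **not** emulate: intergenic sequence and
transposable elements, indel-containing alignments in families,
fragmented assemblies, alternative splicing beyond simple truncated
decoy isoforms, fractionated (gene-loss-degraded) WGD blocks, and
realistic E-value statistics. Passing the recovery tests therefore
shows the algorithms implement their definitions correctly on clean
geometry, not that real-genome noise is handled; on real data the
interesting failure modes are annotation quality and threshold choice.

## Numerical and design choices

- Chain DP tie-breaks, isoform tie-breaks and file row orderings are
  all deterministic; reruns on identical inputs and seeds are
  byte-identical.
- The mixture seed, k range and Ks ceiling are configuration; the
  component count is never hard-coded.
- `ratio` is None when Ks is 0 or undefined — no infinities propagate.
- Errors carry line numbers (parsers), gene names (sequence
  mismatches) or stage names (pipeline), and partial outputs are
  retained on stage failure so runs can be debugged step-by-step.

## Limitations

- Transposed-duplicate calls need an outgroup; without one, TRD
  candidates are reported as dispersed.
- No gene-level disjoint partition ("unique" variant): the
  classification is per pair by design.
- NG86 with Jukes–Cantor is a counting method; for saturated or highly
  biased sequences a likelihood method would be preferable.
- Chain extraction is greedy after the exact per-chain optimum; like
  MCScanX, it does not globally optimize the partition of anchors into
  blocks.
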