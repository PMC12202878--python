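"""Assign every paralog pair exactly one of five duplication modes.

Classification runs in fixed priority order on the not-yet-classified
pairs, mirroring DupGen_finder semantics:

1. WGD — the pair is an anchor pair of an intra-genome synteny block;
2. TD  — same chromosome, rank distance exactly 1 (tandem; an option
   allows up to ``tandem_max_intervening`` intervening genes);
3. PD  — same chromosome, rank distance 2..proximal_max_d (proximal);
4. TRD — exactly one gene of the pair sits at an ancestral locus
   (anchor in a focal-vs-outgroup synteny block, or member of the
   intra-genome anchor set); the other does not (transposed);
5. DD  — everything left (dispersed).

Every input pair receives exactly one mode; a gene may appear in pairs
of different modes (the partition is over pairs, not genes).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .collinearity import SyntenyBlock, anchor_gene_set
from .io_formats import MODES, DuplicatePair, GeneModel


@dataclass
class ClassifyParams:
    """proximal_max_d: maximum rank distance (in genes) treated as
    proximal (DupGen_finder's ``-d``, default 10).

    tandem_max_intervening: intervening unrelated genes allowed inside a
    tandem pair (default 0 = strictly rank-adjacent).

    trd_requires_outgroup_block: if True (default), the ancestral-locus
    test for TRD uses focal-vs-outgroup synteny-block anchors; if False,
    any outgroup homolog marks a gene ancestral (fallback for fragmented
    outgroup assemblies).
    """

    proximal_max_d: int = 10
    tandem_max_intervening: int = 0
    trd_requires_outgroup_block: bool = True

    def __post_init__(self) -> None:
        if self.proximal_max_d < 2:
            raise ValueError("proximal_max_d must be >= 2")
        if self.tandem_max_intervening < 0:
            raise ValueError("tandem_max_intervening must be >= 0")


def classify_duplicates(
    pairs: Iterable,
    genes: Sequence[GeneModel],
    intra_blocks: Sequence[SyntenyBlock] = (),
    outgroup_pairs: Iterable = (),
    outgroup_blocks: Sequence[SyntenyBlock] = (),
    params: ClassifyParams | None = None,
    unplaced_chromosomes: set[str] | None = None,
) -> list[DuplicatePair]:
    """Label every paralog pair with one of {WGD, TD, PD, TRD, DD}.

    Parameters
    ----------
    pairs:
        Filtered gene-level paralog pairs of the focal genome (anything
        with ``gene_a``/``gene_b`` attributes, or 2-tuples).
    genes:
        Focal gene table with chromosome and rank assigned.
    intra_blocks:
        Intra-genome synteny blocks (WGD evidence).
    outgroup_pairs:
        Focal-vs-outgroup gene homology pairs; ``(focal_gene, outgroup
        gene)`` order (used when the outgroup-block criterion is off).
    outgroup_blocks:
        Focal-vs-outgroup synteny blocks whose A side is the focal
        genome (ancestral-locus evidence for TRD).
    unplaced_chromosomes:
        Sequence names treated as unplaced scaffolds: pairs touching one
        are never TD/PD (rank distance is undefined across sequences).
    """
    if params is None:
        params = ClassifyParams()
    loc = {g.gene_id: (g.chromosome, g.rank) for g in genes}
    unplaced = unplaced_chromosomes or set()

    anchor_lookup: dict[tuple[str, str], int] = {}
    for b in intra_blocks:
        for a in b.anchors:
            key = tuple(sorted((a.gene_a, a.gene_b)))
            anchor_lookup.setdefault(key, b.block_id)
    intra_anchor_genes = anchor_gene_set(intra_blocks)

    outgroup_pairs = list(outgroup_pairs)
    has_outgroup = bool(outgroup_blocks) or bool(outgroup_pairs)
    if params.trd_requires_outgroup_block:
        ancestral = {a.gene_a for b in outgroup_blocks for a in b.anchors}
        criterion = "outgroup-block-anchor"
    else:
        ancestral = set()
        for p in outgroup_pairs:
            ga = p.gene_a if hasattr(p, "gene_a") else p[0]
            ancestral.add(ga)
        criterion = "outgroup-homolog"
    if has_outgroup:
        # intra-genome anchors also mark ancestral loci, but only when an
        # outgroup is supplied: without one, no TRD call is possible and
        # candidate pairs fall through to DD.
        ancestral |= intra_anchor_genes
    else:
        ancestral = set()

    out: list[DuplicatePair] = []
    for pair in pairs:
        if hasattr(pair, "gene_a"):
            a, b = pair.gene_a, pair.gene_b
        else:
            a, b = pair[0], pair[1]
        if a == b:
            continue
        for g in (a, b):
            if g not in loc:
                raise KeyError(f"gene {g} in a paralog pair is absent from the gene table")
        a, b = sorted((a, b))
        ca, ra = loc[a]
        cb, rb = loc[b]

        key = (a, b)
        if key in anchor_lookup:
            out.append(DuplicatePair(a, b, "WGD", f"block:{anchor_lookup[key]}"))
            continue
        placed = ca not in unplaced and cb not in unplaced
        if placed and ca == cb:
            d = abs(ra - rb)
            if d <= 1 + params.tandem_max_intervening:
                out.append(DuplicatePair(a, b, "TD", f"rank_distance:{d}"))
                continue
            if d <= params.proximal_max_d:
                out.append(DuplicatePair(a, b, "PD", f"rank_distance:{d}"))
                continue
        a_anc = a in ancestral
        b_anc = b in ancestral
        if a_anc != b_anc:
            anc = a if a_anc else b
            out.append(DuplicatePair(a, b, "TRD", f"ancestral:{anc}({criterion})"))
            continue
        out.append(DuplicatePair(a, b, "DD", "excluded-from-other-modes"))
    return out


def mode_summary(classified: Iterable[DuplicatePair]) -> dict:
    """Per-mode pair counts and unique gene counts.

    Returns ``{"pairs": {mode: n}, "genes": {mode: n}, "total_pairs": N}``;
    pair counts always sum to the number of input pairs.
    """
    pair_counts = {m: 0 for m in MODES}
    gene_sets: dict[str, set[str]] = {m: set() for m in MODES}
    total = 0
    for p in classified:
        pair_counts[p.mode] += 1
        gene_sets[p.mode].update((p.gene_a, p.gene_b))
        total += 1
    return {
        "pairs": pair_counts,
        "genes": {m: len(s) for m, s in gene_sets.items()},
        "total_pairs": total,
    }
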