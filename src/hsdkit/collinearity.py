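"""Collinear (synteny) block detection by chaining homologous gene pairs
in rank space.

Chaining follows the MCScanX convention: gene order (chromosome rank),
not base-pair distance, defines proximity.  For each chromosome pair the
homology pairs are anchors on a rank-by-rank grid; a block is a chain of
anchors whose ranks increase strictly on chromosome A and increase
(same orientation) or decrease (inverted) strictly on chromosome B.
Chain score = match_score * n_anchors + gap_penalty * total skipped
genes (summed over both chromosomes); a chain is valid when every
single-step gap is at most ``max_gap_genes`` genes per chromosome and it
has at least ``min_anchors`` anchors.  Overlapping candidates are
resolved greedily by descending score, each anchor used at most once.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .io_formats import GeneModel


@dataclass
class CollinearityParams:
    min_anchors: int = 5
    max_gap_genes: int = 25
    match_score: float = 50.0
    gap_penalty: float = -1.0  # per skipped gene

    def __post_init__(self) -> None:
        if self.min_anchors < 2:
            raise ValueError("min_anchors must be >= 2")
        if self.max_gap_genes < 1:
            raise ValueError("max_gap_genes must be >= 1")


@dataclass
class AnchorPair:
    gene_a: str
    gene_b: str
    rank_a: int
    rank_b: int
    evalue: float = 0.0


@dataclass
class SyntenyBlock:
    chrom_a: str
    chrom_b: str
    anchors: list[AnchorPair]
    orientation: str  # "same" | "inverted"
    score: float
    block_id: int = 0

    def gene_ids(self) -> set[str]:
        out: set[str] = set()
        for a in self.anchors:
            out.add(a.gene_a)
            out.add(a.gene_b)
        return out


def _pair_fields(pair) -> tuple[str, str, float]:
    """Accept ParalogPair-likes, (a, b) or (a, b, evalue) tuples."""
    if hasattr(pair, "gene_a"):
        ev = getattr(pair, "best_evalue", getattr(pair, "evalue", 0.0))
        return pair.gene_a, pair.gene_b, ev
    a, b = pair[0], pair[1]
    ev = pair[2] if len(pair) > 2 else 0.0
    return a, b, ev


def find_synteny_blocks(
    genes_a: Sequence[GeneModel],
    genes_b: Sequence[GeneModel],
    pairs: Iterable,
    params: CollinearityParams | None = None,
) -> list[SyntenyBlock]:
    """Chain gene-level homology pairs into maximal-scoring synteny blocks.

    ``genes_a`` and ``genes_b`` may be the same list (intra-genome mode),
    in which case self pairs are excluded, chromosome pairs are
    canonicalized (unordered) and each block is reported once.

    Returns blocks sorted deterministically by (chrom_a, chrom_b, first
    anchor ranks), with sequential ``block_id`` starting at 1.
    """
    if params is None:
        params = CollinearityParams()
    intra = genes_a is genes_b or [g.gene_id for g in genes_a] == [
        g.gene_id for g in genes_b
    ]
    loc_a = {g.gene_id: (g.chromosome, g.rank) for g in genes_a}
    loc_b = {g.gene_id: (g.chromosome, g.rank) for g in genes_b}

    # bucket anchors per chromosome pair
    grid: dict[tuple[str, str], list[AnchorPair]] = {}
    seen: set[tuple[str, str]] = set()
    for pair in pairs:
        ga, gb, ev = _pair_fields(pair)
        if ga == gb:
            continue
        if not intra and ga not in loc_a and gb in loc_a and ga in loc_b:
            ga, gb = gb, ga  # pair arrived subject-first; reorient
        if ga not in loc_a or gb not in loc_b:
            continue
        ca, ra = loc_a[ga]
        cb, rb = loc_b[gb]
        if intra:
            # canonical orientation: order by (chromosome, rank)
            if (cb, rb) < (ca, ra):
                ga, gb, ca, ra, cb, rb = gb, ga, cb, rb, ca, ra
        key = tuple(sorted((ga, gb)))
        if key in seen:
            continue
        seen.add(key)
        grid.setdefault((ca, cb), []).append(AnchorPair(ga, gb, ra, rb, ev))

    blocks: list[SyntenyBlock] = []
    for (ca, cb), anchors in grid.items():
        blocks.extend(_extract_blocks(ca, cb, anchors, params))

    blocks.sort(
        key=lambda b: (
            b.chrom_a,
            b.chrom_b,
            b.anchors[0].rank_a,
            b.anchors[0].rank_b,
            b.orientation,
        )
    )
    for i, b in enumerate(blocks, start=1):
        b.block_id = i
    return blocks


def _extract_blocks(
    chrom_a: str, chrom_b: str, anchors: list[AnchorPair], params: CollinearityParams
) -> list[SyntenyBlock]:
    """Greedy best-chain extraction on one chromosome-pair anchor grid."""
    remaining = list(anchors)
    out: list[SyntenyBlock] = []
    while True:
        best = None  # (score, tiebreak, chain, orientation)
        for orientation in ("same", "inverted"):
            chain, score = _best_chain(remaining, params, orientation)
            if chain is None:
                continue
            tiebreak = (
                chain[0].rank_a,
                chain[0].rank_b,
                0 if orientation == "same" else 1,
            )
            if best is None or (score, ) + tuple(-t for t in tiebreak) > (
                best[0],
            ) + tuple(-t for t in best[1]):
                best = (score, tiebreak, chain, orientation)
        if best is None:
            break
        score, _, chain, orientation = best
        out.append(SyntenyBlock(chrom_a, chrom_b, chain, orientation, score))
        used = {id(a) for a in chain}
        remaining = [a for a in remaining if id(a) not in used]
    return out


def _best_chain(
    anchors: list[AnchorPair], params: CollinearityParams, orientation: str
) -> tuple[list[AnchorPair] | None, float]:
    """Optimal-score valid chain with >= min_anchors anchors, or (None, 0).

    Exact DP over (end anchor, chain length); strictly increasing rank_a,
    strictly increasing (same) / decreasing (inverted) rank_b, per-step
    gaps bounded by max_gap_genes on each chromosome.
    """
    n = len(anchors)
    if n < params.min_anchors:
        return None, 0.0
    sign = 1 if orientation == "same" else -1
    # deterministic processing order
    order = sorted(
        range(n), key=lambda i: (anchors[i].rank_a, sign * anchors[i].rank_b)
    )
    ra = [anchors[i].rank_a for i in order]
    rb = [sign * anchors[i].rank_b for i in order]
    m, gmax = params.match_score, params.max_gap_genes
    pen = params.gap_penalty
    kmax = n
    NEG = float("-inf")
    # dp[j][k]: best score of a valid chain of exactly k anchors ending at j
    dp = [[NEG] * (kmax + 1) for _ in range(n)]
    back = [[None] * (kmax + 1) for _ in range(n)]
    for j in range(n):
        dp[j][1] = m
        for i in range(j):
            da = ra[j] - ra[i] - 1
            db = rb[j] - rb[i] - 1
            if da < 0 or db < 0 or da > gmax or db > gmax:
                continue
            if ra[j] == ra[i] or rb[j] == rb[i]:
                continue
            step = m + pen * (da + db)
            for k in range(2, kmax + 1):
                prev = dp[i][k - 1]
                if prev == NEG:
                    continue
                cand = prev + step
                if cand > dp[j][k]:
                    dp[j][k] = cand
                    back[j][k] = i
    best_score, best_end = NEG, None
    for j in range(n):
        for k in range(params.min_anchors, kmax + 1):
            if dp[j][k] > best_score:
                best_score, best_end = dp[j][k], (j, k)
    if best_end is None:
        return None, 0.0
    j, k = best_end
    idx = []
    while j is not None:
        idx.append(j)
        j2 = back[j][k]
        j, k = j2, k - 1
    idx.reverse()
    chain = [anchors[order[i]] for i in idx]
    return chain, best_score


def anchor_gene_set(blocks: Iterable[SyntenyBlock]) -> set[str]:
    """Union of all genes appearing in any anchor of any block."""
    out: set[str] = set()
    for b in blocks:
        out |= b.gene_ids()
    return out


def write_collinearity(blocks: Iterable[SyntenyBlock], path: str | Path) -> None:
    """Write a '.collinearity'-style report: one header per block followed
    by its tab-separated anchor pairs."""
    with open(path, "w") as fh:
        for b in blocks:
            fh.write(
                f"## block {b.block_id}: {b.chrom_a}&{b.chrom_b} "
                f"score={b.score:.1f} orientation={b.orientation} "
                f"anchors={len(b.anchors)}\n"
            )
            for a in b.anchors:
                fh.write(f"{b.block_id}\t{a.gene_a}\t{a.gene_b}\t{a.evalue:.2e}\n")


def read_collinearity(path: str | Path) -> list[SyntenyBlock]:
    """Read back a report written by :func:`write_collinearity` (rank
    information is not stored in the report; anchors carry ranks 0)."""
    blocks: list[SyntenyBlock] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("## block"):
                head, rest = line[3:].split(":", 1)
                bid = int(head.split()[1])
                fields = rest.split()
                ca, cb = fields[0].split("&")
                score = float(fields[1].split("=")[1])
                orientation = fields[2].split("=")[1]
                blocks.append(SyntenyBlock(ca, cb, [], orientation, score, bid))
            else:
                cols = line.split("\t")
                blocks[-1].anchors.append(
                    AnchorPair(cols[1], cols[2], 0, 0, float(cols[3]))
                )
    return blocks
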