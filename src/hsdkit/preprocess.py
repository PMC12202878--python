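"""Reduce raw annotation + homology input to the filtered gene-level pairs
the duplicate classifier consumes.

The homology search is performed externally (DIAMOND/BLAST all-vs-all on
primary proteins); this module selects one primary isoform per gene,
filters the protein-level hit table (E-value cutoff, self-hits, top hits
per query) and collapses directed hits into unordered gene pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .io_formats import GeneModel, HomologyHit

logger = logging.getLogger(__name__)


@dataclass
class FilterParams:
    """Homology-hit filter settings.

    max_evalue: retain hits with evalue <= this (default 1e-10, the
    DIAMOND blastp cutoff the pipeline assumes upstream).
    top_hits_per_query: best hits kept per query gene, by ascending
    evalue then descending bitscore (default 5, MCScanX convention).
    """

    max_evalue: float = 1e-10
    top_hits_per_query: int = 5
    drop_self_hits: bool = True

    def __post_init__(self) -> None:
        if self.max_evalue <= 0:
            raise ValueError("max_evalue must be > 0")
        if self.top_hits_per_query < 1:
            raise ValueError("top_hits_per_query must be >= 1")


def select_primary_isoforms(genes: list[GeneModel]) -> dict[str, str]:
    """Choose one primary protein per gene: the longest isoform's protein,
    ties broken by lexicographically smallest protein id.

    Returns gene_id -> protein_id.  Raises on a gene with no isoforms.
    """
    out: dict[str, str] = {}
    for g in genes:
        if not g.isoform_ids:
            raise ValueError(f"gene {g.gene_id} has no isoforms")
        _, pid, _ = min(g.isoform_ids, key=lambda t: (-t[2], t[1]))
        out[g.gene_id] = pid
    return out


def filter_hits(
    hits: list[HomologyHit],
    params: FilterParams,
    primary_map: dict[str, str],
    subject_map: dict[str, str] | None = None,
) -> list[HomologyHit]:
    """Filter a protein-level hit table and rewrite ids to gene ids.

    Drops hits failing the E-value cutoff, self-hits (including hits
    between two isoforms of one gene), and hits involving non-primary
    isoforms; then keeps the ``top_hits_per_query`` best hits per query
    gene (ascending evalue, ties by descending bitscore, then subject id
    for determinism).

    ``primary_map`` maps gene_id -> primary protein_id for the query
    side; ``subject_map`` (defaults to ``primary_map``) does the same
    for the subject side, which differs in cross-genome searches.
    Hits referencing unknown proteins are dropped with a warning count.
    """
    if subject_map is None:
        subject_map = primary_map
    q_prot2gene = {pid: gid for gid, pid in primary_map.items()}
    s_prot2gene = {pid: gid for gid, pid in subject_map.items()}

    unknown = 0
    by_query: dict[str, list[HomologyHit]] = {}
    for h in hits:
        if h.evalue > params.max_evalue:
            continue
        qgene = q_prot2gene.get(h.query_id, None)
        sgene = s_prot2gene.get(h.subject_id, None)
        if qgene is None or sgene is None:
            # non-primary isoform or a protein absent from the annotation
            unknown += 1
            continue
        if params.drop_self_hits and qgene == sgene:
            continue
        rewritten = HomologyHit(
            query_id=qgene,
            subject_id=sgene,
            pident=h.pident,
            align_len=h.align_len,
            mismatches=h.mismatches,
            gap_opens=h.gap_opens,
            qstart=h.qstart,
            qend=h.qend,
            sstart=h.sstart,
            send=h.send,
            evalue=h.evalue,
            bitscore=h.bitscore,
        )
        by_query.setdefault(qgene, []).append(rewritten)

    if unknown:
        logger.warning("%d hits referenced unknown/non-primary proteins; dropped", unknown)

    out: list[HomologyHit] = []
    for qgene in sorted(by_query):
        ranked = sorted(
            by_query[qgene], key=lambda h: (h.evalue, -h.bitscore, h.subject_id)
        )
        out.extend(ranked[: params.top_hits_per_query])
    return out


@dataclass
class ParalogPair:
    """An unordered gene pair surviving the hit filter, with best evidence."""

    gene_a: str
    gene_b: str
    best_evalue: float
    max_pident: float

    @property
    def key(self) -> tuple[str, str]:
        return (self.gene_a, self.gene_b)


def paralog_pairs(filtered_hits: list[HomologyHit]) -> list[ParalogPair]:
    """Collapse directed gene-level hits into unordered pairs.

    A pair is kept if either direction had a surviving hit; it carries
    the minimum evalue and maximum pident seen in either direction.
    Output is sorted by (gene_a, gene_b).
    """
    acc: dict[tuple[str, str], ParalogPair] = {}
    for h in filtered_hits:
        a, b = sorted((h.query_id, h.subject_id))
        if a == b:
            continue
        cur = acc.get((a, b))
        if cur is None:
            acc[(a, b)] = ParalogPair(a, b, h.evalue, h.pident)
        else:
            cur.best_evalue = min(cur.best_evalue, h.evalue)
            cur.max_pident = max(cur.max_pident, h.pident)
    return [acc[k] for k in sorted(acc)]
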