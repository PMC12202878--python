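"""Readers and writers for the standard formats the pipeline touches.

All genomic coordinates are 1-based and inclusive (GFF3 convention)
throughout the package; nothing downstream uses half-open intervals.

Supported formats
-----------------
read:  GFF3 (gene/mRNA/CDS), FASTA (protein and CDS), BLAST tabular
       ``-outfmt 6`` (12 columns, extra columns tolerated), InterProScan
       TSV, two-column gene -> KEGG KO tables.
write: MCScanX-dialect gene position tables, per-duplication-mode pair
       TSVs, BLAST tabular homology tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from gffutils.feature import feature_from_line

logger = logging.getLogger(__name__)

#: canonical duplication-mode labels, in classification priority order
MODES = ("WGD", "TD", "PD", "TRD", "DD")

#: file-name stems used for the per-mode pair files
MODE_STEMS = {
    "WGD": "wgd",
    "TD": "tandem",
    "PD": "proximal",
    "TRD": "transposed",
    "DD": "dispersed",
}


@dataclass
class GeneModel:
    """A protein-coding gene: location, rank along its chromosome, isoforms.

    ``rank`` is the 1-based position of the gene among all genes on its
    chromosome ordered by ascending start (ties: ascending end, then
    gene_id); strand never affects rank.  ``isoform_ids`` holds
    ``(transcript_id, protein_id, protein_length_aa)`` triples and
    ``primary_protein_id`` is the longest isoform's protein (ties broken
    by lexicographically smallest protein id).
    """

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str
    rank: int = 0
    primary_protein_id: str = ""
    primary_protein_length: int = 0
    isoform_ids: list[tuple[str, str, int]] = field(default_factory=list)


@dataclass
class HomologyHit:
    """One row of a 12-column BLAST/DIAMOND tabular (outfmt 6) result."""

    query_id: str
    subject_id: str
    pident: float
    align_len: int
    mismatches: int
    gap_opens: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float


@dataclass
class DomainAnnotation:
    """One InterProScan match row: a signature hit on a protein interval."""

    protein_id: str
    analysis: str
    signature_acc: str
    signature_desc: str
    dstart: int
    dend: int
    interpro_acc: str = ""

    @property
    def length(self) -> int:
        return self.dend - self.dstart + 1


@dataclass
class KoAnnotation:
    """A gene -> KEGG Orthology (K#####) assignment; empty ko_id = unannotated."""

    gene_id: str
    ko_id: str


@dataclass
class DuplicatePair:
    """An unordered paralog pair labeled with one of the five duplication modes.

    ``gene_a < gene_b`` lexicographically; ``evidence`` records what fired
    (block id, rank distance, or the ancestral-locus criterion).
    """

    gene_a: str
    gene_b: str
    mode: str
    evidence: str = ""

    def __post_init__(self) -> None:
        if self.gene_a > self.gene_b:
            self.gene_a, self.gene_b = self.gene_b, self.gene_a

    @property
    def key(self) -> tuple[str, str]:
        return (self.gene_a, self.gene_b)


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

_TRANSCRIPT_TYPES = {"mRNA", "transcript"}


def parse_gff3(
    path: str | Path,
    protein_attr: Sequence[str] = ("protein_id", "Name"),
) -> list[GeneModel]:
    """Parse a GFF3 annotation into :class:`GeneModel` records.

    Genes are linked to proteins through their CDS features: for each
    mRNA/transcript the protein id is taken from the first attribute in
    ``protein_attr`` present on its CDS rows (falling back to the same
    attributes on the mRNA row).  Protein length is ``total_CDS_nt // 3``.
    Genes with no CDS-bearing isoform are dropped with a warning.

    Parameters
    ----------
    path:
        GFF3 file with gene / mRNA (or transcript) / CDS features.
    protein_attr:
        Attribute names tried, in order, to recover the protein id
        (configurable for non-NCBI GFF dialects).

    Raises
    ------
    ValueError
        On a malformed line (fewer than 9 tab-separated columns), with
        the offending line number.
    """
    genes: dict[str, GeneModel] = {}
    transcripts: dict[str, dict] = {}  # tid -> {gene, protein, cds_nt}
    orphan_cds = 0

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if line.startswith("##FASTA"):
                break
            if not line or line.startswith("#"):
                continue
            if line.count("\t") < 8:
                raise ValueError(
                    f"{path}: malformed GFF3 line {lineno}: expected 9 "
                    f"tab-separated columns, got {line.count(chr(9)) + 1}"
                )
            try:
                feat = feature_from_line(line)
            except Exception as exc:  # pragma: no cover - gffutils detail
                raise ValueError(
                    f"{path}: malformed GFF3 line {lineno}: {exc}"
                ) from exc

            ftype = feat.featuretype
            attrs = feat.attributes
            if ftype == "gene":
                gid = _first(attrs, "ID")
                if gid is None:
                    raise ValueError(
                        f"{path}: gene without ID attribute at line {lineno}"
                    )
                genes[gid] = GeneModel(
                    gene_id=gid,
                    chromosome=feat.seqid,
                    start=feat.start,
                    end=feat.end,
                    strand=feat.strand,
                )
            elif ftype in _TRANSCRIPT_TYPES:
                tid = _first(attrs, "ID")
                parent = _first(attrs, "Parent")
                if tid is None or parent is None:
                    continue
                transcripts[tid] = {
                    "gene": parent,
                    "protein": _first_of(attrs, protein_attr),
                    "cds_nt": 0,
                }
            elif ftype == "CDS":
                parent = _first(attrs, "Parent")
                if parent is None or parent not in transcripts:
                    orphan_cds += 1
                    continue
                rec = transcripts[parent]
                rec["cds_nt"] += feat.end - feat.start + 1
                pid = _first_of(attrs, protein_attr)
                if pid is not None:
                    rec["protein"] = pid

    if orphan_cds:
        logger.warning("%s: %d CDS rows with unknown parent ignored", path, orphan_cds)

    for tid, rec in transcripts.items():
        gene = genes.get(rec["gene"])
        if gene is None or rec["cds_nt"] == 0 or rec["protein"] is None:
            continue
        gene.isoform_ids.append((tid, rec["protein"], rec["cds_nt"] // 3))

    out = []
    for gene in genes.values():
        if not gene.isoform_ids:
            logger.warning("gene %s has no CDS-bearing isoform; dropped", gene.gene_id)
            continue
        # longest protein wins; ties -> lexicographically smallest protein id
        _, pid, plen = min(gene.isoform_ids, key=lambda t: (-t[2], t[1]))
        gene.primary_protein_id = pid
        gene.primary_protein_length = plen
        out.append(gene)

    assign_ranks(out)
    return out


def assign_ranks(genes: list[GeneModel]) -> None:
    """Assign per-chromosome ranks 1..n in place, ordered by (start, end, id)."""
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chromosome, []).append(g)
    for members in by_chrom.values():
        members.sort(key=lambda g: (g.start, g.end, g.gene_id))
        for i, g in enumerate(members, start=1):
            g.rank = i


def _first(attrs, key: str) -> str | None:
    vals = attrs.get(key)
    return vals[0] if vals else None


def _first_of(attrs, keys: Iterable[str]) -> str | None:
    for key in keys:
        val = _first(attrs, key)
        if val is not None:
            return val
    return None


# ---------------------------------------------------------------------------
# BLAST tabular (outfmt 6)
# ---------------------------------------------------------------------------


def read_homology_table(path: str | Path) -> list[HomologyHit]:
    """Read a BLAST/DIAMOND tabular (``-outfmt 6``) homology table.

    Requires >= 12 tab-separated columns per row; extra columns
    (``qlen``/``slen`` variants) are ignored.  Scientific-notation
    E-values are accepted.
    """
    hits: list[HomologyHit] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 12:
                raise ValueError(
                    f"{path}: line {lineno}: expected >= 12 tab-separated "
                    f"columns, got {len(cols)}"
                )
            try:
                hits.append(
                    HomologyHit(
                        query_id=cols[0],
                        subject_id=cols[1],
                        pident=float(cols[2]),
                        align_len=int(cols[3]),
                        mismatches=int(cols[4]),
                        gap_opens=int(cols[5]),
                        qstart=int(cols[6]),
                        qend=int(cols[7]),
                        sstart=int(cols[8]),
                        send=int(cols[9]),
                        evalue=float(cols[10]),
                        bitscore=float(cols[11]),
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
    return hits


def write_homology_table(hits: Iterable[HomologyHit], path: str | Path) -> None:
    """Write hits back out in 12-column outfmt-6 layout."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t{h.pident:.1f}\t{h.align_len}\t"
                f"{h.mismatches}\t{h.gap_opens}\t{h.qstart}\t{h.qend}\t"
                f"{h.sstart}\t{h.send}\t{h.evalue:.2e}\t{h.bitscore:.1f}\n"
            )


# ---------------------------------------------------------------------------
# InterProScan TSV / KO table
# ---------------------------------------------------------------------------


def read_interproscan_tsv(path: str | Path) -> list[DomainAnnotation]:
    """Read an InterProScan TSV (protein in col 1, analysis col 4,
    signature acc/desc cols 5-6, start/stop cols 7-8, InterPro acc col 12).
    """
    out: list[DomainAnnotation] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) < 8:
                raise ValueError(
                    f"{path}: line {lineno}: expected >= 8 columns, got {len(cols)}"
                )
            try:
                dstart, dend = int(cols[6]), int(cols[7])
            except ValueError as exc:
                raise ValueError(
                    f"{path}: line {lineno}: non-numeric domain start/stop"
                ) from exc
            interpro = cols[11] if len(cols) > 11 and cols[11] not in ("-", "") else ""
            out.append(
                DomainAnnotation(
                    protein_id=cols[0],
                    analysis=cols[3],
                    signature_acc=cols[4],
                    signature_desc=cols[5],
                    dstart=dstart,
                    dend=dend,
                    interpro_acc=interpro,
                )
            )
    return out


def read_ko_table(path: str | Path) -> list[KoAnnotation]:
    """Read a two-column gene -> KO table; a missing second column means
    the gene is unannotated (empty ko_id)."""
    out: list[KoAnnotation] = []
    with open(path) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            ko = cols[1].strip() if len(cols) > 1 else ""
            out.append(KoAnnotation(gene_id=cols[0].strip(), ko_id=ko))
    return out


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an id -> sequence mapping (order preserved)."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# MCScanX-dialect gene position table / per-mode pair files
# ---------------------------------------------------------------------------


def write_gene_position_table(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Write the 4-column (chromosome, gene_id, start, end) gene table
    consumed by MCScanX-style tools."""
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chromosome}\t{g.gene_id}\t{g.start}\t{g.end}\n")


def write_pair_files(
    pairs: Iterable[DuplicatePair], outdir: str | Path, prefix: str = ""
) -> dict[str, Path]:
    """Write one TSV per duplication mode (header + gene_a, gene_b, evidence).

    Rows are sorted by (gene_a, gene_b); every mode file is written even
    when empty.  Returns mode -> path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    by_mode: dict[str, list[DuplicatePair]] = {m: [] for m in MODES}
    for p in pairs:
        if p.mode not in by_mode:
            raise ValueError(f"unknown duplication mode {p.mode!r} for pair {p.key}")
        by_mode[p.mode].append(p)

    paths: dict[str, Path] = {}
    for mode, members in by_mode.items():
        path = outdir / f"{prefix}{MODE_STEMS[mode]}.pairs.tsv"
        with open(path, "w") as fh:
            fh.write("gene_a\tgene_b\tevidence\n")
            for p in sorted(members, key=lambda p: p.key):
                fh.write(f"{p.gene_a}\t{p.gene_b}\t{p.evidence}\n")
        paths[mode] = path
    return paths
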