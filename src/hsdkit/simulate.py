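"""Deterministic synthetic-genome generator with planted duplicate families.

The generator emits every input the pipeline reads — GFF3 annotation,
protein and CDS FASTA, an all-vs-all homology table, InterProScan-style
domain TSV, a gene->KO table and (optionally) an outgroup bundle —
together with a machine-readable truth ledger of every planted pair,
its duplication mode, realized identity and planted Ks.

Planting geometry, by mode:

* WGD — a run of ``wgd_block_len`` consecutive anchor genes on one
  chromosome duplicated as a collinear run on another (a clean synteny
  block diagonal).
* TD — rank-adjacent copies; PD — copies at rank distance 2..d on one
  chromosome; DD — singleton copies on distant chromosomes.
* TRD — one copy inside a region mirrored collinearly in the outgroup
  genome (the ancestral locus), the other at a novel locus.

Features whose homology pairs fall on the same chromosome-pair anchor
grid are separated by more than ``max_gap_genes`` ranks, so chains can
never bridge two planted features and each feature's collinearity is
exactly what was planted.

Sequence divergence is codon-exact: each family copy mutates codons
drawn from its own disjoint pool of codon positions, receiving the
planted number of amino-acid-changing and synonymous single-nucleotide
substitutions, so pairwise amino-acid identity and synonymous
divergence are additive and hit their targets up to rounding.  The
homology table is computed by actually aligning the generated proteins
(global, BLOSUM62) for every candidate pair sharing a 6-mer seed;
E-values follow a deterministic length-and-score formula.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices

from .io_formats import write_fasta
from .kaks import STOP_CODONS, _codon_sites, translate_codon

_CODONS = sorted(
    c
    for c in ("".join(t) for t in __import__("itertools").product("ACGT", repeat=3))
    if c not in STOP_CODONS
)

MODES = ("WGD", "TD", "PD", "TRD", "DD")


@dataclass
class PlantSpec:
    """One planted duplicate family.

    For WGD, ``family_size`` is the number of anchor pairs in the
    planted collinear run (>= the chain detector's min_anchors);
    otherwise it is the number of gene copies.  ``diverged_extra`` adds
    one extra copy at ~60% identity next to the family (an HSD
    pseudo-copy that similarity thresholds must exclude).
    """

    mode: str
    family_size: int = 2
    target_identity: float = 92.0
    target_ks: float = 0.3
    diverged_extra: bool = False

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}")
        if not 50 < self.target_identity <= 100:
            raise ValueError("target_identity must be in (50, 100]")
        if self.family_size < 2:
            raise ValueError("family_size must be >= 2")


def default_planted() -> list[PlantSpec]:
    """Two families per mode: the default desk-scale study conditions."""
    return [
        PlantSpec("WGD", 6, 90.0, 0.8),
        PlantSpec("WGD", 6, 88.0, 0.8),
        PlantSpec("TD", 3, 95.0, 0.15),
        PlantSpec("TD", 2, 94.0, 0.2),
        PlantSpec("PD", 2, 93.0, 0.25),
        PlantSpec("PD", 2, 95.0, 0.2),
        PlantSpec("TRD", 2, 92.0, 0.3),
        PlantSpec("TRD", 2, 94.0, 0.25),
        PlantSpec("DD", 2, 93.0, 0.3),
        PlantSpec("DD", 2, 95.0, 0.25),
    ]


@dataclass
class SimConfig:
    seed: int = 0
    n_chromosomes: int = 2
    genes_per_chromosome: int = 200
    planted: list[PlantSpec] = field(default_factory=default_planted)
    outgroup: bool = True
    n_domain_types: int = 20
    n_ko_types: int = 30
    family_protein_length: int = 200  # codons per planted-family protein
    background_length_range: tuple[int, int] = (120, 250)
    proximal_distance: int = 5  # rank distance used for PD plants (2..d)
    outgroup_region_len: int = 8
    outgroup_identity: float = 80.0
    n_decoy_isoforms: int = 3
    max_gap_genes: int = 25  # chain-gap bound the placement must defeat
    ko_background_rate: float = 0.4

    def __post_init__(self) -> None:
        if self.n_chromosomes < 2:
            raise ValueError("need at least 2 chromosomes")
        if self.genes_per_chromosome < 10:
            raise ValueError("need at least 10 genes per chromosome")
        if not 2 <= self.proximal_distance <= 10:
            raise ValueError("proximal_distance must be in 2..10")


@dataclass
class TruthPair:
    gene_a: str
    gene_b: str
    mode: str
    family_id: str
    identity: float  # realized pairwise aa identity (%)
    planted_ks: float

    def __post_init__(self) -> None:
        if self.gene_a > self.gene_b:
            self.gene_a, self.gene_b = self.gene_b, self.gene_a


@dataclass
class TruthHsdFamily:
    family_id: str
    members: frozenset[str]
    target_identity: float
    mode: str


@dataclass
class TruthLedger:
    """Ground truth for one simulated bundle."""

    pairs: list[TruthPair] = field(default_factory=list)
    hsd_families: list[TruthHsdFamily] = field(default_factory=list)
    wgd_anchor_genes: set[str] = field(default_factory=set)
    n_homology_rows: int = 0
    sum_align_len: int = 0
    n_gene_pairs: int = 0  # distinct significant non-self unordered gene pairs
    domain_length_sums: dict[str, int] = field(default_factory=dict)

    def mode_counts(self) -> dict[str, int]:
        out = {m: 0 for m in MODES}
        for p in self.pairs:
            out[p.mode] += 1
        return out

    def pair_modes(self) -> dict[tuple[str, str], str]:
        return {tuple(sorted((p.gene_a, p.gene_b))): p.mode for p in self.pairs}


@dataclass
class SimBundle:
    config: SimConfig
    out_dir: Path
    paths: dict[str, Path]
    ledger: TruthLedger


# ---------------------------------------------------------------------------
# sequence helpers
# ---------------------------------------------------------------------------


def _syn_variants(codon: str) -> list[str]:
    aa = translate_codon(codon)
    out = []
    for pos in range(3):
        for b in "ACGT":
            if b == codon[pos]:
                continue
            m = codon[:pos] + b + codon[pos + 1 :]
            if m not in STOP_CODONS and translate_codon(m) == aa:
                out.append(m)
    return out


def _nonsyn_variants(codon: str) -> list[str]:
    aa = translate_codon(codon)
    out = []
    for pos in range(3):
        for b in "ACGT":
            if b == codon[pos]:
                continue
            m = codon[:pos] + b + codon[pos + 1 :]
            if m not in STOP_CODONS and translate_codon(m) != aa:
                out.append(m)
    return out


def _random_codons(rng: np.random.Generator, n: int) -> list[str]:
    idx = rng.integers(0, len(_CODONS), size=n)
    return [_CODONS[i] for i in idx]


def _syn_sites(codons: list[str]) -> float:
    return sum(_codon_sites(c)[0] for c in codons)


def _ps_for_ks(ks: float) -> float:
    """Invert the Jukes-Cantor correction: proportion for a target rate."""
    return 0.75 * (1.0 - math.exp(-4.0 * ks / 3.0))


def _mutate_copy(
    ancestor: list[str],
    pool: list[int],
    n_nonsyn: int,
    n_syn: int,
    rng: np.random.Generator,
) -> tuple[list[str], int, int]:
    """Mutate one family copy inside its private codon pool.

    Applies at most one substitution per codon: first ``n_nonsyn``
    amino-acid-changing single-nucleotide changes, then ``n_syn``
    synonymous ones, skipping codons lacking a suitable variant.
    Returns (codons, realized nonsyn count, realized syn count).
    """
    codons = list(ancestor)
    pool = list(pool)
    rng.shuffle(pool)
    done_nonsyn = done_syn = 0
    remaining = []
    for i in pool:
        if done_nonsyn >= n_nonsyn:
            remaining.append(i)
            continue
        variants = _nonsyn_variants(codons[i])
        if variants:
            codons[i] = variants[rng.integers(0, len(variants))]
            done_nonsyn += 1
        else:
            remaining.append(i)
    for i in remaining:
        if done_syn >= n_syn:
            break
        variants = _syn_variants(codons[i])
        if variants:
            codons[i] = variants[rng.integers(0, len(variants))]
            done_syn += 1
    return codons, done_nonsyn, done_syn


def _make_family(
    spec_identity: float,
    target_ks: float,
    n_copies: int,
    length: int,
    rng: np.random.Generator,
) -> list[list[str]]:
    """Generate ``n_copies`` codon sequences around one random ancestor.

    Each copy receives half the target pairwise divergence inside its
    own codon pool, so divergence between any two copies is additive.
    """
    ancestor = _random_codons(rng, length)
    n_nonsyn_half = round((1.0 - spec_identity / 100.0) / 2.0 * length)
    S = _syn_sites(ancestor)
    sd_target = _ps_for_ks(target_ks) * S
    n_syn_half = round(sd_target / 2.0)
    pool_order = list(rng.permutation(length))
    size = length // n_copies
    copies = []
    for c in range(n_copies):
        pool = pool_order[c * size : (c + 1) * size]
        need = n_nonsyn_half + n_syn_half
        if len(pool) < need:
            raise ValueError(
                f"family length {length} too short for {n_copies} copies at "
                f"identity {spec_identity}% / Ks {target_ks}"
            )
        codons, _, _ = _mutate_copy(ancestor, pool, n_nonsyn_half, n_syn_half, rng)
        copies.append(codons)
    return copies


def _diverged_copy(
    ancestor_like: list[str], identity: float, rng: np.random.Generator
) -> list[str]:
    n_nonsyn = round((1.0 - identity / 100.0) * len(ancestor_like))
    pool = list(range(len(ancestor_like)))
    codons, _, _ = _mutate_copy(ancestor_like, pool, n_nonsyn, 0, rng)
    return codons


# ---------------------------------------------------------------------------
# placement
# ---------------------------------------------------------------------------


class _Placer:
    """Allocate gene-slot runs so that no two features sharing an anchor
    grid can be bridged by a chain step (separation > max_gap_genes)."""

    def __init__(self, n_chrom: int, n_genes: int, max_gap: int):
        self.n_genes = n_genes
        self.sep = max_gap + 2
        self.cross_cursor = {c: 0 for c in range(n_chrom)}  # grows upward
        self.tail_cursor = {c: n_genes - 1 for c in range(n_chrom)}  # shrinks
        self.cross_max_used = {c: -1 for c in range(n_chrom)}
        self.tail_min_used = {c: n_genes for c in range(n_chrom)}

    def cross_run(self, chrom: int, length: int) -> list[int]:
        start = self.cross_cursor[chrom]
        end = start + length - 1
        if end >= self.tail_min_used[chrom] or end >= self.n_genes:
            raise ValueError(
                "cannot place planted features: increase genes_per_chromosome"
            )
        self.cross_cursor[chrom] = end + self.sep
        self.cross_max_used[chrom] = max(self.cross_max_used[chrom], end)
        return list(range(start, end + 1))

    def tail_run(self, chrom: int, length: int) -> list[int]:
        end = self.tail_cursor[chrom]
        start = end - length + 1
        if start <= self.cross_max_used[chrom] or start < 0:
            raise ValueError(
                "cannot place planted features: increase genes_per_chromosome"
            )
        self.tail_cursor[chrom] = start - self.sep
        self.tail_min_used[chrom] = min(self.tail_min_used[chrom], start)
        return list(range(start, end + 1))


# ---------------------------------------------------------------------------
# alignment-backed homology table
# ---------------------------------------------------------------------------

_KMER = 6


def _seed_candidates(
    prots_a: dict[str, str], prots_b: dict[str, str] | None = None
) -> list[tuple[str, str]]:
    """Pairs sharing at least one exact 6-mer (BLAST-style seeding)."""
    same = prots_b is None
    if same:
        prots_b = prots_a
    index: dict[str, list[str]] = {}
    for name, seq in prots_b.items():
        for i in range(len(seq) - _KMER + 1):
            index.setdefault(seq[i : i + _KMER], []).append(name)
    pairs: set[tuple[str, str]] = set()
    for name, seq in prots_a.items():
        hits: set[str] = set()
        for i in range(len(seq) - _KMER + 1):
            hits.update(index.get(seq[i : i + _KMER], ()))
        for other in hits:
            if same:
                if other == name:
                    continue
                pairs.add(tuple(sorted((name, other))))
            else:
                pairs.add((name, other))
    return sorted(pairs)


def _align_stats(aligner: PairwiseAligner, sa: str, sb: str):
    aln = aligner.align(sa, sb)[0]
    ra, rb = str(aln[0]), str(aln[1])
    ident = mismatch = gap_opens = 0
    in_gap = False
    for x, y in zip(ra, rb):
        if x == "-" or y == "-":
            if not in_gap:
                gap_opens += 1
            in_gap = True
            continue
        in_gap = False
        if x == y:
            ident += 1
        else:
            mismatch += 1
    align_len = len(ra)
    pident = 100.0 * ident / align_len if align_len else 0.0
    bitscore = max(aln.score / 2.0, 1.0)
    evalue = len(sa) * len(sb) * math.pow(2.0, -min(bitscore, 1000.0))
    return pident, align_len, mismatch, gap_opens, evalue, bitscore


def _homology_rows(
    prots_a: dict[str, str],
    prots_b: dict[str, str] | None = None,
    with_self: bool = True,
) -> list[tuple]:
    """All-vs-all outfmt-6 rows from true global alignments.

    Intra mode (prots_b None) emits both directions of every candidate
    pair plus perfect self-hits; cross mode emits a->b rows only.
    """
    aligner = PairwiseAligner(scoring=None)
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.mode = "global"
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5

    rows = []
    intra = prots_b is None
    for a, b in _seed_candidates(prots_a, prots_b):
        sa = prots_a[a]
        sb = (prots_a if intra else prots_b)[b]
        pident, alen, mm, go, ev, bits = _align_stats(aligner, sa, sb)
        rows.append((a, b, pident, alen, mm, go, 1, len(sa), 1, len(sb), ev, bits))
        if intra:
            rows.append((b, a, pident, alen, mm, go, 1, len(sb), 1, len(sa), ev, bits))
    if intra and with_self:
        for a, sa in prots_a.items():
            bits = max(
                sum(
                    aligner.substitution_matrix[res, res] for res in sa
                )
                / 2.0,
                1.0,
            )
            ev = len(sa) * len(sa) * math.pow(2.0, -min(bits, 1000.0))
            rows.append((a, a, 100.0, len(sa), 0, 0, 1, len(sa), 1, len(sa), ev, bits))
    rows.sort(key=lambda r: (r[0], r[10], r[1]))
    return rows


def _write_blast(rows: list[tuple], path: Path) -> None:
    with open(path, "w") as fh:
        for r in rows:
            fh.write(
                f"{r[0]}\t{r[1]}\t{r[2]:.1f}\t{r[3]}\t{r[4]}\t{r[5]}\t{r[6]}\t"
                f"{r[7]}\t{r[8]}\t{r[9]}\t{r[10]:.3e}\t{r[11]:.1f}\n"
            )


# ---------------------------------------------------------------------------
# main generator
# ---------------------------------------------------------------------------


@dataclass
class _Gene:
    gene_id: str
    chrom: str
    slot: int
    codons: list[str]  # without stop codon
    domains: list[tuple[str, int, int]] = field(default_factory=list)  # acc,s,e
    ko: str = ""
    decoy: bool = False

    @property
    def protein(self) -> str:
        return "".join(translate_codon(c) for c in self.codons)

    @property
    def protein_id(self) -> str:
        return f"{self.gene_id}.p1"


def simulate(config: SimConfig, out_dir: str | Path) -> SimBundle:
    """Generate a synthetic genome bundle plus truth ledger.

    Writes (under ``out_dir``): ``genome.gff3``, ``proteins.faa``,
    ``cds.fna``, ``self.blast.tsv``, ``interproscan.tsv``, ``ko.tsv``,
    the truth TSVs, and, with an outgroup, ``outgroup.gff3``,
    ``outgroup.faa`` and ``outgroup.blast.tsv``.  Fully deterministic
    for a fixed config (byte-identical reruns).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    n_chrom, n_genes = config.n_chromosomes, config.genes_per_chromosome
    chrom_names = [f"chr{i + 1}" for i in range(n_chrom)]

    def gene_id(chrom_idx: int, slot: int) -> str:
        return f"{chrom_names[chrom_idx]}g{slot + 1:04d}"

    # background genes everywhere; planted slots overwritten below
    genes: dict[tuple[int, int], _Gene] = {}
    lo, hi = config.background_length_range
    for c in range(n_chrom):
        for s in range(n_genes):
            L = int(rng.integers(lo, hi + 1))
            genes[(c, s)] = _Gene(gene_id(c, s), chrom_names[c], s, _random_codons(rng, L))

    placer = _Placer(n_chrom, n_genes, config.max_gap_genes)
    ledger = TruthLedger()
    outgroup_regions: list[tuple[int, list[int]]] = []  # (chrom idx, slots)

    def cross_chrom_pair(i: int) -> tuple[int, int]:
        a = i % n_chrom
        return a, (a + 1) % n_chrom

    cross_i = 0
    same_i = 0
    fam_hsd_members: dict[str, list[str]] = {}
    for fam_idx, spec in enumerate(config.planted):
        fam_id = f"fam{fam_idx + 1}_{spec.mode}"
        if spec.mode == "WGD":
            ca, cb = cross_chrom_pair(cross_i)
            cross_i += 1
            slots_a = placer.cross_run(ca, spec.family_size)
            slots_b = placer.cross_run(cb, spec.family_size)
            for k, (sa, sb) in enumerate(zip(slots_a, slots_b)):
                pair_fam = f"{fam_id}_a{k + 1}"
                copies = _make_family(
                    spec.target_identity,
                    spec.target_ks,
                    2,
                    config.family_protein_length,
                    rng,
                )
                ga, gb = gene_id(ca, sa), gene_id(cb, sb)
                genes[(ca, sa)].codons = copies[0]
                genes[(cb, sb)].codons = copies[1]
                ledger.wgd_anchor_genes.update((ga, gb))
                ledger.pairs.append(
                    TruthPair(ga, gb, "WGD", pair_fam, 0.0, spec.target_ks)
                )
            continue

        if spec.mode in ("TD", "PD"):
            chrom = same_i % n_chrom
            same_i += 1
            if spec.mode == "TD":
                n_extra = 1 if spec.diverged_extra else 0
                slots = placer.tail_run(chrom, spec.family_size + n_extra)
                fam_slots = slots[:spec.family_size]
            else:
                span = (spec.family_size - 1) * config.proximal_distance + 1
                slots = placer.tail_run(chrom, span)
                fam_slots = slots[:: config.proximal_distance]
            copies = _make_family(
                spec.target_identity,
                spec.target_ks,
                len(fam_slots),
                config.family_protein_length,
                rng,
            )
            ids = []
            for codons, s in zip(copies, fam_slots):
                genes[(chrom, s)].codons = codons
                ids.append(gene_id(chrom, s))
            for i in range(len(fam_slots)):
                for j in range(i + 1, len(fam_slots)):
                    d = abs(fam_slots[i] - fam_slots[j])
                    mode = "TD" if d == 1 else ("PD" if d <= 10 else "DD")
                    ledger.pairs.append(
                        TruthPair(
                            ids[i], ids[j], mode, fam_id, 0.0, spec.target_ks
                        )
                    )
            fam_hsd_members[fam_id] = ids
            ledger.hsd_families.append(
                TruthHsdFamily(fam_id, frozenset(ids), spec.target_identity, spec.mode)
            )
            if spec.diverged_extra:
                ds = slots[spec.family_size]
                genes[(chrom, ds)].codons = _diverged_copy(copies[0], 62.0, rng)
                did = gene_id(chrom, ds)
                for i, s in enumerate(fam_slots):
                    d = abs(s - ds)
                    mode = "TD" if d == 1 else ("PD" if d <= 10 else "DD")
                    ledger.pairs.append(
                        TruthPair(ids[i], did, mode, f"{fam_id}_div", 62.0, 1.5)
                    )
            continue

        # cross-chromosome singleton-copy modes: TRD and DD
        ca, cb = cross_chrom_pair(cross_i)
        cross_i += 1
        if spec.mode == "TRD":
            region = placer.cross_run(ca, config.outgroup_region_len)
            slot_a = region[len(region) // 2]
            outgroup_regions.append((ca, region))
        else:
            slot_a = placer.cross_run(ca, 1)[0]
        slot_b = placer.cross_run(cb, 1)[0]
        copies = _make_family(
            spec.target_identity,
            spec.target_ks,
            2,
            config.family_protein_length,
            rng,
        )
        genes[(ca, slot_a)].codons = copies[0]
        genes[(cb, slot_b)].codons = copies[1]
        ga, gb = gene_id(ca, slot_a), gene_id(cb, slot_b)
        ledger.pairs.append(TruthPair(ga, gb, spec.mode, fam_id, 0.0, spec.target_ks))
        fam_hsd_members[fam_id] = [ga, gb]
        ledger.hsd_families.append(
            TruthHsdFamily(fam_id, frozenset((ga, gb)), spec.target_identity, spec.mode)
        )

    # --- domains and KOs ---------------------------------------------------
    domain_vocab = [f"PF{i + 1:05d}" for i in range(config.n_domain_types)]
    ko_vocab = [f"K{i + 1:05d}" for i in range(config.n_ko_types)]
    fam_of_gene: dict[str, str] = {}
    for fam, members in fam_hsd_members.items():
        for g in members:
            fam_of_gene[g] = fam
    for p in ledger.pairs:  # WGD + diverged members share family domains too
        fam_of_gene.setdefault(p.gene_a, p.family_id)
        fam_of_gene.setdefault(p.gene_b, p.family_id)

    fam_domains: dict[str, list[tuple[str, int, int]]] = {}
    fam_ko: dict[str, str] = {}
    for key in sorted({f.split("_a")[0].replace("_div", "") for f in fam_of_gene.values()}):
        acc = domain_vocab[int(rng.integers(0, len(domain_vocab)))]
        start = int(rng.integers(5, 30))
        length = int(rng.integers(40, 90))
        fam_domains[key] = [(acc, start, start + length - 1)]
        fam_ko[key] = ko_vocab[int(rng.integers(0, len(ko_vocab)))]

    for (c, s), g in genes.items():
        fam = fam_of_gene.get(g.gene_id)
        if fam is not None:
            key = fam.split("_a")[0].replace("_div", "")
            g.domains = list(fam_domains[key])
            g.ko = fam_ko[key]
        else:
            if rng.random() < 0.7:
                acc = domain_vocab[int(rng.integers(0, len(domain_vocab)))]
                plen = len(g.codons)
                start = int(rng.integers(1, max(2, plen // 3)))
                end = min(plen, start + int(rng.integers(30, 80)))
                g.domains = [(acc, start, end)]
            if rng.random() < config.ko_background_rate:
                g.ko = ko_vocab[int(rng.integers(0, len(ko_vocab)))]

    # decoy short isoforms on the first background genes of chr1
    decoys: list[_Gene] = []
    n_decoys = 0
    for s in range(n_genes):
        if n_decoys >= config.n_decoy_isoforms:
            break
        g = genes[(0, s)]
        if g.gene_id in fam_of_gene:
            continue
        g.decoy = True
        n_decoys += 1

    # --- outgroup genome ---------------------------------------------------
    og_genes: list[_Gene] = []
    if config.outgroup:
        for r, (c, region) in enumerate(outgroup_regions):
            chrom = f"og{r + 1}"
            for k, s in enumerate(region):
                src = genes[(c, s)]
                n_nonsyn = round(
                    (1.0 - config.outgroup_identity / 100.0) * len(src.codons)
                )
                codons, _, _ = _mutate_copy(
                    src.codons, list(range(len(src.codons))), n_nonsyn, 0, rng
                )
                og_genes.append(_Gene(f"{chrom}g{k + 1:03d}", chrom, k, codons))

    # --- emit files --------------------------------------------------------
    focal = [genes[(c, s)] for c in range(n_chrom) for s in range(n_genes)]
    paths: dict[str, Path] = {}

    proteins: dict[str, str] = {}
    cds: dict[str, str] = {}
    for g in focal:
        proteins[g.protein_id] = g.protein
        cds[g.protein_id] = "".join(g.codons) + "TAA"
        if g.decoy:
            half = len(g.codons) // 2
            pid2 = f"{g.gene_id}.p2"
            proteins[pid2] = "".join(translate_codon(c) for c in g.codons[:half])
            cds[pid2] = "".join(g.codons[:half]) + "TAA"

    paths["gff"] = out_dir / "genome.gff3"
    _write_gff(focal, paths["gff"])
    paths["proteins"] = out_dir / "proteins.faa"
    write_fasta(proteins, paths["proteins"])
    paths["cds"] = out_dir / "cds.fna"
    write_fasta(cds, paths["cds"])

    # homology: all-vs-all on every protein (isoforms included)
    rows = _homology_rows(proteins)
    paths["blast"] = out_dir / "self.blast.tsv"
    _write_blast(rows, paths["blast"])
    ledger.n_homology_rows = len(rows)
    ledger.sum_align_len = sum(r[3] for r in rows)

    # significant distinct gene pairs among primary proteins (generator-side
    # arithmetic, independent of the preprocess implementation)
    prim = {g.protein_id for g in focal}
    sig: set[tuple[str, str]] = set()
    realized_ident: dict[tuple[str, str], float] = {}
    for r in rows:
        if r[0] == r[1] or r[0] not in prim or r[1] not in prim:
            continue
        ga, gb = r[0].rsplit(".p", 1)[0], r[1].rsplit(".p", 1)[0]
        key = tuple(sorted((ga, gb)))
        if r[10] <= 1e-10:
            sig.add(key)
            realized_ident[key] = max(realized_ident.get(key, 0.0), r[2])
    ledger.n_gene_pairs = len(sig)
    for p in ledger.pairs:
        p.identity = realized_ident.get(tuple(sorted((p.gene_a, p.gene_b))), 0.0)

    # domain + KO tables
    paths["interproscan"] = out_dir / "interproscan.tsv"
    with open(paths["interproscan"], "w") as fh:
        for g in focal:
            plen = len(g.codons)
            for acc, dstart, dend in g.domains:
                dend = min(dend, plen)
                ledger.domain_length_sums[g.protein_id] = (
                    ledger.domain_length_sums.get(g.protein_id, 0) + (dend - dstart + 1)
                )
                fh.write(
                    f"{g.protein_id}\tmd5\t{plen}\tPfam\t{acc}\t{acc} domain\t"
                    f"{dstart}\t{dend}\t1e-30\tT\t01-01-2000\tIPR{acc[2:]}\t"
                    f"{acc} family\n"
                )
    paths["ko"] = out_dir / "ko.tsv"
    with open(paths["ko"], "w") as fh:
        for g in focal:
            fh.write(f"{g.gene_id}\t{g.ko}\n")

    if config.outgroup:
        paths["outgroup_gff"] = out_dir / "outgroup.gff3"
        _write_gff(og_genes, paths["outgroup_gff"])
        og_prot = {g.protein_id: g.protein for g in og_genes}
        paths["outgroup_proteins"] = out_dir / "outgroup.faa"
        write_fasta(og_prot, paths["outgroup_proteins"])
        og_rows = _homology_rows(proteins, og_prot)
        paths["outgroup_blast"] = out_dir / "outgroup.blast.tsv"
        _write_blast(og_rows, paths["outgroup_blast"])

    _write_truth(ledger, out_dir, paths)
    return SimBundle(config=config, out_dir=out_dir, paths=paths, ledger=ledger)


def _write_gff(gene_list: list[_Gene], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        by_chrom: dict[str, list[_Gene]] = {}
        for g in gene_list:
            by_chrom.setdefault(g.chrom, []).append(g)
        for chrom in by_chrom:
            by_chrom[chrom].sort(key=lambda g: g.slot)
            for g in by_chrom[chrom]:
                start = 1 + g.slot * 2000
                cds_nt = 3 * (len(g.codons) + 1)  # incl. stop codon
                end = start + cds_nt - 1
                gid, tid, pid = g.gene_id, f"{g.gene_id}.t1", g.protein_id
                fh.write(
                    f"{chrom}\thsdkit_sim\tgene\t{start}\t{end}\t.\t+\t.\tID={gid}\n"
                )
                fh.write(
                    f"{chrom}\thsdkit_sim\tmRNA\t{start}\t{end}\t.\t+\t.\t"
                    f"ID={tid};Parent={gid}\n"
                )
                fh.write(
                    f"{chrom}\thsdkit_sim\tCDS\t{start}\t{end}\t.\t+\t0\t"
                    f"ID={tid}.cds;Parent={tid};protein_id={pid}\n"
                )
                if g.decoy:
                    half_nt = 3 * (len(g.codons) // 2 + 1)
                    tid2, pid2 = f"{g.gene_id}.t2", f"{g.gene_id}.p2"
                    fh.write(
                        f"{chrom}\thsdkit_sim\tmRNA\t{start}\t{start + half_nt - 1}"
                        f"\t.\t+\t.\tID={tid2};Parent={gid}\n"
                    )
                    fh.write(
                        f"{chrom}\thsdkit_sim\tCDS\t{start}\t{start + half_nt - 1}"
                        f"\t.\t+\t0\tID={tid2}.cds;Parent={tid2};protein_id={pid2}\n"
                    )


def _write_truth(ledger: TruthLedger, out_dir: Path, paths: dict[str, Path]) -> None:
    paths["truth_pairs"] = out_dir / "truth.pairs.tsv"
    with open(paths["truth_pairs"], "w") as fh:
        fh.write("gene_a\tgene_b\tmode\tfamily\tidentity\tplanted_ks\n")
        for p in sorted(ledger.pairs, key=lambda p: (p.gene_a, p.gene_b)):
            fh.write(
                f"{p.gene_a}\t{p.gene_b}\t{p.mode}\t{p.family_id}\t"
                f"{p.identity:.1f}\t{p.planted_ks:.3f}\n"
            )
    paths["truth_hsds"] = out_dir / "truth.hsds.tsv"
    with open(paths["truth_hsds"], "w") as fh:
        fh.write("family\tmembers\ttarget_identity\tmode\n")
        for f in sorted(ledger.hsd_families, key=lambda f: f.family_id):
            fh.write(
                f"{f.family_id}\t{','.join(sorted(f.members))}\t"
                f"{f.target_identity:.1f}\t{f.mode}\n"
            )
    paths["truth_meta"] = out_dir / "truth.meta.tsv"
    with open(paths["truth_meta"], "w") as fh:
        fh.write("key\tvalue\n")
        fh.write(f"n_homology_rows\t{ledger.n_homology_rows}\n")
        fh.write(f"sum_align_len\t{ledger.sum_align_len}\n")
        fh.write(f"n_gene_pairs\t{ledger.n_gene_pairs}\n")
        for mode, n in ledger.mode_counts().items():
            fh.write(f"n_pairs_{mode}\t{n}\n")
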