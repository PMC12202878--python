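"""Highly similar duplicate gene (HSD) detection, curation and summaries.

An HSD group is a set of >= 2 gene copies in one genome joined by
pairwise amino-acid identity above a threshold, full protein-length
difference below a threshold, and consistent conserved-domain content.
Groups are single-linkage connected components of the qualifying-pair
graph: two copies belong together if a chain of qualifying pairs links
them.  Thresholds are written in the ``70%_30aa`` notation (min 70%
identity, at most 30 aa length difference).

Curation follows the add-on rule: groups from a relaxed threshold are
appended to a stricter run unless their member set duplicates or is
contained in an existing group; folding over a strict-to-relaxed grid
assembles the curated dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .io_formats import DomainAnnotation, HomologyHit, KoAnnotation


@dataclass(frozen=True)
class HsdThreshold:
    """(min identity %, max full-length protein difference in aa)."""

    min_identity: float = 90.0
    max_len_diff: int = 10

    def __post_init__(self) -> None:
        if not 50 <= self.min_identity <= 100:
            raise ValueError("min_identity must be in [50, 100]")
        if not 10 <= self.max_len_diff <= 100:
            raise ValueError("max_len_diff must be in [10, 100]")

    @property
    def tag(self) -> str:
        ident = (
            f"{self.min_identity:g}"
            if self.min_identity != int(self.min_identity)
            else f"{int(self.min_identity)}"
        )
        return f"{ident}%_{self.max_len_diff}aa"


@dataclass
class HSDGroup:
    """A detected HSD: >= 2 near-identical gene copies at one threshold."""

    hsd_id: str
    members: frozenset[str]
    threshold: HsdThreshold
    domain_signature: tuple[tuple[str, int], ...] = ()
    ko_ids: frozenset[str] = frozenset()

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class HsdStatistics:
    threshold_tag: str
    n_hsds: int
    n_gene_copies: int  # with multiplicity across groups
    n_nonredundant_copies: int  # distinct genes


@dataclass
class HsdCategoryCounts:
    threshold_tag: str
    counts: dict[str, int]  # keys "2", "3", ">3"


@dataclass
class HeatmapMatrix:
    """KO-by-label incidence counts (rows KO ids + 'unannotated')."""

    table: pd.DataFrame

    @property
    def row_labels(self) -> list[str]:
        return list(self.table.index)

    @property
    def column_labels(self) -> list[str]:
        return list(self.table.columns)


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------


def domain_signature(
    protein_id: str,
    domains: Mapping[str, list[DomainAnnotation]],
    analyses: Sequence[str] = ("Pfam",),
) -> tuple[tuple[str, int], ...]:
    """Sorted (signature accession, domain length) multiset for a protein,
    restricted to the given analysis subset."""
    rows = [
        d
        for d in domains.get(protein_id, [])
        if not analyses or d.analysis in analyses
    ]
    return tuple(sorted((d.signature_acc, d.length) for d in rows))


def domains_consistent(
    sig_a: tuple[tuple[str, int], ...],
    sig_b: tuple[tuple[str, int], ...],
    domain_tol: int = 10,
) -> bool:
    """True when both proteins carry the same multiset of signature
    accessions and each matching domain's length differs by <= tol.

    Two proteins with no domain annotation at all are consistent; a
    domain-bearing and a domain-free protein are not.
    """
    accs_a = [acc for acc, _ in sig_a]
    accs_b = [acc for acc, _ in sig_b]
    if accs_a != accs_b:  # both sorted, so multiset equality
        return False
    by_acc_a: dict[str, list[int]] = {}
    by_acc_b: dict[str, list[int]] = {}
    for acc, ln in sig_a:
        by_acc_a.setdefault(acc, []).append(ln)
    for acc, ln in sig_b:
        by_acc_b.setdefault(acc, []).append(ln)
    for acc, lens_a in by_acc_a.items():
        for la, lb in zip(sorted(lens_a), sorted(by_acc_b[acc])):
            if abs(la - lb) > domain_tol:
                return False
    return True


def detect_hsds(
    pairs: Iterable,
    hits: Iterable[HomologyHit] | None,
    protein_lengths: Mapping[str, int],
    domains: Mapping[str, list[DomainAnnotation]] | None,
    thr: HsdThreshold,
    domain_tol: int = 10,
    analyses: Sequence[str] = ("Pfam",),
    ignore_domains: bool = False,
    ko_map: Mapping[str, set[str]] | None = None,
) -> list[HSDGroup]:
    """Detect HSD groups at one (identity, length-difference) threshold.

    An edge joins genes a and b iff some retained hit between them has
    pident >= thr.min_identity, the full protein lengths differ by at
    most thr.max_len_diff aa, and the two genes' domain content is
    consistent (same signature multiset, per-domain length within
    ``domain_tol``; ``ignore_domains=True`` reproduces similarity-only
    behavior).  Groups are connected components with >= 2 members.

    ``pairs`` restricts the candidate pair universe (e.g. one
    duplication mode's pairs); pident is read from ``hits`` when given,
    else from the pairs' own ``max_pident``.
    """
    pident: dict[tuple[str, str], float] = {}
    if hits is not None:
        for h in hits:
            key = tuple(sorted((h.query_id, h.subject_id)))
            if key[0] == key[1]:
                continue
            pident[key] = max(pident.get(key, 0.0), h.pident)

    domains = domains or {}
    sig_cache: dict[str, tuple[tuple[str, int], ...]] = {}

    def sig(g: str) -> tuple[tuple[str, int], ...]:
        if g not in sig_cache:
            sig_cache[g] = domain_signature(g, domains, analyses)
        return sig_cache[g]

    graph = nx.Graph()
    for pair in pairs:
        if hasattr(pair, "gene_a"):
            a, b = pair.gene_a, pair.gene_b
            own_pident = getattr(pair, "max_pident", None)
        else:
            a, b = pair[0], pair[1]
            own_pident = None
        if a == b:
            continue
        key = tuple(sorted((a, b)))
        ident = pident.get(key, own_pident)
        if ident is None or ident < thr.min_identity:
            continue
        la, lb = protein_lengths.get(a), protein_lengths.get(b)
        if la is None or lb is None or abs(la - lb) > thr.max_len_diff:
            continue
        if not ignore_domains and not domains_consistent(sig(a), sig(b), domain_tol):
            continue
        graph.add_edge(a, b)

    groups: list[HSDGroup] = []
    for comp in nx.connected_components(graph):
        if len(comp) < 2:
            continue
        members = frozenset(comp)
        rep = min(members)
        kos = frozenset()
        if ko_map:
            kos = frozenset(k for g in members for k in ko_map.get(g, ()) if k)
        groups.append(
            HSDGroup(
                hsd_id=f"{rep}|{thr.tag}",
                members=members,
                threshold=thr,
                domain_signature=sig(rep),
                ko_ids=kos,
            )
        )
    groups.sort(key=lambda g: g.hsd_id)
    return groups


# ---------------------------------------------------------------------------
# curation
# ---------------------------------------------------------------------------


def add_on(strict_groups: list[HSDGroup], relaxed_groups: list[HSDGroup]) -> list[HSDGroup]:
    """Merge a relaxed-threshold run into a strict one.

    Keeps every strict group; appends each relaxed group whose member
    set is neither equal to nor a subset of any strict group's member
    set; never emits two groups with identical member sets.
    """
    out = list(strict_groups)
    kept_sets = {g.members for g in strict_groups}
    for g in relaxed_groups:
        if g.members in kept_sets:
            continue
        if any(g.members <= s.members for s in strict_groups):
            continue
        out.append(g)
        kept_sets.add(g.members)
    return out


def batch_run(
    thresholds: Sequence[HsdThreshold],
    detect: Callable[[HsdThreshold], list[HSDGroup]],
) -> tuple[list[HSDGroup], dict[str, int]]:
    """Fold :func:`add_on` over a strict-to-relaxed threshold grid.

    ``detect`` maps a threshold to its groups (usually a closure over
    :func:`detect_hsds` inputs).  Returns the merged group list and a
    ledger of groups contributed per threshold tag; contributions sum to
    the merged size.
    """
    if not thresholds:
        raise ValueError("threshold grid is empty")
    merged: list[HSDGroup] = []
    ledger: dict[str, int] = {}
    for thr in thresholds:
        groups = detect(thr)
        new = add_on(merged, groups) if merged else list(groups)
        ledger[thr.tag] = len(new) - len(merged)
        merged = new
    return merged, ledger


# ---------------------------------------------------------------------------
# statistics / categories / heatmap
# ---------------------------------------------------------------------------


def hsd_statistics(groups: Sequence[HSDGroup], threshold_tag: str = "") -> HsdStatistics:
    tag = threshold_tag or (groups[0].threshold.tag if groups else "")
    copies = sum(g.size for g in groups)
    distinct = len({m for g in groups for m in g.members})
    return HsdStatistics(
        threshold_tag=tag,
        n_hsds=len(groups),
        n_gene_copies=copies,
        n_nonredundant_copies=distinct,
    )


def hsd_categories(groups: Sequence[HSDGroup], threshold_tag: str = "") -> HsdCategoryCounts:
    """Bucket groups by copy number into {2, 3, >3}; counts sum to n_hsds."""
    tag = threshold_tag or (groups[0].threshold.tag if groups else "")
    counts = {"2": 0, "3": 0, ">3": 0}
    for g in groups:
        if g.size == 2:
            counts["2"] += 1
        elif g.size == 3:
            counts["3"] += 1
        else:
            counts[">3"] += 1
    return HsdCategoryCounts(threshold_tag=tag, counts=counts)


UNANNOTATED = "unannotated"


def build_ko_heatmap(
    group_sets: Mapping[str, Sequence[HSDGroup]],
    ko_table: Iterable[KoAnnotation] | Mapping[str, set[str]],
) -> HeatmapMatrix:
    """Count, per (KO, label), the HSD groups under that label with >= 1
    member gene carrying that KO.

    A group annotated to several KOs increments each once; a group with
    no annotated member counts in the 'unannotated' row.  Labels are
    species names or duplication-mode names.
    """
    if isinstance(ko_table, Mapping):
        ko_map = {g: {k for k in ks if k} for g, ks in ko_table.items()}
    else:
        ko_map = {}
        for rec in ko_table:
            if rec.ko_id:
                ko_map.setdefault(rec.gene_id, set()).add(rec.ko_id)

    cells: dict[str, dict[str, int]] = {}
    all_kos: set[str] = set()
    for label, groups in group_sets.items():
        col = cells.setdefault(label, {})
        for g in groups:
            kos = {k for m in g.members for k in ko_map.get(m, ())} or g.ko_ids
            if not kos:
                col[UNANNOTATED] = col.get(UNANNOTATED, 0) + 1
                continue
            for ko in kos:
                col[ko] = col.get(ko, 0) + 1
                all_kos.add(ko)

    rows = sorted(all_kos) + [UNANNOTATED]
    cols = list(group_sets)
    data = {
        label: [cells.get(label, {}).get(r, 0) for r in rows] for label in cols
    }
    return HeatmapMatrix(pd.DataFrame(data, index=rows, columns=cols, dtype=int))


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def write_hsd_table(groups: Sequence[HSDGroup], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("hsd_id\tthreshold\tn_copies\tmembers\tdomain_signature\tko_ids\n")
        for g in groups:
            doms = ";".join(f"{acc}:{ln}" for acc, ln in g.domain_signature)
            fh.write(
                f"{g.hsd_id}\t{g.threshold.tag}\t{g.size}\t"
                f"{','.join(sorted(g.members))}\t{doms}\t"
                f"{','.join(sorted(g.ko_ids))}\n"
            )


def write_statistics(stats: Sequence[HsdStatistics], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("threshold\tn_hsds\tgene_copies\tnonredundant_copies\n")
        for s in stats:
            fh.write(
                f"{s.threshold_tag}\t{s.n_hsds}\t{s.n_gene_copies}\t"
                f"{s.n_nonredundant_copies}\n"
            )


def write_categories(cats: Sequence[HsdCategoryCounts], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("threshold\tcopies_2\tcopies_3\tcopies_gt3\n")
        for c in cats:
            fh.write(
                f"{c.threshold_tag}\t{c.counts['2']}\t{c.counts['3']}\t"
                f"{c.counts['>3']}\n"
            )


def write_heatmap_tsv(matrix: HeatmapMatrix, path: str | Path) -> None:
    matrix.table.to_csv(path, sep="\t", index_label="ko")


def plot_heatmap(matrix: HeatmapMatrix, path: str | Path, max_rows: int = 60) -> None:
    """Render the KO incidence matrix (top rows by total count) to file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    tab = matrix.table
    if len(tab) > max_rows:
        order = tab.sum(axis=1).sort_values(ascending=False).index[:max_rows]
        tab = tab.loc[order]
    fig, ax = plt.subplots(
        figsize=(2 + 0.6 * len(tab.columns), 1.5 + 0.22 * max(len(tab), 4))
    )
    im = ax.imshow(tab.values, aspect="auto", cmap="YlOrRd")
    ax.set_xticks(range(len(tab.columns)), tab.columns, rotation=45, ha="right")
    ax.set_yticks(range(len(tab)), tab.index, fontsize=6)
    fig.colorbar(im, ax=ax, label="HSD groups sharing KO")
    fig.tight_layout()
    fig.savefig(str(path))
    plt.close(fig)
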