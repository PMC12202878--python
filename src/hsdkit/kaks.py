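"""Ka/Ks estimation for duplicate pairs and Ks-distribution decomposition.

Substitution rates are estimated with the Nei–Gojobori (1986) counting
method on codon alignments obtained by aligning the two proteins
globally and back-translating (protein alignments are more informative
than nucleotide alignments at these divergences).  Per codon, each of
the three positions contributes the fraction of its valid one-step
nucleotide changes that are synonymous to the synonymous site count;
changes creating a stop codon are not valid and the three positions are
renormalized so every codon contributes exactly 3 sites.  Differences
between codons separated by 2–3 substitutions are averaged over all
orderings of the minimal substitution paths, excluding paths that pass
through a stop codon (if every path does, all are kept and the result
is flagged).  The proportions ps = Sd/S and pn = Nd/N receive the
Jukes–Cantor multiple-hit correction d = -(3/4)·ln(1 - (4/3)p); a
proportion >= 3/4 is saturated and the corresponding rate undefined
(None), never NaN.

The Ks distribution over anchor pairs of synteny blocks is decomposed
with a Gaussian mixture fitted by EM, the component count chosen by BIC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import permutations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Data import CodonTable
from sklearn.mixture import GaussianMixture

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS = frozenset(_STANDARD.stop_codons)
_FORWARD = dict(_STANDARD.forward_table)


def translate_codon(codon: str) -> str:
    """Translate one codon; '*' for stop."""
    if codon in STOP_CODONS:
        return "*"
    return _FORWARD[codon]


# ---------------------------------------------------------------------------
# codon alignment
# ---------------------------------------------------------------------------


@dataclass
class CodonAlignment:
    """Two gap-aligned codon sequences; each row element is a codon or '---'."""

    gene_a: str
    gene_b: str
    codons_a: list[str]
    codons_b: list[str]

    def ungapped_columns(self) -> list[tuple[str, str]]:
        return [
            (ca, cb)
            for ca, cb in zip(self.codons_a, self.codons_b)
            if ca != "---" and cb != "---"
        ]


def _make_aligner(gap_open: float = 10.0, gap_extend: float = 0.5) -> PairwiseAligner:
    aligner = PairwiseAligner(scoring=None)
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.mode = "global"
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner


def _strip_stop(cds: str, prot: str, name: str) -> str:
    cds = cds.upper().replace("U", "T")
    if len(cds) == 3 * len(prot) + 3 and cds[-3:] in STOP_CODONS:
        cds = cds[:-3]
    if len(cds) != 3 * len(prot):
        raise ValueError(
            f"{name}: CDS length {len(cds)} does not match protein length "
            f"{len(prot)} (expected 3x, optionally + stop codon)"
        )
    for i in range(0, len(cds), 3):
        codon = cds[i : i + 3]
        if codon in STOP_CODONS:
            raise ValueError(f"{name}: internal stop codon at codon {i // 3 + 1}")
        if all(b in "ACGT" for b in codon) and translate_codon(codon) != prot[i // 3]:
            raise ValueError(
                f"{name}: CDS translation mismatch at codon {i // 3 + 1} "
                f"({codon} -> {translate_codon(codon)} != {prot[i // 3]})"
            )
    return cds


def align_codon_pair(
    cds_a: str,
    cds_b: str,
    prot_a: str,
    prot_b: str,
    gene_a: str = "a",
    gene_b: str = "b",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> CodonAlignment:
    """Globally align two proteins (BLOSUM62, affine gaps) and
    back-translate the alignment to codons.

    Terminal stop codons on the CDS are stripped; a CDS/protein
    translation mismatch or an internal stop raises ValueError naming
    the gene.
    """
    cds_a = _strip_stop(cds_a, prot_a, gene_a)
    cds_b = _strip_stop(cds_b, prot_b, gene_b)
    aligner = _make_aligner(gap_open, gap_extend)
    aln = aligner.align(prot_a, prot_b)[0]
    row_a, row_b = str(aln[0]), str(aln[1])

    codons_a, codons_b = [], []
    ia = ib = 0
    for res_a, res_b in zip(row_a, row_b):
        if res_a == "-":
            codons_a.append("---")
        else:
            codons_a.append(cds_a[3 * ia : 3 * ia + 3])
            ia += 1
        if res_b == "-":
            codons_b.append("---")
        else:
            codons_b.append(cds_b[3 * ib : 3 * ib + 3])
            ib += 1
    return CodonAlignment(gene_a, gene_b, codons_a, codons_b)


# ---------------------------------------------------------------------------
# NG86
# ---------------------------------------------------------------------------


@dataclass
class KaKsResult:
    """NG86 substitution-rate estimates plus underlying counts for one pair.

    ``Ka``/``Ks``/``ratio`` are None when undefined (saturation, zero
    synonymous sites, or Ks == 0 for the ratio).
    """

    gene_a: str
    gene_b: str
    n_codons: int
    S_sites: float
    N_sites: float
    Sd: float
    Nd: float
    ps: float
    pn: float
    Ka: float | None
    Ks: float | None
    ratio: float | None
    skipped_columns: int = 0
    stop_path_codons: int = 0  # codon pairs where every minimal path hit a stop

    @property
    def key(self) -> tuple[str, str]:
        return tuple(sorted((self.gene_a, self.gene_b)))


@lru_cache(maxsize=None)
def _codon_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts for one codon,
    stop-excluded and renormalized so they sum to 3."""
    aa = translate_codon(codon)
    s = n = 0
    for pos in range(3):
        for base in "ACGT":
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if mutant in STOP_CODONS:
                continue  # not a valid one-step change
            if translate_codon(mutant) == aa:
                s += 1
            else:
                n += 1
    total = s + n
    return 3.0 * s / total, 3.0 * n / total


@lru_cache(maxsize=None)
def _codon_differences(c1: str, c2: str) -> tuple[float, float, bool]:
    """(Sd, Nd, all_paths_hit_stop) between two codons, averaged over all
    orderings of the minimal substitution paths; paths through stop
    codons are excluded unless every path hits one."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0, False
    paths: list[list[tuple[str, str]]] = []
    clean: list[list[tuple[str, str]]] = []
    for order in permutations(diff):
        steps = []
        cur = c1
        hit_stop = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            steps.append((cur, nxt))
            if nxt in STOP_CODONS and nxt != c2:
                hit_stop = True
            cur = nxt
        paths.append(steps)
        if not hit_stop:
            clean.append(steps)
    used = clean if clean else paths
    sd = nd = 0.0
    for steps in used:
        for x, y in steps:
            if translate_codon(x) == translate_codon(y):
                sd += 1.0
            else:
                nd += 1.0
    k = len(used)
    return sd / k, nd / k, not clean


def jukes_cantor(p: float) -> float | None:
    """JC69 distance d = -(3/4) ln(1 - 4p/3); None at saturation (p >= 3/4)."""
    if p >= 0.75:
        return None
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0) + 0.0  # normalize -0.0


def ng86(alignment: CodonAlignment) -> KaKsResult:
    """Nei–Gojobori (1986) Ka/Ks on a codon alignment.

    Gap columns are excluded; columns with ambiguity codes are skipped
    and tallied in ``skipped_columns``.  Requires at least one usable
    codon column.
    """
    S1 = N1 = S2 = N2 = 0.0
    Sd = Nd = 0.0
    n_codons = 0
    skipped = 0
    stop_path = 0
    for ca, cb in alignment.ungapped_columns():
        if any(b not in "ACGT" for b in ca + cb):
            skipped += 1
            continue
        n_codons += 1
        s1, n1 = _codon_sites(ca)
        s2, n2 = _codon_sites(cb)
        S1 += s1
        N1 += n1
        S2 += s2
        N2 += n2
        sd, nd, flagged = _codon_differences(ca, cb)
        Sd += sd
        Nd += nd
        if flagged:
            stop_path += 1
    if n_codons == 0:
        raise ValueError(
            f"pair ({alignment.gene_a}, {alignment.gene_b}): no usable codon columns"
        )
    S = (S1 + S2) / 2.0
    N = (N1 + N2) / 2.0
    ps = Sd / S if S > 0 else 0.0
    pn = Nd / N if N > 0 else 0.0
    Ks = jukes_cantor(ps) if S > 0 else None
    Ka = jukes_cantor(pn) if N > 0 else None
    ratio = Ka / Ks if (Ka is not None and Ks is not None and Ks > 0) else None
    return KaKsResult(
        gene_a=alignment.gene_a,
        gene_b=alignment.gene_b,
        n_codons=n_codons,
        S_sites=S,
        N_sites=N,
        Sd=Sd,
        Nd=Nd,
        ps=ps,
        pn=pn,
        Ka=Ka,
        Ks=Ks,
        ratio=ratio,
        skipped_columns=skipped,
        stop_path_codons=stop_path,
    )


def kaks_for_pairs(
    pairs: Iterable,
    cds: Mapping[str, str],
    proteins: Mapping[str, str],
    gene_to_protein: Mapping[str, str] | None = None,
) -> list[KaKsResult]:
    """Align and score NG86 for each gene pair.

    ``cds``/``proteins`` are keyed by protein id; ``gene_to_protein``
    translates gene ids when the pair lists use them (identity if None).
    Pairs whose sequences are missing are skipped.
    """
    out: list[KaKsResult] = []
    for pair in pairs:
        if hasattr(pair, "gene_a"):
            a, b = pair.gene_a, pair.gene_b
        else:
            a, b = pair[0], pair[1]
        pa = gene_to_protein.get(a, a) if gene_to_protein else a
        pb = gene_to_protein.get(b, b) if gene_to_protein else b
        if pa not in proteins or pb not in proteins or pa not in cds or pb not in cds:
            continue
        aln = align_codon_pair(cds[pa], cds[pb], proteins[pa], proteins[pb], a, b)
        out.append(ng86(aln))
    return out


def write_kaks_table(results: Iterable[KaKsResult], path: str | Path) -> None:
    """Write the per-pair Ka/Ks TSV (NG86 counting model noted in header)."""

    def fmt(x: float | None) -> str:
        return "NA" if x is None else f"{x:.6f}"

    with open(path, "w") as fh:
        fh.write("# model: NG86 (Nei-Gojobori 1986) with Jukes-Cantor correction\n")
        fh.write("gene_a\tgene_b\tn_codons\tS_sites\tN_sites\tSd\tNd\tKa\tKs\tKa_Ks\n")
        for r in results:
            fh.write(
                f"{r.gene_a}\t{r.gene_b}\t{r.n_codons}\t{r.S_sites:.4f}\t"
                f"{r.N_sites:.4f}\t{r.Sd:.4f}\t{r.Nd:.4f}\t{fmt(r.Ka)}\t"
                f"{fmt(r.Ks)}\t{fmt(r.ratio)}\n"
            )


# ---------------------------------------------------------------------------
# Ks-distribution Gaussian mixture
# ---------------------------------------------------------------------------


@dataclass
class GmmFit:
    """Selected Gaussian mixture on the Ks axis (components sorted by mean)."""

    k: int
    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    loglik: float
    bic: float
    bics: dict[int, float] = field(default_factory=dict)

    def pdf(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        out = np.zeros_like(x)
        for w, m, s in zip(self.weights, self.means, self.sds):
            out += w * np.exp(-0.5 * ((x - m) / s) ** 2) / (s * math.sqrt(2 * math.pi))
        return out


def fit_ks_gmm(
    ks_values: Sequence[float],
    k_max: int = 4,
    seed: int = 0,
    ks_ceiling: float | None = 3.0,
) -> GmmFit:
    """Fit Gaussian mixtures with k = 1..k_max components by EM and return
    the fit minimizing BIC.

    Undefined (None/NaN) values are dropped; with ``ks_ceiling`` set
    (default 3.0) only Ks in (0, ceiling] enter the fit, excluding
    saturation noise.  Requires >= 20 usable values.  Deterministic for
    a fixed seed.
    """
    vals = np.asarray(
        [v for v in ks_values if v is not None and np.isfinite(v)], dtype=float
    )
    if ks_ceiling is not None:
        vals = vals[(vals > 0) & (vals <= ks_ceiling)]
    if vals.size < 20:
        raise ValueError(
            f"only {vals.size} usable Ks values (need >= 20); run on a larger pair set"
        )
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    X = vals.reshape(-1, 1)
    best: GmmFit | None = None
    bics: dict[int, float] = {}
    for k in range(1, k_max + 1):
        import warnings

        with warnings.catch_warnings():
            from sklearn.exceptions import ConvergenceWarning

            # degenerate inputs (few distinct values) are guarded by
            # sklearn's covariance floor; the warning is expected there
            warnings.simplefilter("ignore", ConvergenceWarning)
            gm = GaussianMixture(
                n_components=k,
                covariance_type="full",
                random_state=seed,
                n_init=3,
                max_iter=500,
            ).fit(X)
        bic = float(gm.bic(X))
        bics[k] = bic
        if best is None or bic < best.bic:
            order = np.argsort(gm.means_.ravel())
            best = GmmFit(
                k=k,
                weights=gm.weights_.ravel()[order].copy(),
                means=gm.means_.ravel()[order].copy(),
                sds=np.sqrt(gm.covariances_.reshape(k, -1)[:, 0])[order].copy(),
                loglik=float(gm.score(X) * vals.size),
                bic=bic,
            )
    assert best is not None
    best.bics = bics
    return best


def block_ks(
    blocks: Iterable, kaks_results: Iterable[KaKsResult]
) -> dict[int, tuple[float, int]]:
    """Per-synteny-block median anchor Ks.

    Returns block_id -> (median Ks over anchors with defined Ks, count of
    defined anchors); blocks with no defined anchor Ks are omitted.
    """
    by_pair = {r.key: r for r in kaks_results}
    out: dict[int, tuple[float, int]] = {}
    for b in blocks:
        vals = []
        for a in b.anchors:
            r = by_pair.get(tuple(sorted((a.gene_a, a.gene_b))))
            if r is not None and r.Ks is not None:
                vals.append(r.Ks)
        if vals:
            out[b.block_id] = (float(np.median(vals)), len(vals))
    return out


def plot_ks_distribution(
    ks_values: Sequence[float],
    fit: GmmFit | None,
    path: str | Path,
    ks_ceiling: float = 3.0,
    bins: int = 50,
) -> None:
    """Histogram of Ks with fitted mixture density curves overlaid."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    vals = np.asarray(
        [v for v in ks_values if v is not None and np.isfinite(v)], dtype=float
    )
    vals = vals[(vals > 0) & (vals <= ks_ceiling)]
    fig, ax = plt.subplots(figsize=(7, 4.5))
    ax.hist(vals, bins=bins, density=True, alpha=0.5, color="steelblue", label="Ks")
    if fit is not None and vals.size:
        x = np.linspace(0, ks_ceiling, 400)
        ax.plot(x, fit.pdf(x), "k-", lw=2, label=f"GMM (k={fit.k})")
        for w, m, s in zip(fit.weights, fit.means, fit.sds):
            comp = w * np.exp(-0.5 * ((x - m) / s) ** 2) / (s * math.sqrt(2 * math.pi))
            ax.plot(x, comp, "--", lw=1)
            ax.axvline(m, color="grey", lw=0.5)
    ax.set_xlabel("Ks (synonymous substitutions per synonymous site)")
    ax.set_ylabel("density")
    ax.legend()
    fig.tight_layout()
    fig.savefig(str(path))
    plt.close(fig)
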