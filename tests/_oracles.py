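"""Independent reference implementations used only by the tests.

These deliberately avoid sharing code paths with the package: codon
translation goes through Bio.Seq, chain search through exhaustive
recursion, and group merging through plain set algebra.
"""

from __future__ import annotations

import itertools
import math
from itertools import permutations

from Bio.Seq import Seq

ALL_CODONS = ["".join(t) for t in itertools.product("ACGT", repeat=3)]


def _tr(codon: str) -> str:
    return str(Seq(codon).translate())


STOPS = {c for c in ALL_CODONS if _tr(c) == "*"}
NONSTOP_CODONS = [c for c in ALL_CODONS if c not in STOPS]
# codons where no one-step neighbor nor any substitution path can touch a
# stop codon (all stops start with T): safe ground for cross-checking other
# NG86 implementations with different stop conventions
SAFE_CODONS = [
    c for c in NONSTOP_CODONS if c[0] in "ACG" and c[1:] not in ("AA", "AG", "GA")
]


def ng86_reference(codons_a: list[str], codons_b: list[str]):
    """Brute-force NG86: returns (S, N, Sd, Nd, Ks, Ka); None at saturation."""

    def sites(codon):
        syn = valid = 0
        for i in range(3):
            for nt in "ACGT":
                if nt == codon[i]:
                    continue
                m = codon[:i] + nt + codon[i + 1 :]
                if m in STOPS:
                    continue
                valid += 1
                if _tr(m) == _tr(codon):
                    syn += 1
        return 3.0 * syn / valid, 3.0 * (valid - syn) / valid

    def diffs(c1, c2):
        pos = [i for i in range(3) if c1[i] != c2[i]]
        if not pos:
            return 0.0, 0.0
        all_paths, clean = [], []
        for order in permutations(pos):
            cur, steps, hit = c1, [], False
            for i in order:
                nxt = cur[:i] + c2[i] + cur[i + 1 :]
                steps.append((cur, nxt))
                if nxt in STOPS and nxt != c2:
                    hit = True
                cur = nxt
            all_paths.append(steps)
            if not hit:
                clean.append(steps)
        use = clean or all_paths
        sd = sum(1 for st in use for x, y in st if _tr(x) == _tr(y)) / len(use)
        nd = sum(1 for st in use for x, y in st if _tr(x) != _tr(y)) / len(use)
        return sd, nd

    S1 = N1 = S2 = N2 = Sd = Nd = 0.0
    for x, y in zip(codons_a, codons_b):
        s, n = sites(x)
        S1, N1 = S1 + s, N1 + n
        s, n = sites(y)
        S2, N2 = S2 + s, N2 + n
        sd, nd = diffs(x, y)
        Sd, Nd = Sd + sd, Nd + nd
    S, N = (S1 + S2) / 2.0, (N1 + N2) / 2.0

    def jc(p):
        return None if p >= 0.75 else -0.75 * math.log(1.0 - 4.0 * p / 3.0)

    return S, N, Sd, Nd, jc(Sd / S), jc(Nd / N)


def best_chain_reference(anchors, min_anchors, max_gap, match, gap_pen):
    """Exhaustive best valid chain score over both orientations, or None.

    ``anchors`` is a list of (rank_a, rank_b) tuples.  A chain is valid
    when rank_a strictly increases, rank_b strictly increases (same) or
    decreases (inverted), every per-step per-axis gap is <= max_gap,
    and it has >= min_anchors anchors.
    """
    best = [None]

    def extend(order, ranks, chain_len, score, last):
        if chain_len >= min_anchors and (best[0] is None or score > best[0]):
            best[0] = score
        for j in order:
            ra, rb = ranks[j]
            if last is not None:
                la, lb = last
                da, db = ra - la - 1, rb - lb - 1
                if da < 0 or db < 0 or da > max_gap or db > max_gap:
                    continue
                step = match + gap_pen * (da + db)
            else:
                step = match
            extend([k for k in order if ranks[k][0] > ra], ranks, chain_len + 1,
                   score + step, (ra, rb))

    for sign in (1, -1):
        ranks = [(ra, sign * rb) for ra, rb in anchors]
        idx = sorted(range(len(ranks)), key=lambda i: ranks[i])
        extend(idx, ranks, 0, 0.0, None)
    return best[0]


def merge_groups_reference(group_lists):
    """Union-with-subset-pruning over ordered per-threshold group lists.

    Admits each group (in grid order) unless its member set equals or is
    contained in an already-admitted group's member set.
    """
    admitted = []
    for groups in group_lists:
        for g in groups:
            if any(g.members <= other.members for other in admitted):
                continue
            admitted.append(g)
    return admitted
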