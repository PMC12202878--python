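"""Codon alignment, NG86 counting, and Ks mixture decomposition."""

import math
import random

import numpy as np
import pytest

from hsdkit.kaks import (
    CodonAlignment,
    align_codon_pair,
    block_ks,
    fit_ks_gmm,
    kaks_for_pairs,
    ng86,
    translate_codon,
)

from _oracles import NONSTOP_CODONS, SAFE_CODONS, ng86_reference


def protein_of(codons):
    return "".join(translate_codon(c) for c in codons)


def random_pair(rng, n=60, sub_rate=0.3, codon_pool=NONSTOP_CODONS):
    ca = [rng.choice(codon_pool) for _ in range(n)]
    cb = [rng.choice(codon_pool) if rng.random() < sub_rate else c for c in ca]
    return ca, cb


class TestCodonAlignment:
    def test_identical_sequences_align_without_gaps(self):
        codons = ["ATG", "GCT", "CAT", "TGG", "AAA", "CCC", "GGG", "TTT", "GAG", "CTT"]
        cds = "".join(codons)
        aln = align_codon_pair(cds, cds, protein_of(codons), protein_of(codons))
        assert len(aln.codons_a) == 10
        assert "---" not in aln.codons_a and "---" not in aln.codons_b

    def test_single_deletion_gives_one_codon_gap(self):
        codons = ["ATG", "GCT", "CAT", "TGG", "AAA", "CCC", "GGG", "TTT", "GAG", "CTT"]
        short = codons[:4] + codons[5:]
        aln = align_codon_pair(
            "".join(codons), "".join(short), protein_of(codons), protein_of(short)
        )
        assert aln.codons_b.count("---") == 1
        assert aln.codons_a.count("---") == 0

    def test_terminal_stop_stripped(self):
        codons = ["ATG", "GCT", "CAT", "TGG"]
        cds = "".join(codons) + "TAA"
        aln = align_codon_pair(cds, cds, protein_of(codons), protein_of(codons))
        assert len(aln.codons_a) == 4

    def test_translation_mismatch_names_gene(self):
        with pytest.raises(ValueError, match="geneX"):
            align_codon_pair("ATGGCT", "ATGGCT", "MW", "MA", gene_a="geneX")

    def test_internal_stop_rejected(self):
        with pytest.raises(ValueError, match="internal stop"):
            align_codon_pair("ATGTAAGCT", "ATGTAAGCT", "M*A", "M*A")

    def test_back_translation_round_trip(self):
        rng = random.Random(17)
        for _ in range(5):
            ca, cb = random_pair(rng, n=40)
            aln = align_codon_pair(
                "".join(ca), "".join(cb), protein_of(ca), protein_of(cb)
            )
            ra = "".join(
                translate_codon(c) if c != "---" else "-" for c in aln.codons_a
            )
            assert ra.replace("-", "") == protein_of(ca)


class TestNg86:
    def test_identical_sequences_zero_rates(self):
        codons = ["GCT", "CAT", "TGG", "AAA", "CCC"]
        r = ng86(CodonAlignment("a", "b", codons, list(codons)))
        assert r.Ka == 0.0 and r.Ks == 0.0
        assert r.Sd == 0.0 and r.Nd == 0.0

    def test_hand_computed_single_synonymous_change(self):
        # 9x GCT vs 8x GCT + GCC: every codon has one 4-fold synonymous
        # site (pos 3) and two nonsynonymous sites, no stop-adjacent
        # neighbors; one synonymous difference.
        a = ["GCT"] * 9
        b = ["GCT"] * 8 + ["GCC"]
        r = ng86(CodonAlignment("a", "b", a, b))
        assert r.S_sites == pytest.approx(9.0)
        assert r.N_sites == pytest.approx(18.0)
        assert (r.Sd, r.Nd) == (1.0, 0.0)
        assert r.ps == pytest.approx(1.0 / 9.0)
        # Ks = -(3/4) ln(1 - 4/27)
        assert r.Ks == pytest.approx(-0.75 * math.log(23.0 / 27.0), abs=1e-12)
        assert r.Ka == 0.0 and r.ratio == 0.0

    def test_symmetry_exact(self):
        rng = random.Random(23)
        ca, cb = random_pair(rng)
        fwd = ng86(CodonAlignment("a", "b", ca, cb))
        rev = ng86(CodonAlignment("b", "a", cb, ca))
        assert (fwd.S_sites, fwd.N_sites, fwd.Sd, fwd.Nd) == (
            rev.S_sites,
            rev.N_sites,
            rev.Sd,
            rev.Nd,
        )
        assert fwd.Ks == rev.Ks and fwd.Ka == rev.Ka

    def test_site_conservation(self):
        rng = random.Random(29)
        for _ in range(10):
            ca, cb = random_pair(rng, n=50)
            r = ng86(CodonAlignment("a", "b", ca, cb))
            assert r.S_sites + r.N_sites == pytest.approx(3 * r.n_codons, abs=1e-9)

    def test_saturation_yields_undefined_not_nan(self):
        # every codon differs by a synonymous third-position change:
        # ps = 1 >= 3/4, so Ks must be None (and ratio None), never NaN
        a = ["GCT"] * 30
        b = ["GCA"] * 30
        r = ng86(CodonAlignment("a", "b", a, b))
        assert r.ps >= 0.75 and r.Ks is None and r.ratio is None

    def test_ambiguity_codons_skipped_and_counted(self):
        a = ["GCT", "GCN", "CAT"]
        b = ["GCT", "GCT", "CAT"]
        r = ng86(CodonAlignment("a", "b", a, b))
        assert r.n_codons == 2 and r.skipped_columns == 1

    @pytest.mark.parametrize("trial", range(15))
    def test_matches_independent_reference(self, trial):
        rng = random.Random(1000 + trial)
        ca, cb = random_pair(rng, n=80, sub_rate=0.25)
        S, N, Sd, Nd, Ks, Ka = ng86_reference(ca, cb)
        r = ng86(CodonAlignment("a", "b", ca, cb))
        assert r.S_sites == pytest.approx(S, abs=1e-9)
        assert r.N_sites == pytest.approx(N, abs=1e-9)
        assert r.Sd == pytest.approx(Sd, abs=1e-9)
        assert r.Nd == pytest.approx(Nd, abs=1e-9)
        for mine, ref in ((r.Ks, Ks), (r.Ka, Ka)):
            if ref is None:
                assert mine is None
            else:
                assert mine == pytest.approx(ref, abs=1e-9)

    @pytest.mark.parametrize("trial", range(5))
    def test_matches_biopython_on_stop_safe_codons(self, trial):
        """Cross-check against Bio.Align.analysis NG86 on codon sets where
        no substitution or path can touch a stop codon, so differing
        stop conventions cannot bite."""
        from Bio.Align import Alignment
        from Bio.Align.analysis import calculate_dn_ds

        rng = random.Random(2000 + trial)
        ca, cb = random_pair(rng, n=80, sub_rate=0.25, codon_pool=SAFE_CODONS)
        s1, s2 = "".join(ca), "".join(cb)
        aln = Alignment([s1, s2], np.array([[0, len(s1)], [0, len(s2)]]))
        dN, dS = calculate_dn_ds(aln, method="NG86")
        r = ng86(CodonAlignment("a", "b", ca, cb))
        assert r.Ka == pytest.approx(dN, abs=1e-9)
        assert r.Ks == pytest.approx(dS, abs=1e-9)


class TestGmm:
    def test_single_component_recovery(self):
        rng = np.random.default_rng(7)
        vals = rng.normal(0.5, 0.05, 500)
        fit = fit_ks_gmm(vals, k_max=3, seed=0)
        assert fit.k == 1
        assert fit.means[0] == pytest.approx(0.5, abs=0.02)

    def test_two_component_recovery(self):
        rng = np.random.default_rng(7)
        vals = np.concatenate(
            [rng.normal(0.3, 0.06, 500), rng.normal(1.2, 0.15, 500)]
        )
        fit = fit_ks_gmm(vals, k_max=4, seed=0)
        assert fit.k == 2
        assert fit.means[0] == pytest.approx(0.3, abs=0.05)
        assert fit.means[1] == pytest.approx(1.2, abs=0.05)
        assert fit.weights.sum() == pytest.approx(1.0, abs=1e-9)

    def test_identical_values_guarded(self):
        fit = fit_ks_gmm(np.full(30, 0.5), k_max=3, seed=0)
        assert fit.k >= 1 and np.all(fit.sds > 0)

    def test_too_few_values_error(self):
        with pytest.raises(ValueError, match="larger pair set"):
            fit_ks_gmm([0.5] * 10)

    def test_deterministic_for_seed(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(0.6, 0.1, 200)
        a = fit_ks_gmm(vals, seed=42)
        b = fit_ks_gmm(vals, seed=42)
        assert a.k == b.k
        assert np.array_equal(a.means, b.means)
        assert np.array_equal(a.weights, b.weights)

    def test_undefined_values_dropped(self):
        rng = np.random.default_rng(5)
        vals = list(rng.normal(0.5, 0.05, 100)) + [None, float("nan"), 99.0]
        fit = fit_ks_gmm(vals, k_max=2, seed=0)
        assert fit.means[0] == pytest.approx(0.5, abs=0.05)


class TestBlockKs:
    class _B:
        def __init__(self, bid, anchors):
            self.block_id = bid
            self.anchors = anchors

    class _A:
        def __init__(self, a, b):
            self.gene_a, self.gene_b = a, b

    def _result(self, a, b, ks):
        codons = ["GCT"] * 5
        r = ng86(CodonAlignment(a, b, codons, list(codons)))
        r.Ks = ks
        return r

    def test_median_of_defined_anchors(self):
        anchors = [self._A("g1", "g2"), self._A("g3", "g4"), self._A("g5", "g6")]
        results = [
            self._result("g1", "g2", 0.1),
            self._result("g3", "g4", 0.2),
            self._result("g5", "g6", 0.9),
        ]
        table = block_ks([self._B(1, anchors)], results)
        assert table[1] == (pytest.approx(0.2), 3)

    def test_block_with_no_defined_ks_omitted(self):
        anchors = [self._A("g1", "g2")]
        results = [self._result("g1", "g2", None)]
        assert block_ks([self._B(1, anchors)], results) == {}

    def test_planted_wgd_ks_recovered(self, bundle, pipeline_result):
        """Anchor-pair Ks on the simulated genome recovers the planted
        synonymous divergence within sampling tolerance."""
        planted = {
            (p.gene_a, p.gene_b): p.planted_ks
            for p in bundle.ledger.pairs
            if p.mode == "WGD"
        }
        by_key = {r.key: r for r in pipeline_result.kaks_results}
        checked = 0
        for key, ks_target in planted.items():
            r = by_key.get(key)
            assert r is not None and r.Ks is not None
            assert r.Ks == pytest.approx(ks_target, abs=0.15)
            checked += 1
        assert checked >= 10
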