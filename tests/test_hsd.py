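"""HSD detection, add-on curation algebra, statistics and KO heatmaps."""

import random

import pytest

from hsdkit.hsd import (
    HSDGroup,
    HsdThreshold,
    UNANNOTATED,
    add_on,
    batch_run,
    build_ko_heatmap,
    detect_hsds,
    domains_consistent,
    hsd_categories,
    hsd_statistics,
)
from hsdkit.io_formats import DomainAnnotation, HomologyHit
from hsdkit.preprocess import ParalogPair

from _oracles import merge_groups_reference


def hit(a, b, pident):
    return HomologyHit(a, b, pident, 100, 0, 0, 1, 100, 1, 100, 1e-80, 300.0)


def dom(protein, acc, start, end):
    return DomainAnnotation(protein, "Pfam", acc, "", start, end)


def group(members, thr=HsdThreshold(90, 10)):
    return HSDGroup(min(members) + "|" + thr.tag, frozenset(members), thr)


class TestDetect:
    def test_all_predicates_pass(self):
        groups = detect_hsds(
            [("g1", "g2")],
            [hit("g1", "g2", 95.0)],
            {"g1": 300, "g2": 300},
            {"g1": [dom("g1", "PF1", 10, 110)], "g2": [dom("g2", "PF1", 12, 112)]},
            HsdThreshold(90, 10),
        )
        assert len(groups) == 1 and groups[0].members == {"g1", "g2"}

    def test_length_difference_blocks_group(self):
        groups = detect_hsds(
            [("g1", "g2")],
            [hit("g1", "g2", 95.0)],
            {"g1": 300, "g2": 340},
            {},
            HsdThreshold(90, 10),
        )
        assert groups == []

    def test_identity_threshold_blocks_group(self):
        groups = detect_hsds(
            [("g1", "g2")],
            [hit("g1", "g2", 80.0)],
            {"g1": 300, "g2": 300},
            {},
            HsdThreshold(90, 10),
        )
        assert groups == []

    def test_domain_mismatch_blocks_group(self):
        groups = detect_hsds(
            [("g1", "g2")],
            [hit("g1", "g2", 95.0)],
            {"g1": 300, "g2": 300},
            {"g1": [dom("g1", "PF1", 10, 110)], "g2": [dom("g2", "PF2", 10, 110)]},
            HsdThreshold(90, 10),
        )
        assert groups == []

    def test_domain_free_pair_is_consistent(self):
        assert domains_consistent((), ()) is True
        assert domains_consistent((("PF1", 50),), ()) is False

    def test_domain_length_tolerance(self):
        assert domains_consistent((("PF1", 50),), (("PF1", 59),), domain_tol=10)
        assert not domains_consistent((("PF1", 50),), (("PF1", 70),), domain_tol=10)

    def test_ignore_domains_mode(self):
        groups = detect_hsds(
            [("g1", "g2")],
            [hit("g1", "g2", 95.0)],
            {"g1": 300, "g2": 300},
            {"g1": [dom("g1", "PF1", 10, 110)], "g2": [dom("g2", "PF2", 10, 110)]},
            HsdThreshold(90, 10),
            ignore_domains=True,
        )
        assert len(groups) == 1

    def test_pident_from_pair_objects(self):
        pairs = [ParalogPair("g1", "g2", 1e-90, 96.0)]
        groups = detect_hsds(pairs, None, {"g1": 200, "g2": 200}, {}, HsdThreshold(90, 10))
        assert len(groups) == 1

    def test_planted_family_recovered_diverged_copy_excluded(self, bundle):
        """A planted 3-copy tandem family plus a ~60%-identity pseudo-copy
        yields exactly the 3 true copies at the 90%_10aa threshold."""
        from hsdkit import io_formats as io
        from hsdkit.preprocess import FilterParams, filter_hits, paralog_pairs
        from hsdkit.preprocess import select_primary_isoforms

        genes = io.parse_gff3(bundle.paths["gff"])
        primary = select_primary_isoforms(genes)
        filtered = filter_hits(
            io.read_homology_table(bundle.paths["blast"]), FilterParams(), primary
        )
        pairs = paralog_pairs(filtered)
        prot = io.read_fasta(bundle.paths["proteins"])
        lengths = {g: len(prot[p]) for g, p in primary.items()}
        prot2gene = {p: g for g, p in primary.items()}
        domains = {}
        for d in io.read_interproscan_tsv(bundle.paths["interproscan"]):
            gid = prot2gene.get(d.protein_id)
            if gid:
                domains.setdefault(gid, []).append(d)
        groups = detect_hsds(pairs, filtered, lengths, domains, HsdThreshold(90, 10))
        detected = {g.members for g in groups}
        fam3 = next(
            f for f in bundle.ledger.hsd_families
            if f.mode == "TD" and len(f.members) == 3
        )
        assert fam3.members in detected


class TestAddOn:
    def test_identical_relaxed_group_not_added(self):
        strict = [group({"g1", "g2"})]
        relaxed = [group({"g1", "g2"}, HsdThreshold(70, 30))]
        assert add_on(strict, relaxed) == strict

    def test_subset_relaxed_group_not_added(self):
        strict = [group({"g1", "g2", "g3"})]
        relaxed = [group({"g1", "g2"}, HsdThreshold(70, 30))]
        assert add_on(strict, relaxed) == strict

    def test_superset_relaxed_group_added(self):
        strict = [group({"g1", "g2"})]
        relaxed = [group({"g1", "g2", "g3"}, HsdThreshold(70, 30))]
        merged = add_on(strict, relaxed)
        assert len(merged) == 2

    def test_idempotence(self):
        x = [group({"g1", "g2"}), group({"g3", "g4", "g5"})]
        assert add_on(x, x) == x

    def test_no_duplicate_member_sets_in_output(self):
        strict = [group({"g1", "g2"})]
        relaxed = [
            group({"g3", "g4"}, HsdThreshold(70, 30)),
            group({"g3", "g4"}, HsdThreshold(70, 30)),
        ]
        merged = add_on(strict, relaxed)
        assert len({g.members for g in merged}) == len(merged) == 2


def random_hsd_inputs(rng, n_genes=30):
    """Random pair universe with identities and lengths, no domains."""
    genes = [f"g{i}" for i in range(n_genes)]
    lengths = {g: rng.randrange(150, 260) for g in genes}
    pairs = []
    for i in range(n_genes):
        for j in range(i + 1, n_genes):
            if rng.random() < 0.12:
                pairs.append(
                    ParalogPair(genes[i], genes[j], 1e-50, rng.uniform(55, 100))
                )
    return pairs, lengths


GRID = [HsdThreshold(90, 10), HsdThreshold(70, 30), HsdThreshold(70, 50)]


class TestBatchRun:
    def test_single_threshold_equals_detect(self):
        rng = random.Random(1)
        pairs, lengths = random_hsd_inputs(rng)
        detect = lambda thr: detect_hsds(pairs, None, lengths, {}, thr)
        merged, ledger = batch_run([HsdThreshold(90, 10)], detect)
        assert {g.members for g in merged} == {
            g.members for g in detect(HsdThreshold(90, 10))
        }
        assert sum(ledger.values()) == len(merged)

    def test_monotone_accumulation(self):
        rng = random.Random(2)
        pairs, lengths = random_hsd_inputs(rng)
        detect = lambda thr: detect_hsds(pairs, None, lengths, {}, thr)
        merged, _ = batch_run(GRID, detect)
        assert len(merged) >= len(detect(GRID[0]))

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            batch_run([], lambda thr: [])

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_union_with_subset_pruning(self, seed):
        rng = random.Random(300 + seed)
        pairs, lengths = random_hsd_inputs(rng)
        detect = lambda thr: detect_hsds(pairs, None, lengths, {}, thr)
        merged, ledger = batch_run(GRID, detect)
        expected = merge_groups_reference([detect(t) for t in GRID])
        assert {g.members for g in merged} == {g.members for g in expected}
        assert sum(ledger.values()) == len(merged)

    @pytest.mark.parametrize("seed", range(10))
    def test_threshold_relaxation_refines_groups(self, seed):
        """Every strict-threshold group is contained in some group at a
        relaxed threshold (edges only get added)."""
        rng = random.Random(400 + seed)
        pairs, lengths = random_hsd_inputs(rng)
        strict = detect_hsds(pairs, None, lengths, {}, HsdThreshold(90, 10))
        relaxed = detect_hsds(pairs, None, lengths, {}, HsdThreshold(70, 50))
        for s in strict:
            assert any(s.members <= r.members for r in relaxed)


class TestStatisticsAndCategories:
    def test_counting_example(self):
        groups = [
            group({"g1", "g2"}),
            group({"g3", "g4"}),
            group({"g5", "g6", "g7"}),
            group({"h1", "h2", "h3", "h4", "h5"}),
        ]
        stats = hsd_statistics(groups)
        assert stats.n_hsds == 4
        assert stats.n_gene_copies == 12
        assert stats.n_nonredundant_copies == 12
        cats = hsd_categories(groups)
        assert cats.counts == {"2": 2, "3": 1, ">3": 1}

    def test_redundant_copies_counted_once(self):
        groups = [group({"g1", "g2"}), group({"g2", "g3"}, HsdThreshold(70, 30))]
        stats = hsd_statistics(groups)
        assert stats.n_gene_copies == 4 and stats.n_nonredundant_copies == 3

    def test_empty_groups_zero(self):
        stats = hsd_statistics([])
        assert (stats.n_hsds, stats.n_gene_copies, stats.n_nonredundant_copies) == (
            0, 0, 0,
        )
        assert hsd_categories([]).counts == {"2": 0, "3": 0, ">3": 0}

    @pytest.mark.parametrize("seed", range(5))
    def test_category_conservation(self, seed):
        rng = random.Random(500 + seed)
        pairs, lengths = random_hsd_inputs(rng)
        for thr in GRID:
            groups = detect_hsds(pairs, None, lengths, {}, thr)
            cats = hsd_categories(groups, thr.tag)
            assert sum(cats.counts.values()) == len(groups)


class TestHeatmap:
    def test_shared_ko_counts_group_once(self):
        groups = [group({"g1", "g2"})]
        matrix = build_ko_heatmap(
            {"tandem": groups}, {"g1": {"K00001"}, "g2": {"K00001"}}
        )
        assert matrix.table.loc["K00001", "tandem"] == 1

    def test_multi_ko_group_increments_each_once(self):
        groups = [group({"g1", "g2"})]
        matrix = build_ko_heatmap(
            {"tandem": groups}, {"g1": {"K00001"}, "g2": {"K00002"}}
        )
        assert matrix.table.loc["K00001", "tandem"] == 1
        assert matrix.table.loc["K00002", "tandem"] == 1

    def test_unannotated_row(self):
        groups = [group({"g1", "g2"})]
        matrix = build_ko_heatmap({"tandem": groups}, {})
        assert matrix.table.loc[UNANNOTATED, "tandem"] == 1

    def test_column_conservation(self):
        """When every group has at most one KO, each column sums to the
        label's group count."""
        rng = random.Random(9)
        labels = {}
        ko_map = {}
        for label in ("modeA", "modeB"):
            groups = []
            for i in range(6):
                members = {f"{label}g{i}a", f"{label}g{i}b"}
                groups.append(group(members))
                if rng.random() < 0.7:
                    ko = f"K{rng.randrange(1, 5):05d}"
                    for m in members:
                        ko_map[m] = {ko}
            labels[label] = groups
        matrix = build_ko_heatmap(labels, ko_map)
        for label, groups in labels.items():
            assert matrix.table[label].sum() == len(groups)
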