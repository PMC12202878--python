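"""End-to-end pipeline: preprocess -> collinearity -> classify -> kaks -> hsd.

Stages are single-process and file-mediated: each writes its outputs to
the run directory and can be re-run standalone on the previous stage's
files, so every step can be quality-checked in isolation.  A YAML
config names the inputs and parameters; stage functions log input and
output counts at INFO.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import classify as _classify
from . import collinearity as _coll
from . import hsd as _hsd
from . import io_formats as io
from . import kaks as _kaks
from . import preprocess as _pre

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Validated inputs and parameters for a full run."""

    gff: Path
    proteins: Path
    cds: Path
    blast: Path
    out_dir: Path
    outgroup_gff: Path | None = None
    outgroup_blast: Path | None = None
    interproscan: Path | None = None
    ko: Path | None = None
    filter_params: _pre.FilterParams = field(default_factory=_pre.FilterParams)
    collinearity_params: _coll.CollinearityParams = field(
        default_factory=_coll.CollinearityParams
    )
    classify_params: _classify.ClassifyParams = field(
        default_factory=_classify.ClassifyParams
    )
    hsd_thresholds: list[_hsd.HsdThreshold] = field(
        default_factory=lambda: [
            _hsd.HsdThreshold(90, 10),
            _hsd.HsdThreshold(70, 30),
            _hsd.HsdThreshold(70, 50),
        ]
    )
    gmm_k_max: int = 4
    ks_ceiling: float = 3.0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        kwargs: dict = {}
        for key in (
            "gff",
            "proteins",
            "cds",
            "blast",
            "out_dir",
            "outgroup_gff",
            "outgroup_blast",
            "interproscan",
            "ko",
        ):
            if key in raw and raw[key] is not None:
                kwargs[key] = Path(raw[key])
        if "filter" in raw:
            kwargs["filter_params"] = _pre.FilterParams(**raw["filter"])
        if "collinearity" in raw:
            kwargs["collinearity_params"] = _coll.CollinearityParams(
                **raw["collinearity"]
            )
        if "classify" in raw:
            kwargs["classify_params"] = _classify.ClassifyParams(**raw["classify"])
        if "hsd_thresholds" in raw:
            kwargs["hsd_thresholds"] = [
                _hsd.HsdThreshold(t["min_identity"], t["max_len_diff"])
                for t in raw["hsd_thresholds"]
            ]
        for key in ("gmm_k_max", "ks_ceiling", "seed"):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)

    def validate(self) -> None:
        for name in ("gff", "proteins", "cds", "blast"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"config input {name}: {p} does not exist")
        for name in ("outgroup_gff", "outgroup_blast", "interproscan", "ko"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"config input {name}: {p} does not exist")


@dataclass
class PipelineResult:
    summary: dict
    out_dir: Path
    classified: list[io.DuplicatePair]
    kaks_results: list
    hsd_merged: dict[str, list]
    report_path: Path


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run every stage in order, writing per-stage outputs and a final
    aggregate report.  Raises on the first failing stage (partial
    outputs are retained)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # -- preprocess ---------------------------------------------------------
    genes = io.parse_gff3(config.gff)
    primary = _pre.select_primary_isoforms(genes)
    hits = io.read_homology_table(config.blast)
    filtered = _pre.filter_hits(hits, config.filter_params, primary)
    pairs = _pre.paralog_pairs(filtered)
    logger.info(
        "preprocess: %d genes, %d hits in, %d hits kept, %d paralog pairs",
        len(genes), len(hits), len(filtered), len(pairs),
    )
    io.write_gene_position_table(genes, out / "gene_positions.tsv")
    io.write_homology_table(filtered, out / "filtered.blast.tsv")

    # -- collinearity -------------------------------------------------------
    intra_blocks = _coll.find_synteny_blocks(
        genes, genes, pairs, config.collinearity_params
    )
    _coll.write_collinearity(intra_blocks, out / "intra.collinearity")
    logger.info("collinearity: %d intra-genome blocks", len(intra_blocks))

    outgroup_pairs: list = []
    outgroup_blocks: list = []
    if config.outgroup_gff is not None and config.outgroup_blast is not None:
        og_genes = io.parse_gff3(config.outgroup_gff)
        og_primary = _pre.select_primary_isoforms(og_genes)
        og_hits = io.read_homology_table(config.outgroup_blast)
        og_filtered = _pre.filter_hits(
            og_hits, config.filter_params, primary, subject_map=og_primary
        )
        outgroup_pairs = _pre.paralog_pairs(og_filtered)
        outgroup_blocks = _coll.find_synteny_blocks(
            genes, og_genes, outgroup_pairs, config.collinearity_params
        )
        _coll.write_collinearity(outgroup_blocks, out / "outgroup.collinearity")
        logger.info(
            "collinearity: %d focal-vs-outgroup blocks from %d pairs",
            len(outgroup_blocks), len(outgroup_pairs),
        )

    # -- classify -----------------------------------------------------------
    classified = _classify.classify_duplicates(
        pairs,
        genes,
        intra_blocks,
        outgroup_pairs,
        outgroup_blocks,
        config.classify_params,
    )
    summary = _classify.mode_summary(classified)
    io.write_pair_files(classified, out)
    with open(out / "mode_summary.tsv", "w") as fh:
        fh.write("mode\tpairs\tgenes\n")
        for m in io.MODES:
            fh.write(f"{m}\t{summary['pairs'][m]}\t{summary['genes'][m]}\n")
        fh.write(f"total\t{summary['total_pairs']}\t\n")
    logger.info("classify: %s", summary["pairs"])

    # -- kaks ---------------------------------------------------------------
    proteins = io.read_fasta(config.proteins)
    cds = io.read_fasta(config.cds)
    kaks_results = _kaks.kaks_for_pairs(classified, cds, proteins, primary)
    _kaks.write_kaks_table(kaks_results, out / "pairs.kaks.tsv")
    anchor_keys = {
        tuple(sorted((a.gene_a, a.gene_b)))
        for b in intra_blocks
        for a in b.anchors
    }
    anchor_ks = [r.Ks for r in kaks_results if r.Ks is not None and r.key in anchor_keys]
    gmm = None
    if len(anchor_ks) >= 20:
        gmm = _kaks.fit_ks_gmm(
            anchor_ks, config.gmm_k_max, config.seed, config.ks_ceiling
        )
        _kaks.plot_ks_distribution(
            anchor_ks, gmm, out / "synteny.blocks.ks.distri.pdf", config.ks_ceiling
        )
    block_medians = _kaks.block_ks(intra_blocks, kaks_results)
    with open(out / "block_ks.tsv", "w") as fh:
        fh.write("block_id\tmedian_ks\tn_anchors\n")
        for bid, (med, n) in sorted(block_medians.items()):
            fh.write(f"{bid}\t{med:.4f}\t{n}\n")
    logger.info(
        "kaks: %d pair estimates, %d anchor Ks values, GMM %s",
        len(kaks_results), len(anchor_ks), f"k={gmm.k}" if gmm else "skipped",
    )

    # -- hsd ----------------------------------------------------------------
    domains_by_protein: dict[str, list] = {}
    if config.interproscan is not None:
        for d in io.read_interproscan_tsv(config.interproscan):
            domains_by_protein.setdefault(d.protein_id, []).append(d)
    # key domain table by gene id through the primary-protein map
    prot2gene = {pid: gid for gid, pid in primary.items()}
    domains_by_gene = {
        prot2gene[pid]: doms
        for pid, doms in domains_by_protein.items()
        if pid in prot2gene
    }
    ko_map: dict[str, set[str]] = {}
    if config.ko is not None:
        for rec in io.read_ko_table(config.ko):
            if rec.ko_id:
                ko_map.setdefault(rec.gene_id, set()).add(rec.ko_id)
    protein_lengths = {g.gene_id: len(proteins.get(primary[g.gene_id], "")) for g in genes}

    by_mode: dict[str, list[io.DuplicatePair]] = {m: [] for m in io.MODES}
    for p in classified:
        by_mode[p.mode].append(p)
    pair_pident = {
        pp.key: pp.max_pident for pp in pairs
    }

    hsd_merged: dict[str, list] = {}
    all_stats, all_cats = [], []
    for mode in io.MODES:
        mode_pairs = [
            (p.gene_a, p.gene_b, pair_pident.get(p.key, 0.0)) for p in by_mode[mode]
        ]

        def detect(thr, _mp=mode_pairs):
            return _hsd.detect_hsds(
                [(a, b) for a, b, _ in _mp],
                [
                    io.HomologyHit(a, b, pid, 0, 0, 0, 1, 1, 1, 1, 0.0, 0.0)
                    for a, b, pid in _mp
                ],
                protein_lengths,
                domains_by_gene,
                thr,
                ko_map=ko_map,
            )

        merged, ledger = _hsd.batch_run(config.hsd_thresholds, detect)
        hsd_merged[mode] = merged
        _hsd.write_hsd_table(merged, out / f"{io.MODE_STEMS[mode]}.batch_run.tsv")
        stats = _hsd.hsd_statistics(merged, "+".join(t.tag for t in config.hsd_thresholds))
        cats = _hsd.hsd_categories(merged, stats.threshold_tag)
        all_stats.append(stats)
        all_cats.append(cats)
    _hsd.write_statistics(all_stats, out / "hsd.stat.tsv")
    _hsd.write_categories(all_cats, out / "hsd.category.tsv")

    heatmap = _hsd.build_ko_heatmap(
        {io.MODE_STEMS[m]: hsd_merged[m] for m in io.MODES}, ko_map
    )
    _hsd.write_heatmap_tsv(heatmap, out / "hsd.heatmap.tsv")
    _hsd.plot_heatmap(heatmap, out / "hsd.heatmap.png")
    logger.info("hsd: %s groups per mode", {m: len(v) for m, v in hsd_merged.items()})

    # -- report -------------------------------------------------------------
    report_path = out / "report.md"
    with open(report_path, "w") as fh:
        fh.write("# hsdkit pipeline report\n\n## Duplication modes (pairs)\n\n")
        fh.write("| mode | pairs | genes |\n|---|---|---|\n")
        for m in io.MODES:
            fh.write(f"| {m} | {summary['pairs'][m]} | {summary['genes'][m]} |\n")
        fh.write(f"\nTotal pairs: {summary['total_pairs']}\n")
        defined = [r.Ks for r in kaks_results if r.Ks is not None]
        fh.write(f"\n## Ka/Ks\n\n{len(kaks_results)} pairs scored; ")
        fh.write(f"{len(defined)} with defined Ks")
        if defined:
            import numpy as np

            fh.write(f"; median Ks {float(np.median(defined)):.3f}")
        fh.write(".\n")
        if gmm is not None:
            means = ", ".join(f"{m:.3f}" for m in gmm.means)
            fh.write(f"Ks mixture: k={gmm.k} components at means [{means}].\n")
        fh.write("\n## HSD groups per duplication mode\n\n")
        fh.write("| mode | groups | copies-2 | copies-3 | copies->3 |\n|---|---|---|---|---|\n")
        for m, cats in zip(io.MODES, all_cats):
            fh.write(
                f"| {m} | {len(hsd_merged[m])} | {cats.counts['2']} | "
                f"{cats.counts['3']} | {cats.counts['>3']} |\n"
            )

    return PipelineResult(
        summary=summary,
        out_dir=out,
        classified=classified,
        kaks_results=kaks_results,
        hsd_merged=hsd_merged,
        report_path=report_path,
    )
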