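"""Pipeline orchestration: configuration, stage ordering and report generation.

``run_pipeline`` executes the full chain

    expression -> fold changes -> regulon -> promoter scan -> operons -> islands

from a YAML config, writes every stage's output file, and produces a
:class:`SummaryReport` whose counts mirror the headline numbers of a
nitrogen-fixation / ammonium-repression profiling study (genes up and down
under fixation, genes altered by shock, regulon size, ortholog-backed core
subset, inside/outside island partition, operon count).

Optional inputs (genome sequence, orthologs, core-genome list, category
map) skip their stages with a logged notice.  Promoter flags may be
supplied externally (a worked-example table) instead of being scanned from
sequence.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import expression as ex
from . import io_formats as io
from . import operon_island as oi
from . import promoter_scan as ps
from . import regulon as rg

logger = logging.getLogger("nifregulon")

__all__ = [
    "ConfigError",
    "SummaryReport",
    "run_pipeline",
    "report_table1_style",
    "reproduce_supplementary_counts",
]


class ConfigError(ValueError):
    """Malformed pipeline configuration (reports the offending key)."""


@dataclass
class SummaryReport:
    """Headline counts of one pipeline run."""

    n_genes: int = 0
    n_up_nfix: int = 0
    n_down_nfix: int = 0
    n_altered_shock: int = 0
    n_up_shock: int = 0
    n_down_shock: int = 0
    n_regulon: int = 0
    n_core_subset: int | None = None
    n_regulon_in_island: int = 0
    n_regulon_outside: int = 0
    n_core_genome_overlap: int | None = None
    n_yes_yes_promoters: int | None = None
    n_operons: int | None = None
    n_operon_genes: int | None = None
    islands: list[dict[str, Any]] = field(default_factory=list)
    category_proportions: dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        if self.n_regulon_in_island + self.n_regulon_outside != self.n_regulon:
            raise AssertionError("island partition does not sum to the regulon size")
        if self.n_regulon > self.n_up_nfix:
            raise AssertionError("regulon larger than the nitrogen-fixation up-set")
        if self.n_core_subset is not None and self.n_core_subset > self.n_regulon:
            raise AssertionError("core subset larger than the regulon")

    def to_json(self, path: Path) -> None:
        self.validate()
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)
            fh.write("\n")

    def to_tsv(self, path: Path) -> None:
        self.validate()
        flat = {k: v for k, v in asdict(self).items() if not isinstance(v, (list, dict))}
        pd.Series(flat, name="value").to_csv(path, sep="\t", index_label="quantity")


def _load_config(path: str | Path) -> dict[str, Any]:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ConfigError("config must be a YAML mapping")
    return cfg


def _scan_config(section: Mapping[str, Any]) -> ps.ScanConfig:
    try:
        return ps.ScanConfig(
            upstream_window=int(section.get("upstream_window", 400)),
            min_uas_distance=int(section.get("min_uas_distance", 100)),
            uas_pattern=ps.compile_pattern(
                section.get("uas_pattern", "TGT-N10-ACA"),
                int(section.get("uas_mismatches", 0)),
                name="NifA_UAS",
            ),
            rpon_pattern=ps.compile_pattern(
                section.get("rpon_pattern", "TGGCAC-N5-TTGC"),
                int(section.get("rpon_mismatches", 1)),
                name="sigma54",
            ),
            uas_strands=section.get("uas_strands", "both"),
            rpon_strands=section.get("rpon_strands", "+"),
        )
    except (ValueError, TypeError) as exc:
        raise ConfigError(f"bad 'scan' section: {exc}") from exc


def run_pipeline(config_path: str | Path) -> SummaryReport:
    """Run every stage named by the config; returns the summary report.

    All output files land in the config's ``out_dir`` (default
    ``nifregulon_out`` next to the config).
    """
    config_path = Path(config_path)
    cfg = _load_config(config_path)
    base = config_path.parent

    def resolve(key: str) -> Path | None:
        value = cfg.get(key)
        if value is None:
            return None
        path = Path(value)
        return path if path.is_absolute() else base / path

    out_dir = resolve("out_dir") or base / "nifregulon_out"
    out_dir.mkdir(parents=True, exist_ok=True)

    try:
        de_cfg = ex.DEConfig(**(cfg.get("de") or {}))
        operon_cfg = oi.OperonConfig(**(cfg.get("operon") or {}))
        island_cfg = oi.IslandConfig(**(cfg.get("island_detect") or {}))
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"bad threshold section: {exc}") from exc
    scan_cfg = _scan_config(cfg.get("scan") or {})

    report = SummaryReport()

    # ----- expression / fold changes ---------------------------------------
    folds_nfix: pd.Series
    folds_shock: pd.Series
    products: pd.DataFrame | None = None
    if resolve("expression") is not None:
        matrix = ex.ExpressionMatrix.from_tsv(resolve("expression"))
        folds_nfix = ex.compute_fold_changes(matrix, ("nfix", "nexcess"), de_cfg).ratio
        folds_shock = ex.compute_fold_changes(matrix, ("shock10", "nfix"), de_cfg).ratio
        logger.info("expression: %d genes, 3 conditions", len(matrix))
    elif resolve("fold_changes") is not None:
        fixture = io.read_table1(resolve("fold_changes"))
        folds_nfix = fixture.fold_changes("nfix_fold")
        folds_shock = fixture.fold_changes("shock_ratio")
        products = fixture.rows
        logger.info("fold table: %d genes", len(fixture))
    else:
        raise ConfigError("config needs 'expression' or 'fold_changes'")

    labels_nfix = ex.classify_table(folds_nfix, de_cfg)
    labels_shock = ex.classify_table(folds_shock, de_cfg)
    s_nfix = ex.summarize_contrast(labels_nfix)
    s_shock = ex.summarize_contrast(labels_shock)
    report.n_genes = s_nfix.total
    report.n_up_nfix, report.n_down_nfix = s_nfix.n_up, s_nfix.n_down
    report.n_up_shock, report.n_down_shock = s_shock.n_up, s_shock.n_down
    report.n_altered_shock = s_shock.n_altered
    pd.DataFrame({"ratio": folds_nfix, "label": labels_nfix}).to_csv(
        out_dir / "fold_nfix_vs_nexcess.tsv", sep="\t", index_label="gene_id"
    )
    pd.DataFrame({"ratio": folds_shock, "label": labels_shock}).to_csv(
        out_dir / "fold_shock10_vs_nfix.tsv", sep="\t", index_label="gene_id"
    )
    logger.info(
        "contrasts: nfix %d up / %d down; shock %d altered",
        s_nfix.n_up, s_nfix.n_down, s_shock.n_altered,
    )

    # ----- regulon ----------------------------------------------------------
    calls = rg.infer_regulon(labels_nfix, labels_shock)
    members = rg.regulon_members(calls)
    report.n_regulon = len(members)
    rg.calls_to_frame(calls).to_csv(out_dir / "regulon_calls.tsv", sep="\t", index=False)
    logger.info("regulon: %d members", len(members))

    if resolve("orthologs") is not None:
        orthologs = io.read_ortholog_table(resolve("orthologs"))
        required = cfg.get("required_references") or list(orthologs.columns)
        core = rg.core_subset(members, orthologs, required)
        report.n_core_subset = len(core)
        pd.Series(sorted(core)).to_csv(
            out_dir / "core_subset.tsv", sep="\t", index=False, header=["gene_id"]
        )
        logger.info("core subset: %d members retained in %s", len(core), required)
    else:
        core = None
        logger.info("orthologs not supplied; core-subset stage skipped")

    if resolve("core_genome") is not None:
        core_ids = io.read_gene_list(resolve("core_genome"))
        overlap = rg.core_genome_overlap(members, core_ids)
        report.n_core_genome_overlap = len(overlap)
        logger.info("core-genome overlap: %d genes", len(overlap))

    if resolve("category_map") is not None:
        category_map = io.read_category_map(resolve("category_map"))
        summary = rg.categorize_functions(core if core is not None else members, category_map)
        report.category_proportions = dict(sorted(summary.proportions.items()))

    # ----- annotation-backed stages -----------------------------------------
    annotation = None
    genome_seq = None
    if resolve("annotations") is not None and resolve("fasta") is not None:
        annotation = io.read_annotations(
            resolve("annotations"), resolve("fasta"), circular=bool(cfg.get("circular", False))
        )
        _, genome_seq = io.read_fasta(resolve("fasta"))
        logger.info("annotation: %d genes on %s", len(annotation), annotation.genome_id)
    else:
        logger.info("annotation/fasta not supplied; scan/operon/island stages reduced")

    # promoter flags: scanned from sequence for the regulon members, or external
    promoters: dict[str, ps.PromoterAnnotation] | None = None
    flags_frame: pd.DataFrame | None = None
    if resolve("promoter_flags") is not None:
        fixture = io.read_table1(resolve("promoter_flags"))
        promoters = {
            row.locus_id: ps.PromoterAnnotation(row.locus_id, [], [], row.nifa_flag or "No", row.rpon_flag or "No")
            for row in fixture.rows.itertuples()
        }
    elif annotation is not None and genome_seq is not None:
        scan_targets = [annotation[m] for m in sorted(members) if m in annotation]
        promoters = ps.annotate_genes(scan_targets, genome_seq, scan_cfg, circular=annotation.circular)
    if promoters is not None:
        report.n_yes_yes_promoters = sum(
            1 for p in promoters.values() if p.nifa_flag == "Yes" and p.rpon_flag == "Yes"
        )
        flags_frame = pd.DataFrame(
            {
                "gene_id": list(promoters),
                "nifa_flag": [p.nifa_flag for p in promoters.values()],
                "rpon_flag": [p.rpon_flag for p in promoters.values()],
            }
        )
        flags_frame.to_csv(out_dir / "promoter_flags.tsv", sep="\t", index=False)
        logger.info("promoters: %d double-Yes", report.n_yes_yes_promoters)

    # ----- islands ----------------------------------------------------------
    islands: list[oi.ExpressionIsland] = []
    island_range = cfg.get("island")
    if annotation is not None:
        islands = oi.detect_islands(annotation, oi.member_flags(annotation, members), island_cfg)
        report.islands = [
            {
                "first_locus": isl.first_locus,
                "last_locus": isl.last_locus,
                "n_members": isl.gene_count,
                "span_bp": isl.span_bp,
            }
            for isl in islands
        ]
        io.write_bed(
            [
                (
                    annotation.genome_id,
                    min(annotation[l].start for l in isl.member_loci),
                    max(annotation[l].end for l in isl.member_loci),
                    f"island_{i + 1}",
                    isl.gene_count,
                    "+",
                )
                for i, isl in enumerate(islands)
            ],
            out_dir / "islands.bed",
        )
        logger.info("islands: %d detected", len(islands))

    if island_range is not None:
        inside, outside = rg.island_partition(members, tuple(island_range), annotation)
    elif islands:
        largest = max(islands, key=lambda isl: isl.gene_count)
        lo = min(annotation[l].start for l in largest.member_loci)
        hi = max(annotation[l].end for l in largest.member_loci)
        inside, outside = rg.island_partition(members, (lo, hi), annotation)
    else:
        inside, outside = set(), set(members)
    report.n_regulon_in_island = len(inside)
    report.n_regulon_outside = len(outside)

    # ----- operons ----------------------------------------------------------
    if promoters is not None:
        if annotation is not None:
            genes = annotation.genes
            if islands:
                largest = max(islands, key=lambda isl: isl.gene_count)
                i0 = annotation.position(largest.first_locus)
                i1 = annotation.position(largest.last_locus)
                genes = annotation.genes[i0 : i1 + 1]
            sub = io.GenomeAnnotation(
                annotation.genome_id, list(genes), annotation.sequence_length, annotation.circular
            )
            operons = oi.predict_operons(sub, promoters, operon_cfg)
            report.n_operons = len(operons)
            report.n_operon_genes = sum(len(op) for op in operons)
            pd.DataFrame(
                {
                    "operon_id": [f"operon_{i + 1}" for i in range(len(operons))],
                    "leader": [op.leader_locus for op in operons],
                    "strand": [op.strand for op in operons],
                    "n_genes": [len(op) for op in operons],
                    "members": [",".join(op.member_loci) for op in operons],
                }
            ).to_csv(out_dir / "operons.tsv", sep="\t", index=False)
            logger.info(
                "operons: %d covering %d genes", report.n_operons, report.n_operon_genes
            )
        else:
            # without coordinates each double-Yes promoter stands for one operon
            report.n_operons = report.n_yes_yes_promoters

    report.to_json(out_dir / "report.json")
    report.to_tsv(out_dir / "report.tsv")
    if products is not None and promoters is not None:
        table = report_table1_style(folds_shock, folds_nfix, promoters, products)
        io.write_table1(table, out_dir / "island_table.tsv")
    return report


def report_table1_style(
    folds_shock: pd.Series,
    folds_nfix: pd.Series,
    promoters: Mapping[str, ps.PromoterAnnotation] | None = None,
    gene_info: pd.DataFrame | None = None,
) -> io.Table1Fixture:
    """Render per-gene ratios and consensus flags in the worked-example layout.

    One row per gene in ``folds_nfix`` order with columns locus, gene name,
    product, ammonium-shock ratio, nitrogen-fixation fold, NifA flag, RpoN
    flag.  Genes absent from the promoter set get blank flags (the
    "not evaluated" third state).
    """
    promoters = promoters or {}
    names: dict[str, str] = {}
    prods: dict[str, str] = {}
    if gene_info is not None:
        names = dict(zip(gene_info["locus_id"], gene_info.get("gene_name", "")))
        prods = dict(zip(gene_info["locus_id"], gene_info.get("product", "")))
    rows = []
    for locus in folds_nfix.index:
        promoter = promoters.get(locus)
        rows.append(
            {
                "locus_id": locus,
                "gene_name": names.get(locus, ""),
                "product": prods.get(locus, ""),
                "shock_ratio": float(folds_shock[locus]),
                "nfix_fold": float(folds_nfix[locus]),
                "nifa_flag": promoter.nifa_flag if promoter else "",
                "rpon_flag": promoter.rpon_flag if promoter else "",
            }
        )
    return io.Table1Fixture(rows=pd.DataFrame(rows))


_SUPPLEMENTARY_FILES = {
    "n_up_nfix": "s1_up.txt",
    "n_down_nfix": "s1_down.txt",
    "n_down_shock": "s2_down.txt",
    "n_up_shock": "s2_up.txt",
    "n_regulon": "s3_regulon.txt",
}


def reproduce_supplementary_counts(
    directory: str | Path,
    island: tuple[str, str] = ("PST1302", "PST1359"),
) -> dict[str, int]:
    """Recompute the study's headline counts from its deposited gene lists.

    Expects one gene ID per line in ``s1_up.txt`` / ``s1_down.txt``
    (nitrogen fixation vs. excess), ``s2_up.txt`` / ``s2_down.txt``
    (ammonium shock), ``s3_regulon.txt`` (fixation-inducible regulon) and,
    optionally, ``s3_core.txt`` (the ortholog-backed core subset) inside
    ``directory``.  Returns the derived counts, including the
    inside/outside island partition of the regulon.
    """
    directory = Path(directory)
    lists: dict[str, set[str]] = {}
    for key, fname in _SUPPLEMENTARY_FILES.items():
        path = directory / fname
        if not path.exists():
            raise FileNotFoundError(
                f"supplementary gene list {fname} not found under {directory}"
            )
        lists[key] = io.read_gene_list(path)
    counts = {key: len(ids) for key, ids in lists.items()}
    counts["n_altered_shock"] = counts["n_up_shock"] + counts["n_down_shock"]
    inside, outside = rg.island_partition(lists["n_regulon"], island)
    counts["n_regulon_in_island"] = len(inside)
    counts["n_regulon_outside"] = len(outside)
    core_path = directory / "s3_core.txt"
    if core_path.exists():
        counts["n_core_subset"] = len(io.read_gene_list(core_path) & lists["n_regulon"])
    return counts
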