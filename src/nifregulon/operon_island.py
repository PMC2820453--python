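"""Operon prediction from promoter flags and expression-island detection.

Operons: every gene flagged Yes for both the NifA UAS and the σ54 element
seeds an operon; the operon extends in the direction of transcription over
consecutive same-strand genes with small intergenic gaps, stopping when the
next gene carries its own double-Yes promoter.  Genes with a No or blank
flag are legitimate internal operon members — in the worked island example
most operon-internal genes have blank consensus cells.

Islands: maximal runs of regulon-member genes in genome order, tolerating a
bounded number of consecutive non-member genes inside a run (the A1501 nif
island interleaves a few non-regulon genes among its 52 members).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io_formats import GeneRecord, GenomeAnnotation
from .promoter_scan import PromoterAnnotation

__all__ = [
    "Operon",
    "ExpressionIsland",
    "OperonConfig",
    "IslandConfig",
    "predict_operons",
    "detect_islands",
    "island_span",
    "member_flags",
]


@dataclass(frozen=True)
class OperonConfig:
    max_intergenic_gap: int = 200
    require_same_strand: bool = True

    def __post_init__(self) -> None:
        if self.max_intergenic_gap < 0:
            raise ValueError("max_intergenic_gap must be >= 0")


@dataclass(frozen=True)
class IslandConfig:
    min_genes: int = 5
    max_gap_genes: int = 4

    def __post_init__(self) -> None:
        if self.min_genes < 1:
            raise ValueError("min_genes must be >= 1")
        if self.max_gap_genes < 0:
            raise ValueError("max_gap_genes must be >= 0")


@dataclass
class Operon:
    """A transcription unit: leader gene plus downstream members in order."""

    leader_locus: str
    member_loci: list[str]
    strand: str
    promoter: PromoterAnnotation | None = None

    def __len__(self) -> int:
        return len(self.member_loci)


@dataclass
class ExpressionIsland:
    """A contiguous run of co-regulated genes on the chromosome."""

    first_locus: str
    last_locus: str
    gene_count: int
    span_bp: int
    member_loci: list[str]


def _has_yes_yes(ann: PromoterAnnotation | None) -> bool:
    return ann is not None and ann.nifa_flag == "Yes" and ann.rpon_flag == "Yes"


def predict_operons(
    annotation: GenomeAnnotation,
    promoters: Mapping[str, PromoterAnnotation],
    cfg: OperonConfig | None = None,
) -> list[Operon]:
    """Predict one operon per double-Yes promoter.

    Extension follows transcription direction: rightwards along the genome
    for a plus-strand leader, leftwards for a minus-strand leader.  It
    continues while the next gene keeps the leader's strand, the intergenic
    gap stays within ``max_intergenic_gap``, and the next gene does not
    itself carry a double-Yes promoter (which starts a new operon).
    Operons are returned in leader genome order.
    """
    cfg = cfg or OperonConfig()
    genes = annotation.genes
    starts = [g.start for g in genes]
    if starts != sorted(starts):
        raise ValueError("annotation must be sorted by start")

    def gap(left: GeneRecord, right: GeneRecord) -> int:
        return right.start - left.end

    operons: list[Operon] = []
    for i, leader in enumerate(genes):
        promoter = promoters.get(leader.locus_id)
        if not _has_yes_yes(promoter):
            continue
        members = [leader.locus_id]
        step = 1 if leader.strand == "+" else -1
        j = i
        while True:
            k = j + step
            if not (0 <= k < len(genes)):
                break
            nxt = genes[k]
            if cfg.require_same_strand and nxt.strand != leader.strand:
                break
            g = gap(genes[j], nxt) if step == 1 else gap(nxt, genes[j])
            if g > cfg.max_intergenic_gap:
                break
            if _has_yes_yes(promoters.get(nxt.locus_id)):
                break
            members.append(nxt.locus_id)
            j = k
        operons.append(
            Operon(
                leader_locus=leader.locus_id,
                member_loci=members,
                strand=leader.strand,
                promoter=promoter,
            )
        )
    return operons


def member_flags(annotation: GenomeAnnotation, members: Iterable[str]) -> list[bool]:
    """Genome-ordered membership flags from a member-locus set."""
    members = set(members)
    return [g.locus_id in members for g in annotation.genes]


def detect_islands(
    annotation: GenomeAnnotation,
    flags: Sequence[bool] | Iterable[str],
    cfg: IslandConfig | None = None,
) -> list[ExpressionIsland]:
    """Find maximal member runs along the gene order.

    ``flags`` is either a boolean vector aligned to the annotation's gene
    order or a collection of member locus IDs.  Two member genes belong to
    the same island when at most ``max_gap_genes`` consecutive non-members
    separate them; island boundaries are always member genes.  Runs with
    fewer than ``min_genes`` members are dropped.  ``gene_count`` counts
    member genes only.
    """
    cfg = cfg or IslandConfig()
    if isinstance(flags, np.ndarray):
        flags = [bool(x) for x in flags]
    elif isinstance(flags, Sequence) and not isinstance(flags, str):
        if flags and isinstance(flags[0], str):
            flags = member_flags(annotation, flags)
        else:
            flags = [bool(x) for x in flags]
    else:
        flags = member_flags(annotation, flags)
    if len(flags) != len(annotation.genes):
        raise ValueError(
            f"flag vector length {len(flags)} != number of genes {len(annotation.genes)}"
        )
    member_idx = [i for i, f in enumerate(flags) if f]
    islands: list[ExpressionIsland] = []
    run: list[int] = []
    for idx in member_idx:
        if run and idx - run[-1] - 1 > cfg.max_gap_genes:
            islands.extend(_emit(annotation, run, cfg))
            run = []
        run.append(idx)
    islands.extend(_emit(annotation, run, cfg))
    return islands


def _emit(annotation: GenomeAnnotation, run: list[int], cfg: IslandConfig) -> list[ExpressionIsland]:
    if len(run) < cfg.min_genes:
        return []
    members = [annotation.genes[i] for i in run]
    return [
        ExpressionIsland(
            first_locus=members[0].locus_id,
            last_locus=members[-1].locus_id,
            gene_count=len(members),
            span_bp=max(g.end for g in members) - min(g.start for g in members),
            member_loci=[g.locus_id for g in members],
        )
    ]


def island_span(island: ExpressionIsland, annotation: GenomeAnnotation) -> int:
    """Recompute an island's bp span (max end - min start over members)."""
    genes = [annotation[locus] for locus in island.member_loci]
    if not genes:
        raise ValueError("island has no members")
    return max(g.end for g in genes) - min(g.start for g in genes)
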