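"""Regulon inference and derived gene-set operations.

A nitrogen-fixation-inducible regulon is defined purely by condition
intersection: a gene is a member iff it is up under nitrogen fixation
(vs. nitrogen excess) AND down 10 minutes after ammonium shock (vs.
nitrogen fixation).  Downstream set operations derive the ortholog-backed
core subset, the overlap with a species core genome, the inside/outside
partition against the nif island, and functional-category summaries.

Orthology enters only as a presence/absence table (how orthologs were
called is outside this package's scope).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .expression import DOWN, UP
from .io_formats import GenomeAnnotation

__all__ = [
    "RegulonCall",
    "CategorySummary",
    "infer_regulon",
    "regulon_members",
    "core_subset",
    "core_genome_overlap",
    "island_partition",
    "categorize_functions",
    "calls_to_frame",
]


@dataclass(frozen=True)
class RegulonCall:
    locus_id: str
    up_in_nfix: bool
    down_after_shock: bool

    @property
    def member(self) -> bool:
        return self.up_in_nfix and self.down_after_shock


@dataclass
class CategorySummary:
    """Per-category gene counts and proportions of the summarized set."""

    counts: dict[str, int]
    proportions: dict[str, float]

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def infer_regulon(
    labels_nfix: Mapping[str, str] | pd.Series,
    labels_shock: Mapping[str, str] | pd.Series,
) -> list[RegulonCall]:
    """Intersect two label maps into per-gene regulon calls.

    ``labels_nfix`` labels the nitrogen-fixation vs. nitrogen-excess
    contrast, ``labels_shock`` the shock-10-min vs. nitrogen-fixation
    contrast.  Both must cover the same gene universe.
    """
    nfix = dict(labels_nfix.items() if hasattr(labels_nfix, "items") else labels_nfix)
    shock = dict(labels_shock.items() if hasattr(labels_shock, "items") else labels_shock)
    if set(nfix) != set(shock):
        extra = set(nfix) ^ set(shock)
        raise ValueError(f"gene universes differ between contrasts (e.g. {sorted(extra)[:3]})")
    return [
        RegulonCall(locus, nfix[locus] == UP, shock[locus] == DOWN)
        for locus in nfix
    ]


def regulon_members(calls: Iterable[RegulonCall]) -> set[str]:
    return {c.locus_id for c in calls if c.member}


def core_subset(
    members: Iterable[str],
    orthologs: pd.DataFrame,
    required: Sequence[str],
) -> set[str]:
    """Members with an ortholog in *every* required reference genome.

    ``orthologs`` is a boolean gene-by-reference frame; a gene absent from
    the table is absent from every reference.  With ``required`` empty the
    conjunction is vacuous and the full member set is returned.
    """
    unknown = [r for r in required if r not in orthologs.columns]
    if unknown:
        raise KeyError(f"unknown reference genome(s) {unknown}; have {list(orthologs.columns)}")
    members = set(members)
    if not required:
        return members
    present = orthologs[list(required)].all(axis=1)
    retained = set(present.index[present])
    return members & retained


def core_genome_overlap(members: Iterable[str], core_genome_ids: Iterable[str]) -> set[str]:
    """Regulon members that also belong to the species core genome."""
    return set(members) & set(core_genome_ids)


def _locus_number(locus_id: str) -> tuple[str, int]:
    """Split a locus ID like 'PST1302' into ('PST', 1302) for range tests."""
    i = len(locus_id)
    while i > 0 and locus_id[i - 1].isdigit():
        i -= 1
    if i == len(locus_id):
        raise ValueError(f"locus ID {locus_id!r} has no numeric suffix")
    return locus_id[:i], int(locus_id[i:])


def island_partition(
    members: Iterable[str],
    island: tuple[str, str] | tuple[int, int],
    annotation: GenomeAnnotation | None = None,
) -> tuple[set[str], set[str]]:
    """Partition regulon members into (inside, outside) a genomic island.

    The island is either a locus-ID range like ``("PST1302", "PST1359")``
    (membership by numeric locus suffix, matching prefixes required) or a
    bp interval ``(start, end)`` (0-based half-open; membership by gene-body
    overlap, requires ``annotation``).
    """
    members = set(members)
    lo, hi = island
    if isinstance(lo, str) and isinstance(hi, str):
        prefix_lo, n_lo = _locus_number(lo)
        prefix_hi, n_hi = _locus_number(hi)
        if prefix_lo != prefix_hi:
            raise ValueError(f"island locus range mixes prefixes: {lo!r}..{hi!r}")
        if n_lo > n_hi:
            raise ValueError(f"inverted island range {lo!r}..{hi!r}")

        def inside(locus: str) -> bool:
            try:
                prefix, n = _locus_number(locus)
            except ValueError:
                return False
            return prefix == prefix_lo and n_lo <= n <= n_hi

    else:
        if annotation is None:
            raise ValueError("bp-interval island membership requires a GenomeAnnotation")
        if not (0 <= lo < hi):
            raise ValueError(f"malformed island interval [{lo}, {hi})")

        def inside(locus: str) -> bool:
            g = annotation[locus]
            return g.start < hi and g.end > lo  # gene-body overlap

    inside_set = {m for m in members if inside(m)}
    return inside_set, members - inside_set


def categorize_functions(
    gene_set: Iterable[str],
    category_map: Mapping[str, str],
    unmapped_label: str = "unknown",
) -> CategorySummary:
    """Count genes per functional category; unmapped genes go to ``unknown``.

    Proportions are fractions of the summarized set and sum to 1; an empty
    set yields an empty summary.
    """
    counts: dict[str, int] = {}
    genes = set(gene_set)
    for gene in genes:
        cat = category_map.get(gene, unmapped_label) or unmapped_label
        counts[cat] = counts.get(cat, 0) + 1
    total = len(genes)
    proportions = {cat: n / total for cat, n in counts.items()} if total else {}
    return CategorySummary(counts=counts, proportions=proportions)


def calls_to_frame(calls: Iterable[RegulonCall]) -> pd.DataFrame:
    """Regulon calls as a TSV-ready frame (gene_id, flags, membership)."""
    rows = [
        {
            "gene_id": c.locus_id,
            "up_in_nfix": c.up_in_nfix,
            "down_after_shock": c.down_after_shock,
            "member": c.member,
        }
        for c in sorted(calls, key=lambda c: c.locus_id)
    ]
    return pd.DataFrame(rows, columns=["gene_id", "up_in_nfix", "down_after_shock", "member"])
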