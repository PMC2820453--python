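"""Readers and writers for the external file formats used by the pipeline.

This module is the single home for coordinate and dialect conventions:

* Internally every interval is **0-based, half-open** ``[start, end)``.
* GFF3 is 1-based inclusive at the boundary; the conversion
  ``start_internal = start_gff - 1``, ``end_internal = end_gff`` is applied
  on read and inverted on write (an involution).
* TSV files are tab-separated with a header row; ``.`` denotes a missing
  value (blank gene name, unevaluated consensus flag).
* Fold-change ratios are linear scale, never log2.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

MISSING = "."

__all__ = [
    "GeneRecord",
    "GenomeAnnotation",
    "Table1Fixture",
    "read_annotations",
    "write_annotations",
    "read_fasta",
    "write_fasta",
    "read_table1",
    "write_table1",
    "write_bed",
    "read_ortholog_table",
    "read_gene_list",
    "read_category_map",
]


class FormatError(ValueError):
    """Malformed input file (duplicate IDs, bad columns, bad values)."""


class CoordinateError(ValueError):
    """A feature lies outside the bounds of its genome sequence."""


@dataclass(frozen=True)
class GeneRecord:
    """One annotated gene.

    Coordinates are 0-based half-open on the forward strand regardless of
    the gene's own strand (``start < end`` always).
    """

    locus_id: str
    start: int
    end: int
    strand: str
    name: str | None = None
    product: str = ""
    category: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"{self.locus_id}: need 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.locus_id}: strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GenomeAnnotation:
    """An ordered gene catalogue for one (usually circular) bacterial genome."""

    genome_id: str
    genes: list[GeneRecord]
    sequence_length: int
    circular: bool = False
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        starts = [g.start for g in self.genes]
        if starts != sorted(starts):
            raise ValueError("genes must be sorted ascending by start")
        seen: set[str] = set()
        for g in self.genes:
            if g.locus_id in seen:
                raise FormatError(f"duplicate locus_id {g.locus_id!r}")
            seen.add(g.locus_id)
            if g.end > self.sequence_length:
                raise CoordinateError(
                    f"{g.locus_id} ends at {g.end} beyond sequence length {self.sequence_length}"
                )
        self._index = {g.locus_id: i for i, g in enumerate(self.genes)}

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def __contains__(self, locus_id: str) -> bool:
        return locus_id in self._index

    def __getitem__(self, locus_id: str) -> GeneRecord:
        try:
            return self.genes[self._index[locus_id]]
        except KeyError:
            raise KeyError(f"unknown locus {locus_id!r} in genome {self.genome_id}") from None

    def position(self, locus_id: str) -> int:
        """Genome-order index of a locus."""
        if locus_id not in self._index:
            raise KeyError(f"unknown locus {locus_id!r} in genome {self.genome_id}")
        return self._index[locus_id]

    @property
    def loci(self) -> list[str]:
        return [g.locus_id for g in self.genes]


@dataclass
class Table1Fixture:
    """Per-gene shock/nitrogen-fixation ratios and promoter-consensus flags.

    Mirrors the worked-example table for the A1501 nitrogen fixation island:
    one row per locus with the linear-scale ammonium-shock ratio, the
    nitrogen-fixation fold, and the NifA / RpoN consensus flags.  A blank
    flag is a distinct third state ("not evaluated / operon-internal
    member"), not "No".
    """

    rows: pd.DataFrame  # columns: locus_id, gene_name, product, shock_ratio, nfix_fold, nifa_flag, rpon_flag

    def __post_init__(self) -> None:
        for col in ("shock_ratio", "nfix_fold"):
            bad = self.rows[~(self.rows[col] > 0)]
            if len(bad):
                raise FormatError(f"non-positive {col} for {bad['locus_id'].iloc[0]}")
        for col in ("nifa_flag", "rpon_flag"):
            bad = set(self.rows[col]) - {"Yes", "No", ""}
            if bad:
                raise FormatError(f"{col} must be Yes/No/blank, got {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def loci(self) -> list[str]:
        return list(self.rows["locus_id"])

    def yes_yes_loci(self) -> list[str]:
        """Loci flagged Yes in both consensus columns (putative operon leaders)."""
        m = (self.rows["nifa_flag"] == "Yes") & (self.rows["rpon_flag"] == "Yes")
        return list(self.rows.loc[m, "locus_id"])

    def fold_changes(self, column: str) -> pd.Series:
        """Linear-scale ratios for one contrast column, indexed by locus."""
        return self.rows.set_index("locus_id")[column]


# ---------------------------------------------------------------------------
# GFF3 + FASTA


def read_fasta(path: str | os.PathLike) -> tuple[str, str]:
    """Read the first record of a FASTA file as ``(record_id, sequence)``."""
    record = next(SeqIO.parse(str(path), "fasta"))
    return record.id, str(record.seq).upper()


def write_fasta(seq: str, genome_id: str, path: str | os.PathLike, width: int = 70) -> None:
    SeqIO.write([SeqRecord(Seq(seq), id=genome_id, description="")], str(path), "fasta")


def _attr_first(feature, *keys: str) -> str | None:
    for key in keys:
        if key in feature.attributes:
            return feature.attributes[key][0]
    return None


def read_annotations(
    path: str | os.PathLike,
    fasta_path: str | os.PathLike,
    circular: bool = False,
) -> GenomeAnnotation:
    """Read gene annotations from GFF3 (+ FASTA for the sequence bound).

    Features of type ``gene`` (falling back to ``CDS`` if the file has no
    gene features) carrying a ``locus_tag`` attribute become
    :class:`GeneRecord` objects; 1-based inclusive GFF coordinates are
    converted to the internal 0-based half-open convention.
    """
    genome_id, seq = read_fasta(fasta_path)
    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
    except gffutils.exceptions.EmptyInputError:
        return GenomeAnnotation(genome_id, [], len(seq), circular=circular)
    feature_types = set(db.featuretypes())
    ftype = "gene" if "gene" in feature_types else "CDS"
    genes: list[GeneRecord] = []
    seen: set[str] = set()
    for feat in db.features_of_type(ftype, order_by="start"):
        locus = _attr_first(feat, "locus_tag", "ID")
        if locus is None:
            raise FormatError(f"feature at {feat.start}..{feat.end} lacks a locus_tag")
        if locus in seen:
            raise FormatError(f"duplicate locus_tag {locus!r}")
        seen.add(locus)
        if feat.end > len(seq):
            raise CoordinateError(
                f"{locus} ends at {feat.end} beyond sequence length {len(seq)}"
            )
        genes.append(
            GeneRecord(
                locus_id=locus,
                start=feat.start - 1,  # GFF 1-based inclusive -> 0-based half-open
                end=feat.end,
                strand=feat.strand if feat.strand in ("+", "-") else "+",
                name=_attr_first(feat, "gene", "Name"),
                product=_attr_first(feat, "product") or "",
                category=_attr_first(feat, "category"),
            )
        )
    return GenomeAnnotation(
        genome_id=genome_id,
        genes=genes,
        sequence_length=len(seq),
        circular=circular,
    )


def write_annotations(annotation: GenomeAnnotation, path: str | os.PathLike) -> None:
    """Write gene features as GFF3 (inverse of :func:`read_annotations`)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {annotation.genome_id} 1 {annotation.sequence_length}\n")
        for g in annotation.genes:
            attrs = [f"ID={g.locus_id}", f"locus_tag={g.locus_id}"]
            if g.name:
                attrs.append(f"gene={g.name}")
            if g.product:
                attrs.append(f"product={g.product}")
            if g.category:
                attrs.append(f"category={g.category}")
            fh.write(
                "\t".join(
                    [
                        annotation.genome_id,
                        "nifregulon",
                        "gene",
                        str(g.start + 1),  # back to 1-based inclusive
                        str(g.end),
                        ".",
                        g.strand,
                        ".",
                        ";".join(attrs),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Worked-example table


_TABLE1_CORE = ["locus_id", "gene_name", "shock_ratio", "nfix_fold", "nifa_flag", "rpon_flag"]


def read_table1(path: str | os.PathLike) -> Table1Fixture:
    """Read the island worked-example TSV.

    Requires the six core columns (locus, gene name, shock ratio,
    nitrogen-fixation fold, NifA flag, RpoN flag); a ``product`` column is
    optional.  Blank cells (``.`` or empty) are preserved as blank.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _TABLE1_CORE if c not in df.columns]
    if missing:
        raise FormatError(f"table is missing columns {missing}")
    if "product" not in df.columns:
        df["product"] = ""
    for col in ("gene_name", "product", "nifa_flag", "rpon_flag"):
        df[col] = df[col].replace(MISSING, "")
    for col in ("shock_ratio", "nfix_fold"):
        try:
            df[col] = df[col].astype(float)
        except ValueError as exc:
            raise FormatError(f"non-numeric value in column {col}: {exc}") from None
    cols = ["locus_id", "gene_name", "product", "shock_ratio", "nfix_fold", "nifa_flag", "rpon_flag"]
    return Table1Fixture(rows=df[cols].reset_index(drop=True))


def write_table1(fixture: Table1Fixture, path: str | os.PathLike) -> None:
    df = fixture.rows.copy()
    for col in ("gene_name", "product", "nifa_flag", "rpon_flag"):
        df[col] = df[col].replace("", MISSING)
    df.to_csv(path, sep="\t", index=False, float_format="%.2f")


# ---------------------------------------------------------------------------
# BED6


def write_bed(
    intervals: Iterable[tuple[str, int, int, str, float | int, str]],
    path: str | os.PathLike,
) -> None:
    """Write 0-based half-open intervals as 6-column BED."""
    lines = []
    for chrom, start, end, name, score, strand in intervals:
        if start >= end:
            raise ValueError(f"empty/inverted interval [{start}, {end}) for {name!r}")
        lines.append(f"{chrom}\t{start}\t{end}\t{name}\t{score}\t{strand}\n")
    with open(path, "w") as fh:
        fh.writelines(lines)


# ---------------------------------------------------------------------------
# Simple TSV side-tables


def read_ortholog_table(path: str | os.PathLike) -> pd.DataFrame:
    """Gene-by-reference presence/absence table.

    First column is the gene ID; every other column is one reference genome
    with boolean-ish values (1/0, True/False, Yes/No).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    df = df.set_index(df.columns[0])
    truthy = {"1", "true", "yes", "y"}
    falsy = {"0", "false", "no", "n", ""}
    out = pd.DataFrame(index=df.index)
    for col in df.columns:
        vals = df[col].str.strip().str.lower()
        bad = set(vals) - truthy - falsy
        if bad:
            raise FormatError(f"non-boolean value(s) {sorted(bad)} in column {col!r}")
        out[col] = vals.isin(truthy)
    return out


def read_gene_list(path: str | os.PathLike) -> set[str]:
    """One gene ID per line (or first column of a headered TSV)."""
    ids: set[str] = set()
    with open(path) as fh:
        for i, line in enumerate(fh):
            token = line.strip().split("\t")[0]
            if not token or token.startswith("#"):
                continue
            if i == 0 and token.lower() in ("gene_id", "locus_id", "id"):
                continue
            ids.add(token)
    return ids


def read_category_map(path: str | os.PathLike) -> dict[str, str]:
    """Two-column TSV ``gene_id<TAB>category`` -> dict."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise FormatError("category map needs two columns: gene_id, category")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))
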