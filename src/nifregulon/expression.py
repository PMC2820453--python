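"""Fold-change computation and up/down/unchanged classification.

Expression values are normalized per-gene intensity means, one column per
condition.  The canonical condition labels are ``nfix`` (nitrogen fixation:
0.1 mM ammonium, 0.5% oxygen), ``nexcess`` (20 mM ammonium) and ``shock10``
(10 min after a sudden shift from fixation to 20 mM ammonium).  Ratios are
kept on the linear scale throughout; log2 is a reporting concern only.
"""

from __future__ import annotations

import os
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd

UP, DOWN, UNCHANGED = "up", "down", "unchanged"

CONDITIONS = ("nfix", "nexcess", "shock10")

__all__ = [
    "DEConfig",
    "ExpressionMatrix",
    "FoldChangeTable",
    "ContrastSummary",
    "compute_fold_changes",
    "classify_regulation",
    "classify_table",
    "summarize_contrast",
]


@dataclass(frozen=True)
class DEConfig:
    """Thresholds for the two-fold differential-expression rule.

    Boundary values are inclusive: a gene at exactly ``up_cut`` is called
    up, at exactly ``down_cut`` down.  ``pseudocount`` is added to both
    sides of a ratio to stabilise small intensities (0 by default: the
    input contract already requires positive values).
    """

    up_cut: float = 2.0
    down_cut: float = 0.5
    pseudocount: float = 0.0

    def __post_init__(self) -> None:
        if not (self.down_cut < 1.0 < self.up_cut):
            raise ValueError(f"need down_cut < 1 < up_cut, got {self.down_cut}, {self.up_cut}")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")


class ExpressionMatrix:
    """Per-gene positive intensity means, one column per condition."""

    def __init__(self, values: pd.DataFrame):
        if values.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        if len(values) and not (values > 0).all().all():
            raise ValueError("expression intensities must be positive")
        self.values = values.astype(float)

    @property
    def condition_labels(self) -> list[str]:
        return list(self.values.columns)

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    def __len__(self) -> int:
        return len(self.values)

    def condition(self, label: str) -> pd.Series:
        if label not in self.values.columns:
            raise KeyError(f"condition {label!r} not in matrix (have {self.condition_labels})")
        return self.values[label]

    @classmethod
    def from_tsv(cls, path: str | os.PathLike) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df)

    def to_tsv(self, path: str | os.PathLike) -> None:
        self.values.to_csv(path, sep="\t", index_label="gene_id")


@dataclass
class FoldChangeTable:
    """Linear-scale per-gene ratios for one contrast (numerator/denominator)."""

    contrast: tuple[str, str]
    ratio: pd.Series

    def __post_init__(self) -> None:
        if len(self.ratio) and not (self.ratio > 0).all():
            raise ValueError("fold-change ratios must be positive")

    @property
    def genes(self) -> list[str]:
        return list(self.ratio.index)

    def __len__(self) -> int:
        return len(self.ratio)

    def to_tsv(self, path: str | os.PathLike, labels: pd.Series | None = None) -> None:
        df = pd.DataFrame({"ratio": self.ratio})
        if labels is not None:
            df["label"] = labels
        df.to_csv(path, sep="\t", index_label="gene_id", float_format="%.6g")


class ContrastSummary(NamedTuple):
    n_up: int
    n_down: int
    n_unchanged: int

    @property
    def n_altered(self) -> int:
        return self.n_up + self.n_down

    @property
    def total(self) -> int:
        return self.n_up + self.n_down + self.n_unchanged


def compute_fold_changes(
    matrix: ExpressionMatrix,
    contrast: tuple[str, str],
    cfg: DEConfig | None = None,
) -> FoldChangeTable:
    """Per-gene ratio ``(numerator + pc) / (denominator + pc)`` for a contrast."""
    cfg = cfg or DEConfig()
    num_label, den_label = contrast
    num = matrix.condition(num_label) + cfg.pseudocount
    den = matrix.condition(den_label) + cfg.pseudocount
    if (den == 0).any():
        raise ValueError(
            f"zero denominator in condition {den_label!r} with pseudocount {cfg.pseudocount}"
        )
    return FoldChangeTable(contrast=(num_label, den_label), ratio=num / den)


def classify_regulation(fold: float, cfg: DEConfig | None = None) -> str:
    """Label one linear-scale fold change as up / down / unchanged."""
    cfg = cfg or DEConfig()
    if not fold > 0:
        raise ValueError(f"fold change must be positive, got {fold}")
    if fold >= cfg.up_cut:
        return UP
    if fold <= cfg.down_cut:
        return DOWN
    return UNCHANGED


def classify_table(
    folds: FoldChangeTable | pd.Series,
    cfg: DEConfig | None = None,
    include_mask: Mapping[str, bool] | pd.Series | None = None,
) -> pd.Series:
    """Per-gene labels for a whole fold-change table.

    ``include_mask`` is an optional hook for externally supplied
    significance calls: genes with a false mask value are reported
    ``unchanged`` regardless of their ratio.
    """
    cfg = cfg or DEConfig()
    ratio = folds.ratio if isinstance(folds, FoldChangeTable) else folds
    labels = pd.Series(
        [classify_regulation(x, cfg) for x in ratio], index=ratio.index, name="label"
    )
    if include_mask is not None:
        mask = pd.Series(include_mask).reindex(ratio.index)
        if mask.isna().any():
            raise ValueError("include_mask must cover every gene in the fold table")
        labels[~mask.astype(bool)] = UNCHANGED
    return labels


def summarize_contrast(labels: Iterable[str] | pd.Series) -> ContrastSummary:
    """Count up / down / unchanged labels; the counts partition the genes."""
    counts = Counter(labels)
    unknown = set(counts) - {UP, DOWN, UNCHANGED}
    if unknown:
        raise ValueError(f"unknown labels {sorted(unknown)}")
    return ContrastSummary(counts[UP], counts[DOWN], counts[UNCHANGED])
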