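"""Gapped IUPAC motif compilation and scanning for nif promoter elements.

Two elements matter for NifA-σ54-dependent transcription:

* the NifA **upstream activator sequence** (UAS), consensus ``TGT-N10-ACA``,
  an enhancer-like element that must sit well upstream of the transcription
  start (the classic spacing rule: at least 100 bp);
* the σ54 (RpoN) **-24/-12 promoter element**; the canonical family
  consensus is a GG-N10-GC core, modelled here by default as
  ``TGGCAC-N5-TTGC`` with one mismatch allowed, and fully configurable.

Patterns are small gapped IUPAC strings, so scanning is exact sliding-window
mismatch counting (vectorised with numpy), not PWM scoring.  ``N`` in the
*sequence* matches nothing (it counts as a mismatch at every non-gap
position); gap positions in the *pattern* match any base for free.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .io_formats import GeneRecord

IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

__all__ = [
    "MotifPattern",
    "MotifHit",
    "PromoterAnnotation",
    "ScanConfig",
    "compile_pattern",
    "scan_sequence",
    "extract_upstream",
    "UpstreamWindow",
    "annotate_promoter",
    "annotate_genes",
    "revcomp",
]


def revcomp(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MotifPattern:
    """A gapped IUPAC pattern such as TGT-N10-ACA.

    ``blocks`` alternate IUPAC literals and fixed-length gap tokens
    (``N10``); gaps match any base and never count as mismatches.
    """

    name: str
    blocks: tuple[str, ...]
    max_mismatches: int = 0

    def __post_init__(self) -> None:
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")
        if not self.blocks:
            raise ValueError("pattern has no blocks")

    @property
    def total_length(self) -> int:
        return sum(_block_length(b) for b in self.blocks)

    @property
    def position_sets(self) -> tuple[frozenset[str] | None, ...]:
        """Per-position allowed bases; ``None`` marks a free gap position."""
        out: list[frozenset[str] | None] = []
        for block in self.blocks:
            if _is_gap(block):
                out.extend([None] * _block_length(block))
            else:
                out.extend(IUPAC[ch] for ch in block)
        return tuple(out)

    @property
    def spec(self) -> str:
        return "-".join(self.blocks)


_GAP_RE = re.compile(r"^N(\d+)$")


def _is_gap(block: str) -> bool:
    return _GAP_RE.match(block) is not None


def _block_length(block: str) -> int:
    m = _GAP_RE.match(block)
    return int(m.group(1)) if m else len(block)


def compile_pattern(spec: str, max_mismatches: int = 0, name: str | None = None) -> MotifPattern:
    """Compile a dash-separated spec like ``"TGT-N10-ACA"`` into a pattern.

    Tokens are IUPAC literal blocks or ``Nk`` fixed-length gaps.
    """
    blocks = tuple(tok.strip().upper() for tok in spec.split("-"))
    for tok in blocks:
        if not tok:
            raise ValueError(f"empty block in pattern spec {spec!r}")
        if _is_gap(tok):
            if _block_length(tok) == 0:
                raise ValueError(f"zero-length gap in pattern spec {spec!r}")
            continue
        bad = set(tok) - set(IUPAC)
        if bad:
            raise ValueError(f"non-IUPAC letter(s) {sorted(bad)} in pattern spec {spec!r}")
    return MotifPattern(name=name or spec, blocks=blocks, max_mismatches=max_mismatches)


@dataclass(frozen=True)
class MotifHit:
    """One pattern occurrence on a scanned sequence.

    ``position`` is the 0-based offset of the window on the *given*
    sequence regardless of strand.  ``distance_to_start`` (bp between the
    motif's downstream edge and the gene start on the coding strand) is
    filled in by promoter annotation; it is ``None`` for a bare scan.
    """

    pattern: str
    position: int
    strand: str
    mismatches: int
    distance_to_start: int | None = None


def _mismatch_profile(seq: str, pattern: MotifPattern) -> np.ndarray:
    """Mismatch count of every window of ``seq`` against the pattern."""
    L = pattern.total_length
    n_windows = len(seq) - L + 1
    if n_windows <= 0:
        return np.zeros(0, dtype=np.int32)
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    mism = np.zeros(n_windows, dtype=np.int32)
    for offset, allowed in enumerate(pattern.position_sets):
        if allowed is None:
            continue
        codes = np.frombuffer("".join(sorted(allowed)).encode("ascii"), dtype=np.uint8)
        mism += (~np.isin(arr[offset : offset + n_windows], codes)).astype(np.int32)
    return mism


def scan_sequence(
    seq: str,
    pattern: MotifPattern,
    strands: str = "+",
) -> list[MotifHit]:
    """Report every window within the pattern's mismatch budget.

    ``strands`` is ``"+"``, ``"-"`` or ``"both"``.  Minus-strand hits are
    found on the reverse complement but reported with their window position
    on the given sequence.  Hits come back sorted by position, plus before
    minus at ties.  A sequence shorter than the pattern yields no hits.
    """
    if strands not in ("+", "-", "both"):
        raise ValueError(f"strands must be '+', '-' or 'both', got {strands!r}")
    seq = seq.upper()
    L = pattern.total_length
    hits: list[MotifHit] = []
    if strands in ("+", "both"):
        mism = _mismatch_profile(seq, pattern)
        for pos in np.flatnonzero(mism <= pattern.max_mismatches):
            hits.append(MotifHit(pattern.name, int(pos), "+", int(mism[pos])))
    if strands in ("-", "both"):
        rc = revcomp(seq)
        mism = _mismatch_profile(rc, pattern)
        for pos in np.flatnonzero(mism <= pattern.max_mismatches):
            hits.append(
                MotifHit(pattern.name, len(seq) - int(pos) - L, "-", int(mism[pos]))
            )
    hits.sort(key=lambda h: (h.position, h.strand))
    return hits


@dataclass(frozen=True)
class UpstreamWindow:
    """An upstream region oriented on a gene's coding strand.

    ``seq`` reads 5'->3' on the coding strand and ends immediately before
    the gene's translation start; ``genome_start``/``genome_end`` give the
    forward-strand interval it was cut from (0-based half-open).
    """

    seq: str
    genome_start: int
    genome_end: int
    strand: str

    def __len__(self) -> int:
        return len(self.seq)


def extract_upstream(
    gene: GeneRecord,
    genome_seq: str,
    window: int,
    circular: bool = False,
) -> UpstreamWindow:
    """Cut the ``window`` bp upstream of a gene, oriented on its coding strand.

    For a plus-strand gene this is the window ending at ``gene.start``; for
    a minus-strand gene, the reverse complement of the window starting at
    ``gene.end``.  On a linear genome the window is truncated at the contig
    edge; on a circular genome it wraps.
    """
    if window <= 0:
        raise ValueError(f"window must be positive, got {window}")
    n = len(genome_seq)
    if gene.end > n:
        raise ValueError(f"{gene.locus_id} extends beyond the genome sequence")
    if gene.strand == "+":
        lo = gene.start - window
        if lo >= 0:
            return UpstreamWindow(genome_seq[lo : gene.start], lo, gene.start, "+")
        if circular:
            seq = genome_seq[lo % n :] + genome_seq[: gene.start]
            return UpstreamWindow(seq, lo % n, gene.start, "+")
        return UpstreamWindow(genome_seq[: gene.start], 0, gene.start, "+")
    hi = gene.end + window
    if hi <= n:
        return UpstreamWindow(revcomp(genome_seq[gene.end : hi]), gene.end, hi, "-")
    if circular:
        seq = genome_seq[gene.end :] + genome_seq[: hi % n]
        return UpstreamWindow(revcomp(seq), gene.end, hi % n, "-")
    return UpstreamWindow(revcomp(genome_seq[gene.end :]), gene.end, n, "-")


def _default_uas() -> MotifPattern:
    return compile_pattern("TGT-N10-ACA", max_mismatches=0, name="NifA_UAS")


def _default_rpon() -> MotifPattern:
    return compile_pattern("TGGCAC-N5-TTGC", max_mismatches=1, name="sigma54")


@dataclass(frozen=True)
class ScanConfig:
    """Knobs of the promoter annotation.

    The UAS is searched on both strands by default (enhancer-like elements
    are orientation-tolerant); the σ54 element on the coding strand only.
    ``min_uas_distance`` encodes the spacing rule: a UAS only activates a
    NifA flag when its downstream edge lies at least that far upstream of
    the gene start.
    """

    upstream_window: int = 400
    min_uas_distance: int = 100
    uas_pattern: MotifPattern = field(default_factory=_default_uas)
    rpon_pattern: MotifPattern = field(default_factory=_default_rpon)
    uas_strands: str = "both"
    rpon_strands: str = "+"

    def __post_init__(self) -> None:
        if self.upstream_window <= self.min_uas_distance + self.uas_pattern.total_length:
            raise ValueError(
                "upstream_window must exceed min_uas_distance + UAS length "
                f"({self.min_uas_distance} + {self.uas_pattern.total_length})"
            )


@dataclass
class PromoterAnnotation:
    """Per-gene UAS / σ54 hit lists and the derived Yes/No flags."""

    locus_id: str
    uas_hits: list[MotifHit]
    rpon_hits: list[MotifHit]
    nifa_flag: str
    rpon_flag: str


def annotate_promoter(
    gene: GeneRecord,
    upstream_seq: str | UpstreamWindow,
    cfg: ScanConfig | None = None,
) -> PromoterAnnotation:
    """Scan one upstream region and derive the two consensus flags.

    ``nifa_flag`` is Yes iff some UAS hit ends at least
    ``cfg.min_uas_distance`` bp before the gene start; ``rpon_flag`` is Yes
    iff the -24/-12 element matches anywhere in the window.
    """
    cfg = cfg or ScanConfig()
    seq = upstream_seq.seq if isinstance(upstream_seq, UpstreamWindow) else upstream_seq
    L_uas = cfg.uas_pattern.total_length
    uas_hits = [
        replace(h, distance_to_start=len(seq) - (h.position + L_uas))
        for h in scan_sequence(seq, cfg.uas_pattern, cfg.uas_strands)
    ]
    L_rpon = cfg.rpon_pattern.total_length
    rpon_hits = [
        replace(h, distance_to_start=len(seq) - (h.position + L_rpon))
        for h in scan_sequence(seq, cfg.rpon_pattern, cfg.rpon_strands)
    ]
    nifa = any(h.distance_to_start >= cfg.min_uas_distance for h in uas_hits)
    return PromoterAnnotation(
        locus_id=gene.locus_id,
        uas_hits=uas_hits,
        rpon_hits=rpon_hits,
        nifa_flag="Yes" if nifa else "No",
        rpon_flag="Yes" if rpon_hits else "No",
    )


def annotate_genes(
    genes: Sequence[GeneRecord],
    genome_seq: str,
    cfg: ScanConfig | None = None,
    circular: bool = False,
) -> dict[str, PromoterAnnotation]:
    """Promoter annotation for a set of genes against one genome sequence."""
    cfg = cfg or ScanConfig()
    out: dict[str, PromoterAnnotation] = {}
    for gene in genes:
        window = extract_upstream(gene, genome_seq, cfg.upstream_window, circular=circular)
        out[gene.locus_id] = annotate_promoter(gene, window, cfg)
    return out
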