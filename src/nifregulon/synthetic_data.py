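"""Synthetic genomes, expression matrices and ortholog tables with planted truth.

The generator emulates the structure of a diazotroph ammonium-repression
study: a bacterial chromosome carrying one contiguous nitrogen-fixation
island whose operon leaders have planted NifA UAS and σ54 promoter
elements; an expression matrix over two steady states (nitrogen fixation,
nitrogen excess) plus one 10-minute ammonium-shock time point with
multiplicative log-normal noise; and per-reference ortholog
presence/absence tables.  Every output is bit-reproducible given the
simulation spec (the seed is part of the spec).

Planted-truth guarantee: within the upstream windows of island genes the
planted promoter elements are the **only** consensus matches — background
matches arising in random sequence are mutated away (planted spans are
protected).  This makes planted operon structure exactly recoverable;
real genomes, by contrast, contain background consensus matches at the
analytic rate (e.g. 4^-6 per window per strand for the UAS).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix
from .io_formats import GeneRecord, GenomeAnnotation
from .operon_island import ExpressionIsland, Operon
from .promoter_scan import (
    MotifPattern,
    ScanConfig,
    annotate_genes,
    extract_upstream,
    scan_sequence,
)

__all__ = [
    "IslandSpec",
    "SimulationSpec",
    "PlantedMotif",
    "SyntheticTruth",
    "RecoveryMetrics",
    "generate_genome",
    "generate_expression",
    "generate_orthologs",
    "evaluate_recovery",
    "write_dataset",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# category labels and planted draw probabilities for regulon members,
# echoing the functional breakdown of a nitrogen-fixation core subset
_CATEGORY_LABELS = (
    "nif",
    "regulation_signalling",
    "transport_metabolism",
    "energy",
    "unknown",
    "other",
)
_CATEGORY_PROBS = (0.20, 0.07, 0.39, 0.16, 0.16, 0.02)

_MAX_SLOT_GAP = 4  # non-member island genes tolerated between two operons

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


class SpecError(ValueError):
    """Simulation spec is internally inconsistent or geometrically infeasible."""


@dataclass(frozen=True)
class IslandSpec:
    """Planted nif-island architecture.

    ``operon_structure`` lists the member count of each planted operon in
    island order; the structure of the worked example (11 operons totalling
    52 genes inside a 58-gene island) is the default elsewhere.
    """

    start_index: int
    n_island_genes: int
    n_regulon_in_island: int
    operon_structure: tuple[int, ...]

    def __post_init__(self) -> None:
        if any(s < 1 for s in self.operon_structure):
            raise SpecError("operon sizes must be >= 1")
        n_op = sum(self.operon_structure)
        if n_op > self.n_island_genes:
            raise SpecError("operon sizes sum beyond the island gene count")
        if not (n_op <= self.n_regulon_in_island <= self.n_island_genes):
            raise SpecError(
                "need sum(operon sizes) <= n_regulon_in_island <= n_island_genes"
            )
        n_slots = len(self.operon_structure) - 1
        n_interleaved = self.n_island_genes - n_op
        if n_slots == 0 and n_interleaved > 0:
            raise SpecError("a single-operon island cannot interleave extra genes")
        n_gap = self.n_island_genes - self.n_regulon_in_island
        if n_slots and n_gap > n_slots * _MAX_SLOT_GAP:
            raise SpecError(
                "too many non-member island genes to interleave between operons"
            )


def _default_island() -> IslandSpec:
    return IslandSpec(
        start_index=400,
        n_island_genes=58,
        n_regulon_in_island=52,
        operon_structure=(5, 2, 10, 1, 7, 5, 6, 4, 1, 10, 1),
    )


@dataclass(frozen=True)
class SimulationSpec:
    """Study conditions for one synthetic dataset.

    Defaults emulate the design under test: a ~1000-gene chromosome, a
    58-gene island holding 52 regulon genes in 11 operons spanning 49 kb,
    114 further regulon genes scattered outside, a 20-fold induction under
    nitrogen fixation, a 10-fold repression 10 min after ammonium shock,
    log-intensity noise of 0.2, and 0.6 per-reference ortholog retention.
    """

    n_genes: int = 1000
    gene_length_range: tuple[int, int] = (600, 1500)
    intergenic_range: tuple[int, int] = (30, 180)
    island: IslandSpec | None = field(default_factory=_default_island)
    island_span_bp: int | None = 49_000
    n_regulon_outside: int = 114
    effect_size_nfix: float = 20.0
    effect_size_shock: float = 0.1
    noise_sigma: float = 0.2
    baseline_log_mean: float = 7.0
    baseline_log_sigma: float = 0.8
    ortholog_retention: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 0:
            raise SpecError("n_genes must be >= 0")
        if self.effect_size_nfix <= 0 or self.effect_size_shock <= 0:
            raise SpecError("effect sizes are linear folds and must be positive")
        if self.noise_sigma < 0:
            raise SpecError("noise_sigma must be >= 0")
        if not 0.0 <= self.ortholog_retention <= 1.0:
            raise SpecError("ortholog_retention is a probability")
        lo, hi = self.gene_length_range
        if not 0 < lo <= hi:
            raise SpecError("bad gene_length_range")
        lo, hi = self.intergenic_range
        if not 0 <= lo <= hi:
            raise SpecError("bad intergenic_range")
        if self.island is not None:
            isl = self.island
            if isl.start_index < 0 or isl.start_index + isl.n_island_genes > self.n_genes:
                raise SpecError("island does not fit inside the gene count")
        if self.n_regulon_outside < 0:
            raise SpecError("n_regulon_outside must be >= 0")


class PlantedMotif(NamedTuple):
    locus_id: str
    pattern: str
    start: int  # genome coordinates, 0-based half-open, forward strand
    end: int
    strand: str


@dataclass
class SyntheticTruth:
    """Ground truth planted by the generator, for recovery scoring."""

    loci: list[str]  # every locus, genome order
    regulon_loci: set[str]
    island_member_loci: list[str]  # regulon members inside the island, genome order
    operons: list[tuple[str, tuple[str, ...]]]  # (leader, members in transcription order)
    motif_positions: list[PlantedMotif]
    true_fold_nfix: dict[str, float]
    true_fold_shock: dict[str, float]

    @property
    def island_first(self) -> str | None:
        return self.island_member_loci[0] if self.island_member_loci else None

    @property
    def island_last(self) -> str | None:
        return self.island_member_loci[-1] if self.island_member_loci else None

    @property
    def n_operons(self) -> int:
        return len(self.operons)

    def to_json(self, path) -> None:
        payload = {
            "loci": self.loci,
            "regulon_loci": sorted(self.regulon_loci),
            "island_member_loci": self.island_member_loci,
            "operons": [[leader, list(members)] for leader, members in self.operons],
            "motif_positions": [list(m) for m in self.motif_positions],
            "true_fold_nfix": self.true_fold_nfix,
            "true_fold_shock": self.true_fold_shock,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


# ---------------------------------------------------------------------------
# genome generation


class _GenePlan(NamedTuple):
    role: str  # outside | leader | operon_member | island_gap | island_extra
    operon_index: int | None


def _island_plan(isl: IslandSpec) -> list[_GenePlan]:
    """Order of roles inside the island: operons with gap genes interleaved."""
    n_ops = len(isl.operon_structure)
    n_gap = isl.n_island_genes - isl.n_regulon_in_island
    n_extra = isl.n_regulon_in_island - sum(isl.operon_structure)
    slots: list[list[_GenePlan]] = [[] for _ in range(max(n_ops - 1, 1))]
    items = [_GenePlan("island_gap", None)] * n_gap + [_GenePlan("island_extra", None)] * n_extra
    for i, item in enumerate(items):
        slots[i % len(slots)].append(item)
    plan: list[_GenePlan] = []
    for k, size in enumerate(isl.operon_structure):
        plan.append(_GenePlan("leader", k))
        plan.extend(_GenePlan("operon_member", k) for _ in range(size - 1))
        if k < n_ops - 1:
            plan.extend(slots[k])
    assert len(plan) == isl.n_island_genes
    return plan


def _plant(seq: np.ndarray, start: int, motif: str) -> None:
    seq[start : start + len(motif)] = np.frombuffer(motif.encode(), dtype=np.uint8)


def _random_bases(rng: np.random.Generator, n: int) -> str:
    return rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=n).tobytes().decode()


def generate_genome(
    spec: SimulationSpec,
    scan_cfg: ScanConfig | None = None,
) -> tuple[GenomeAnnotation, str, SyntheticTruth]:
    """Lay out a random-base genome with the planted island architecture.

    Every operon leader receives a forward-strand UAS ending 100-140 bp
    upstream of its start and a σ54 element ending 8-20 bp upstream.
    Non-member island genes sit on the minus strand in the slots between
    operons; a >200 bp gap flanks the island so the planted operons end
    where planted.  ``scan_cfg`` (default :class:`ScanConfig`) defines the
    windows within which background consensus matches are scrubbed.
    """
    cfg = scan_cfg or ScanConfig()
    rng = np.random.default_rng([spec.seed % (2**31), 0])
    genome_id = "synthetic"

    if spec.n_genes == 0:
        seq = _random_bases(rng, 100)
        ann = GenomeAnnotation(genome_id, [], len(seq), circular=False)
        truth = SyntheticTruth([], set(), [], [], [], {}, {})
        return ann, seq, truth

    isl = spec.island
    plans: list[_GenePlan] = [_GenePlan("outside", None)] * spec.n_genes
    if isl is not None:
        island_plan = _island_plan(isl)
        plans[isl.start_index : isl.start_index + isl.n_island_genes] = island_plan
        assert len(plans) == spec.n_genes

    width = max(4, len(str(spec.n_genes)))
    loci = [f"SYN{i:0{width}d}" for i in range(1, spec.n_genes + 1)]

    # --- geometry -----------------------------------------------------------
    ig_lo, ig_hi = spec.intergenic_range
    len_lo, len_hi = spec.gene_length_range
    in_island = [p.role != "outside" for p in plans]
    island_idx = [i for i, f in enumerate(in_island) if f]

    gaps = np.empty(spec.n_genes, dtype=np.int64)
    lengths = np.empty(spec.n_genes, dtype=np.int64)
    for i, plan in enumerate(plans):
        if plan.role == "leader":
            gaps[i] = rng.integers(260, 381)  # room for UAS spacing + jitter
        elif plan.role == "operon_member":
            hi_m = min(ig_hi, 150)  # keep within-operon gaps below the joining threshold
            gaps[i] = rng.integers(min(ig_lo, hi_m), hi_m + 1)
        elif i and in_island[i - 1] and not in_island[i]:
            gaps[i] = rng.integers(250, 401)  # break extension past the island
        else:
            gaps[i] = rng.integers(ig_lo, ig_hi + 1)
        if in_island[i] and spec.island_span_bp is not None:
            lengths[i] = rng.integers(900, 1401)  # rescaled to the target span below
        else:
            lengths[i] = rng.integers(len_lo, len_hi + 1)
    if island_idx and spec.island_span_bp is not None:
        gap_sum = int(gaps[island_idx[1:]].sum())
        target_len = spec.island_span_bp - gap_sum
        raw = lengths[island_idx]
        if target_len < 150 * len(island_idx):
            raise SpecError("island_span_bp too small for the island gene count")
        scaled = np.floor(raw * (target_len / raw.sum())).astype(np.int64)
        scaled[-1] += target_len - int(scaled.sum())  # absorb rounding residual
        if (scaled < 150).any():
            raise SpecError("island_span_bp scaling produced degenerate gene lengths")
        lengths[island_idx] = scaled

    starts = np.cumsum(gaps + lengths) - lengths
    ends = starts + lengths
    genome_len = int(ends[-1] + rng.integers(ig_lo, ig_hi + 1) + 1)

    # --- strands and regulon membership -------------------------------------
    strands: list[str] = []
    for i, plan in enumerate(plans):
        if plan.role in ("leader", "operon_member"):
            strands.append("+")
        elif plan.role in ("island_gap", "island_extra"):
            strands.append("-")
        else:
            strands.append("+" if rng.random() < 0.5 else "-")

    members: set[str] = set()
    island_member_loci: list[str] = []
    for i, plan in enumerate(plans):
        if plan.role in ("leader", "operon_member", "island_extra"):
            members.add(loci[i])
            island_member_loci.append(loci[i])
    if spec.n_regulon_outside:
        buffer = _MAX_SLOT_GAP + 1  # keep outside members from merging into the island
        if island_idx:
            lo_excl = island_idx[0] - buffer
            hi_excl = island_idx[-1] + buffer
        else:
            lo_excl, hi_excl = 1, 0
        eligible = [
            i
            for i, p in enumerate(plans)
            if p.role == "outside" and not (lo_excl <= i <= hi_excl)
        ]
        if spec.n_regulon_outside > len(eligible):
            raise SpecError("not enough outside genes for n_regulon_outside")
        chosen = rng.choice(len(eligible), size=spec.n_regulon_outside, replace=False)
        members.update(loci[eligible[int(c)]] for c in chosen)

    # --- operon truth --------------------------------------------------------
    operons: list[tuple[str, tuple[str, ...]]] = []
    if isl is not None:
        current: dict[int, list[str]] = {}
        for i, plan in enumerate(plans):
            if plan.operon_index is not None:
                current.setdefault(plan.operon_index, []).append(loci[i])
        operons = [(genes[0], tuple(genes)) for _, genes in sorted(current.items())]

    # --- sequence + planted motifs ------------------------------------------
    seq_arr = rng.choice(_BASES, size=genome_len)
    motifs: list[PlantedMotif] = []
    for i, plan in enumerate(plans):
        if plan.role != "leader":
            continue
        start = int(starts[i])
        uas = "TGT" + _random_bases(rng, 10) + "ACA"
        d_uas = int(rng.integers(100, 141))  # spacing rule plus jitter
        uas_start = start - d_uas - len(uas)
        _plant(seq_arr, uas_start, uas)
        motifs.append(PlantedMotif(loci[i], "NifA_UAS", uas_start, uas_start + len(uas), "+"))
        rpon = "TGGCAC" + _random_bases(rng, 5) + "TTGC"
        d_rpon = int(rng.integers(8, 21))  # -24/-12 element close to the start
        rpon_start = start - d_rpon - len(rpon)
        _plant(seq_arr, rpon_start, rpon)
        motifs.append(PlantedMotif(loci[i], "sigma54", rpon_start, rpon_start + len(rpon), "+"))

    genes = [
        GeneRecord(
            locus_id=loci[i],
            start=int(starts[i]),
            end=int(ends[i]),
            strand=strands[i],
            name=None,
            product="synthetic gene",
            category=_draw_category(rng, loci[i] in members),
        )
        for i in range(spec.n_genes)
    ]
    annotation = GenomeAnnotation(genome_id, genes, genome_len, circular=False)

    island_genes = [genes[i] for i in island_idx]
    _scrub_background_matches(seq_arr, island_genes, motifs, cfg, rng)
    seq = seq_arr.tobytes().decode()

    # final guarantee: the double-Yes set inside the island is exactly the leaders
    flags = annotate_genes(island_genes, seq, cfg)
    leaders = {leader for leader, _ in operons}
    yes_yes = {
        locus
        for locus, ann in flags.items()
        if ann.nifa_flag == "Yes" and ann.rpon_flag == "Yes"
    }
    if yes_yes != leaders:
        raise RuntimeError(
            f"background scrub failed: double-Yes set {sorted(yes_yes ^ leaders)} disagrees"
        )

    true_nfix = {
        locus: spec.effect_size_nfix if locus in members else 1.0 for locus in loci
    }
    true_shock = {
        locus: spec.effect_size_shock if locus in members else 1.0 for locus in loci
    }
    truth = SyntheticTruth(
        loci=list(loci),
        regulon_loci=members,
        island_member_loci=island_member_loci,
        operons=operons,
        motif_positions=motifs,
        true_fold_nfix=true_nfix,
        true_fold_shock=true_shock,
    )
    return annotation, seq, truth


def _draw_category(rng: np.random.Generator, is_member: bool) -> str:
    if is_member:
        return str(rng.choice(_CATEGORY_LABELS, p=_CATEGORY_PROBS))
    return str(rng.choice(_CATEGORY_LABELS[1:5]))


def _window_to_genome(window, position: int, length: int) -> tuple[int, int]:
    """Map a hit window on an upstream sequence back to forward-strand coords."""
    if window.strand == "+":
        gs = window.genome_start + position
    else:
        gs = window.genome_end - position - length
    return gs, gs + length


def _scrub_background_matches(
    seq_arr: np.ndarray,
    island_genes: Sequence[GeneRecord],
    planted: Sequence[PlantedMotif],
    cfg: ScanConfig,
    rng: np.random.Generator,
    max_rounds: int = 60,
) -> None:
    """Mutate away consensus matches in island upstream windows except planted ones."""
    protected = [(m.start, m.end) for m in planted]

    def is_protected(pos: int) -> bool:
        return any(s <= pos < e for s, e in protected)

    def is_planted_span(gs: int, ge: int, pattern_name: str) -> bool:
        return any(m.start == gs and m.end == ge and m.pattern == pattern_name for m in planted)

    scans = (
        (cfg.uas_pattern, cfg.uas_strands, 1),  # budget 0 -> one broken base suffices
        (cfg.rpon_pattern, cfg.rpon_strands, cfg.rpon_pattern.max_mismatches + 1),
    )
    for _ in range(max_rounds):
        dirty = False
        seq = seq_arr.tobytes().decode()
        for gene in island_genes:
            window = extract_upstream(gene, seq, cfg.upstream_window)
            for pattern, strands, n_break in scans:
                for hit in scan_sequence(window.seq, pattern, strands):
                    gs, ge = _window_to_genome(window, hit.position, pattern.total_length)
                    if is_planted_span(gs, ge, pattern.name):
                        continue
                    # the instance reads forward on the genome when hit and
                    # window orientations agree; else the pattern reads on
                    # the reverse strand and bases must be complemented
                    forward = hit.strand == window.strand
                    broken = 0
                    for off, allowed in enumerate(pattern.position_sets):
                        if allowed is None:
                            continue
                        gpos = gs + off if forward else ge - 1 - off
                        if is_protected(gpos):
                            continue
                        allowed_fwd = (
                            allowed if forward else {_COMP[a] for a in allowed}
                        )
                        disallowed = sorted(set("ACGT") - allowed_fwd)
                        seq_arr[gpos] = ord(disallowed[int(rng.integers(len(disallowed)))])
                        broken += 1
                        if broken >= n_break:
                            break
                    if broken == 0:
                        raise RuntimeError("cannot scrub a fully protected background hit")
                    dirty = True
            if dirty:
                break  # re-extract windows from the mutated sequence
        if not dirty:
            return
    raise RuntimeError("background scrub did not converge")


# ---------------------------------------------------------------------------
# expression + orthologs


def generate_expression(truth: SyntheticTruth, spec: SimulationSpec) -> ExpressionMatrix:
    """Intensity means for nfix / nexcess / shock10 with log-normal noise.

    Per gene: a log-normal baseline, multiplied by the planted nitrogen
    fixation fold under ``nfix`` and additionally by the planted shock fold
    under ``shock10``; independent multiplicative log-normal noise of
    ``noise_sigma`` (natural-log scale) per condition.
    """
    rng = np.random.default_rng([spec.seed % (2**31), 1])
    n = len(truth.loci)
    baseline = np.exp(rng.normal(spec.baseline_log_mean, spec.baseline_log_sigma, n))
    fold_nfix = np.array([truth.true_fold_nfix[l] for l in truth.loci])
    fold_shock = np.array([truth.true_fold_shock[l] for l in truth.loci])

    def noise() -> np.ndarray:
        if spec.noise_sigma == 0:
            return np.ones(n)
        return np.exp(rng.normal(0.0, spec.noise_sigma, n))

    values = pd.DataFrame(
        {
            "nfix": baseline * fold_nfix * noise(),
            "nexcess": baseline * noise(),
            "shock10": baseline * fold_nfix * fold_shock * noise(),
        },
        index=pd.Index(truth.loci, name="gene_id"),
    )
    return ExpressionMatrix(values)


def generate_orthologs(
    truth: SyntheticTruth,
    spec: SimulationSpec,
    references: Sequence[str],
) -> pd.DataFrame:
    """Independent Bernoulli(ortholog_retention) presence per gene per reference."""
    rng = np.random.default_rng([spec.seed % (2**31), 2])
    data = {
        ref: rng.random(len(truth.loci)) < spec.ortholog_retention for ref in references
    }
    return pd.DataFrame(data, index=pd.Index(truth.loci, name="gene_id"))


# ---------------------------------------------------------------------------
# recovery scoring


@dataclass
class RecoveryMetrics:
    sensitivity: float
    specificity: float
    jaccard: float
    island_first_offset: int | None = None
    island_last_offset: int | None = None
    operon_exact_fraction: float | None = None


def evaluate_recovery(
    calls: Mapping[str, bool] | Iterable[str],
    truth: SyntheticTruth,
    annotation: GenomeAnnotation | None = None,
    islands: Sequence[ExpressionIsland] | None = None,
    operons: Sequence[Operon] | None = None,
) -> RecoveryMetrics:
    """Confusion-matrix metrics for regulon calls, plus structural recovery.

    ``calls`` is a per-gene boolean mapping over the truth's gene universe
    (or a plain set of called loci, which must be a subset of the
    universe).  Island boundary offsets are measured in genes against the
    best-overlapping detected island; operon recovery is the fraction of
    planted operons whose leader and exact member tuple are predicted.
    """
    universe = set(truth.loci)
    if isinstance(calls, Mapping):
        if set(calls) != universe:
            raise ValueError("calls must cover exactly the truth's gene universe")
        called = {locus for locus, flag in calls.items() if flag}
    else:
        called = set(calls)
        if not called <= universe:
            raise ValueError("called loci outside the truth's gene universe")
    positives = truth.regulon_loci
    tp = len(called & positives)
    fn = len(positives - called)
    fp = len(called - positives)
    tn = len(universe) - tp - fn - fp
    sensitivity = tp / (tp + fn) if (tp + fn) else 1.0
    specificity = tn / (tn + fp) if (tn + fp) else 1.0
    union = len(called | positives)
    jaccard = tp / union if union else 1.0

    first_off = last_off = None
    if islands is not None and truth.island_member_loci and annotation is not None:
        true_members = set(truth.island_member_loci)
        best = max(islands, key=lambda isl: len(set(isl.member_loci) & true_members), default=None)
        if best is None or not set(best.member_loci) & true_members:
            first_off = last_off = len(annotation)  # nothing recovered: maximal offset
        else:
            first_off = abs(annotation.position(best.first_locus) - annotation.position(truth.island_first))
            last_off = abs(annotation.position(best.last_locus) - annotation.position(truth.island_last))

    exact = None
    if operons is not None:
        predicted = {(op.leader_locus, tuple(op.member_loci)) for op in operons}
        if truth.operons:
            exact = sum(1 for op in truth.operons if op in predicted) / len(truth.operons)
        else:
            exact = 1.0 if not predicted else 0.0
    return RecoveryMetrics(sensitivity, specificity, jaccard, first_off, last_off, exact)


# ---------------------------------------------------------------------------
# file emission


def write_dataset(spec: SimulationSpec, outdir, references: Sequence[str] = ("BH72", "AvoP")):
    """Emit the file formats the pipeline consumes, plus a truth JSON."""
    from pathlib import Path

    from .io_formats import write_annotations, write_fasta

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    annotation, seq, truth = generate_genome(spec)
    matrix = generate_expression(truth, spec)
    orthologs = generate_orthologs(truth, spec, references)
    write_annotations(annotation, outdir / "genome.gff3")
    write_fasta(seq, annotation.genome_id, outdir / "genome.fasta")
    matrix.to_tsv(outdir / "expression.tsv")
    orthologs.astype(int).to_csv(outdir / "orthologs.tsv", sep="\t", index_label="gene_id")
    categories = pd.DataFrame(
        {"gene_id": [g.locus_id for g in annotation], "category": [g.category for g in annotation]}
    )
    categories.to_csv(outdir / "categories.tsv", sep="\t", index=False)
    truth.to_json(outdir / "truth.json")
    return annotation, seq, truth
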