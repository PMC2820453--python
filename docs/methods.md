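# Methods

## Scope and model

`nifregulon` operates downstream of microarray/RNA summarisation: its
inputs are per-gene, per-condition positive intensity means (or linear
fold-change tables directly).  No normalisation, background correction or
replicate-level variance modelling is performed, and no statistical
significance test is applied — differential expression is a pure
threshold rule, with an optional per-gene include-mask so externally
computed significance calls can be layered on.

**Fold-change classification.**  For a contrast (numerator, denominator)
the per-gene ratio is `(x_num + c) / (x_den + c)` with pseudocount
`c = 0` by default.  A gene is *up* iff ratio ≥ `up_cut` (default 2.0)
and *down* iff ratio ≤ `down_cut` (default 0.5); the boundaries are
inclusive, so a gene at exactly 2.0 counts as induced.  Ratios stay on
the linear scale end to end; log2 is used only for display.

**Regulon inference.**  The nitrogen-fixation-inducible regulon is the
condition intersection: member iff *up* in the fixation-vs-excess
contrast AND *down* in the shock-vs-fixation contrast.  Derived sets are
plain set algebra: the core subset keeps members present in every
required reference genome of an ortholog presence/absence table (a gene
missing from the table is absent everywhere; an empty requirement list is
a vacuous conjunction and returns the full regulon); the core-genome
overlap is a set intersection; the island partition splits members by a
locus-ID range (numeric suffix comparison, e.g. PST1302–PST1359) or by
bp-interval overlap of the gene body when coordinates are available.
How orthologs are called is out of scope — orthology enters only as a
boolean table.

**Promoter scanning.**  Motifs are gapped IUPAC consensus patterns
matched by exact sliding-window mismatch counting (no PWM scores).  Gap
positions (`N10`) are free; `N` in the *sequence* matches nothing and
counts as a mismatch at any non-gap position.  Defaults:

| parameter | default | why |
|---|---|---|
| UAS pattern | `TGT-N10-ACA`, 0 mismatches | the canonical NifA upstream activator sequence |
| UAS strands | both | enhancer-like elements are orientation-tolerant (the pattern happens to be its own reverse complement, so ± hits pair up) |
| σ54 pattern | `TGGCAC-N5-TTGC`, ≤ 1 mismatch | a concrete instance of the σ54 GG-N10-GC family consensus; the element is named "-24/-12" but no single printed sequence exists, so it is fully configurable |
| σ54 strands | coding only | promoter elements are orientation-specific |
| upstream window | 400 bp | must exceed the 100-bp spacing rule plus motif length with room to spare |
| minimum UAS distance | 100 bp (inclusive) | the classic NifA spacing rule: a UAS acts from ≥ 100 bp upstream |

Distances are measured from the motif's 3' edge to the annotated gene
start on the coding strand.  Annotated translation starts proxy for
transcription starts, which are generally unannotated; this shifts all
distances by the (unknown) 5'-UTR length and is the main caveat of the
flag definitions.  Gene bodies overlapping an upstream window are not
masked.  Flags: NifA = Yes iff some UAS hit respects the spacing rule;
RpoN = Yes iff the σ54 element matches anywhere in the window.  A blank
flag (in tables) is a third state meaning "not evaluated /
operon-internal", never "No".

**Operon prediction.**  Every double-Yes gene seeds exactly one operon
(operon count = double-Yes count).  Extension follows transcription
direction over consecutive genes while (i) the strand is unchanged,
(ii) the intergenic gap is ≤ 200 bp (a standard bacterial operon
heuristic — no joining rule is inherited from any particular study), and
(iii) the next gene does not itself carry a double-Yes promoter.  Genes
with No/blank flags are legitimate interior members.  Operons are
provably pairwise disjoint under these rules.

**Island detection.**  Islands are maximal runs of regulon members in
gene order, tolerating at most `max_gap_genes` (default 4) consecutive
non-members inside a run; boundaries are always members; runs with fewer
than `min_genes` (default 5) members are dropped.  `gene_count` counts
members only; spans are `max(end) − min(start)` over members in bp.
With `max_gap_genes = 0` the detector reduces to exact maximal
member-runs (checked against a brute-force run-length oracle), and the
largest island's member count is monotone in the tolerance.

## Synthetic data

The generator emulates the structure of a two-steady-state plus
one-shock-time-point expression study of a diazotroph with a clustered
*nif* region.  Defaults define the simulated study conditions:

* 1000 genes; gene lengths 600–1500 bp; intergenic gaps 30–180 bp;
* one island of 58 genes holding 52 regulon members organised into 11
  operons (sizes 5,2,10,1,7,5,6,4,1,10,1) and spanning exactly 49 kb
  (island gene lengths are rescaled to hit the target span);
* 114 further regulon members scattered outside the island;
* induction fold 20 under fixation, shock fold 0.1 relative to fixation;
* per-condition multiplicative log-normal noise, σ = 0.2 on the natural
  log scale, on a log-normal baseline (μ = 7, σ = 0.8);
* ortholog retention 0.6 per gene per reference, independent.

Layout choices that make the planted truth exactly recoverable under the
default detector configs: operon leaders get a 260–380 bp upstream gap
holding a planted UAS (3' edge 100–140 bp upstream) and a planted σ54
element (3' edge 8–20 bp upstream); non-member island genes sit on the
minus strand only in the slots *between* operons (at most 4 per slot, so
the island stays one run); a 250–400 bp gap flanks the island so no
operon extends past it; and outside regulon members keep a 5-gene buffer
from the island so detected boundaries match the planted ones.

**Background-match scrubbing.**  Random sequence contains consensus
matches at a calculable rate (the UAS expects `4^-6` per window position
per strand; the σ54 element with one mismatch ≈ `31·4^-10` per
position).  Inside the upstream windows of island genes the generator
mutates away every non-planted match (planted spans are protected and
the result is verified), so the double-Yes set within the island equals
the planted leader set by construction.  Passing recovery tests
therefore demonstrates correctness of the detectors on planted
architecture — not a false-positive rate on real genomes, where
background matches remain and promoter flags outside the island may
occasionally be spurious.  The shock response is a single 10-minute
snapshot, not a time course; noise is independent across conditions;
orthology is independent across genes and references.  None of this
models probe effects, replicate structure, operon-level expression
correlation or sequence evolution.

## Numerical and degenerate-input choices

* Coordinates are 0-based half-open internally; GFF3 is 1-based
  inclusive at the boundary (the conversion is an involution).  Genomes
  are linear by default with a circular flag (upstream windows then wrap
  instead of truncating).
* A sequence shorter than a pattern yields an empty hit list, not an
  error; hits are sorted by position with `+` before `-` at ties.
* Fold classification rejects non-positive ratios; a zero denominator
  with zero pseudocount is an error.
* Category summaries send unmapped genes to `unknown`; an empty gene set
  yields an empty summary (no division by zero).  Proportions sum to 1
  within 1e-9.
* All generators draw from `numpy.random.default_rng` seeded from the
  simulation spec (separate child streams for genome, expression and
  orthologs), so outputs are bit-reproducible given the spec.
* Reports assert their own invariants at write time (island partition
  sums to the regulon size; the regulon is contained in the up-set).

## Pipeline conventions

Promoter scanning in the orchestrated pipeline targets the regulon
members (the set whose promoters the analysis is about); operon
prediction runs on the gene span of the largest detected island, which
is where the double-consensus architecture is defined.  When promoter
flags are supplied externally (a worked-example table) without genome
coordinates, each double-Yes promoter stands for one operon and member
lists are not resolved.  Problem sizes in tests and the acceptance
script (1000-gene genomes, 10 seeded replicates, 1000 oracle sequences
of 300 bp) were chosen as the smallest sizes at which the planted
architecture and the analytic expectations are comfortably exercised.

## Known limitations

* Translation starts proxy for transcription starts in all distance
  rules.
* The σ54 consensus and mismatch budget are package defaults, not values
  inherited from any specific study; flag outputs depend on them.
* Threshold-only differential expression reproduces published gene
  *counts* only insofar as those counts were threshold-based; any
  additional significance filtering must be supplied via the
  include-mask.
* The island detector assumes a single linear gene order; it does not
  merge runs across the origin of a circular chromosome.
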