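import re

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import random_dna
from nifregulon.io_formats import GeneRecord
from nifregulon.promoter_scan import (
    ScanConfig,
    annotate_genes,
    annotate_promoter,
    compile_pattern,
    extract_upstream,
    revcomp,
    scan_sequence,
)

# --- independent sliding-window oracle (its own IUPAC table and parser) ----

ORACLE_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
ORACLE_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def oracle_sets(spec):
    sets = []
    for tok in spec.split("-"):
        m = re.fullmatch(r"N(\d+)", tok)
        if m:
            sets.extend([None] * int(m.group(1)))
        else:
            sets.extend(ORACLE_IUPAC[c] for c in tok)
    return sets


def oracle_revcomp(seq):
    return "".join(ORACLE_COMP[c] for c in reversed(seq))


def oracle_scan(seq, spec, max_mm, strands):
    sets = oracle_sets(spec)
    L = len(sets)

    def windows(s):
        for i in range(len(s) - L + 1):
            mm = sum(
                1
                for j, allowed in enumerate(sets)
                if allowed is not None and s[i + j] not in allowed
            )
            if mm <= max_mm:
                yield i, mm

    hits = []
    if strands in ("+", "both"):
        hits += [(i, "+", mm) for i, mm in windows(seq)]
    if strands in ("-", "both"):
        hits += [(len(seq) - i - L, "-", mm) for i, mm in windows(oracle_revcomp(seq))]
    return sorted(hits)


def as_tuples(hits):
    return sorted((h.position, h.strand, h.mismatches) for h in hits)


# ---------------------------------------------------------------------------


class TestCompilePattern:
    @pytest.mark.parametrize(
        "spec,length",
        [("TGT-N10-ACA", 16), ("TGGCAC-N5-TTGC", 15), ("A", 1), ("RYN-N3-SW", 8)],
    )
    def test_total_length(self, spec, length):
        assert compile_pattern(spec).total_length == length

    def test_single_base_matches_only_itself(self):
        p = compile_pattern("A")
        assert as_tuples(scan_sequence("ACAT", p)) == [(0, "+", 0), (2, "+", 0)]

    @pytest.mark.parametrize("spec", ["TGX", "N0", "TGT--ACA", ""])
    def test_malformed_specs_rejected(self, spec):
        with pytest.raises(ValueError):
            compile_pattern(spec)


class TestScanSequence:
    def test_planted_gapped_motif_found_at_origin(self):
        seq = "TGT" + "A" * 10 + "ACA"
        hits = scan_sequence(seq, compile_pattern("TGT-N10-ACA"))
        assert as_tuples(hits) == [(0, "+", 0)]

    def test_poly_a_has_no_uas_hits(self):
        assert scan_sequence("A" * 100, compile_pattern("TGT-N10-ACA"), "both") == []

    def test_sequence_shorter_than_pattern_is_empty_not_error(self):
        assert scan_sequence("TG", compile_pattern("TGT-N10-ACA")) == []

    def test_n_in_sequence_counts_as_mismatch_at_fixed_positions(self):
        seq = "TNT" + "A" * 10 + "ACA"
        assert scan_sequence(seq, compile_pattern("TGT-N10-ACA", 0)) == []
        hits = scan_sequence(seq, compile_pattern("TGT-N10-ACA", 1))
        assert as_tuples(hits) == [(0, "+", 1)]

    def test_n_in_sequence_is_free_inside_the_gap(self):
        seq = "TGT" + "N" * 10 + "ACA"
        assert as_tuples(scan_sequence(seq, compile_pattern("TGT-N10-ACA"))) == [(0, "+", 0)]

    @pytest.mark.parametrize("max_mm", [0, 1, 2])
    @pytest.mark.parametrize("spec", ["TGT-N10-ACA", "TGGCAC-N5-TTGC", "ANA"])
    def test_matches_bruteforce_oracle(self, spec, max_mm):
        rng = np.random.default_rng(hash((spec, max_mm)) % 2**31)
        for _ in range(25):
            seq = random_dna(rng, 200)
            got = as_tuples(scan_sequence(seq, compile_pattern(spec, max_mm), "both"))
            assert got == oracle_scan(seq, spec, max_mm, "both")

    @given(st.text(alphabet="ACGT", min_size=16, max_size=120))
    @settings(max_examples=100, deadline=None)
    def test_reverse_complement_symmetry(self, seq):
        p = compile_pattern("TGT-N10-ACA", 1)
        flipped = {"+": "-", "-": "+"}
        direct = as_tuples(scan_sequence(seq, p, "both"))
        mirrored = sorted(
            (len(seq) - h.position - p.total_length, flipped[h.strand], h.mismatches)
            for h in scan_sequence(revcomp(seq), p, "both")
        )
        assert direct == mirrored

    def test_hits_invariant_under_downstream_extension(self):
        rng = np.random.default_rng(12)
        seq = random_dna(rng, 150)
        p = compile_pattern("TGT-N10-ACA", 1)
        base = as_tuples(scan_sequence(seq, p, "+"))
        extended = as_tuples(scan_sequence(seq + random_dna(rng, 60), p, "+"))
        assert base == [h for h in extended if h[0] + p.total_length <= len(seq)]


class TestExtractUpstream:
    def test_plus_strand_window_ends_at_gene_start(self):
        rng = np.random.default_rng(0)
        genome = random_dna(rng, 1000)
        gene = GeneRecord("g", 400, 700, "+")
        w = extract_upstream(gene, genome, 400)
        assert w.seq == genome[0:400]
        assert (w.genome_start, w.genome_end) == (0, 400)

    def test_window_truncated_at_linear_contig_edge(self):
        rng = np.random.default_rng(1)
        genome = random_dna(rng, 500)
        gene = GeneRecord("g", 50, 200, "+")
        w = extract_upstream(gene, genome, 400)
        assert len(w.seq) == 50
        assert w.seq == genome[0:50]

    def test_circular_genome_wraps_instead_of_truncating(self):
        rng = np.random.default_rng(2)
        genome = random_dna(rng, 500)
        gene = GeneRecord("g", 50, 200, "+")
        w = extract_upstream(gene, genome, 100, circular=True)
        assert w.seq == genome[450:] + genome[:50]

    def test_minus_strand_matches_mirrored_plus_extraction(self):
        # a minus-strand gene on seq is the mirror of a plus-strand gene on revcomp(seq)
        rng = np.random.default_rng(3)
        genome = random_dna(rng, 1000)
        minus = GeneRecord("m", 300, 600, "-")
        w_minus = extract_upstream(minus, genome, 150)
        n = len(genome)
        mirrored = GeneRecord("p", n - 600, n - 300, "+")
        w_plus = extract_upstream(mirrored, revcomp(genome), 150)
        assert w_minus.seq == w_plus.seq

    def test_non_positive_window_rejected(self):
        with pytest.raises(ValueError):
            extract_upstream(GeneRecord("g", 10, 20, "+"), "A" * 50, 0)


class TestAnnotatePromoter:
    @staticmethod
    def make_upstream(uas_end_distance, with_rpon, window=400):
        """Poly-C window (inert against both consensi) with planted elements."""
        seq = ["C"] * window
        uas = "TGT" + "C" * 10 + "ACA"
        pos = window - uas_end_distance - 16
        seq[pos : pos + 16] = uas
        if with_rpon:
            rpon = "TGGCAC" + "C" * 5 + "TTGC"
            seq[window - 30 : window - 15] = rpon
        return "".join(seq)

    def test_spacing_rule_yes_yes(self):
        up = self.make_upstream(uas_end_distance=150, with_rpon=True)
        ann = annotate_promoter(GeneRecord("g", 1000, 2000, "+"), up)
        assert (ann.nifa_flag, ann.rpon_flag) == ("Yes", "Yes")
        assert any(h.distance_to_start == 150 for h in ann.uas_hits)

    def test_proximal_uas_fails_spacing_rule(self):
        up = self.make_upstream(uas_end_distance=50, with_rpon=True)
        ann = annotate_promoter(GeneRecord("g", 1000, 2000, "+"), up)
        assert (ann.nifa_flag, ann.rpon_flag) == ("No", "Yes")

    def test_boundary_distance_is_inclusive(self):
        up = self.make_upstream(uas_end_distance=100, with_rpon=False)
        ann = annotate_promoter(GeneRecord("g", 1000, 2000, "+"), up)
        assert (ann.nifa_flag, ann.rpon_flag) == ("Yes", "No")

    def test_window_must_accommodate_spacing_rule(self):
        with pytest.raises(ValueError):
            ScanConfig(upstream_window=110, min_uas_distance=100)

    def test_all_planted_island_promoters_recovered(self, small_dataset):
        ann, seq, truth = small_dataset
        leaders = {leader for leader, _ in truth.operons}
        island_loci = [
            g for g in ann if truth.island_member_loci[0] <= g.locus_id <= truth.island_member_loci[-1]
        ]
        flags = annotate_genes(island_loci, seq)
        yes_yes = {
            l for l, a in flags.items() if a.nifa_flag == "Yes" and a.rpon_flag == "Yes"
        }
        assert yes_yes == leaders
        # every planted motif is reported as a hit in its leader's window
        for leader in leaders:
            a = flags[leader]
            assert any(h.mismatches == 0 for h in a.uas_hits)
            assert any(h.mismatches == 0 for h in a.rpon_hits)


class TestIslandTableFlags:
    def test_double_consensus_loci_in_island_table(self, table1):
        expected = [
            "PST1306", "PST1314", "PST1315", "PST1325", "PST1326", "PST1333",
            "PST1338", "PST1344", "PST1348", "PST1349", "PST1359",
        ]
        assert table1.yes_yes_loci() == expected
        assert len(table1.yes_yes_loci()) == 11
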