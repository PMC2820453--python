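import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nifregulon.expression import classify_table, compute_fold_changes
from nifregulon.regulon import core_subset
from nifregulon.synthetic_data import (
    IslandSpec,
    RecoveryMetrics,
    SimulationSpec,
    SpecError,
    evaluate_recovery,
    generate_expression,
    generate_genome,
    generate_orthologs,
)


class TestSpecValidation:
    def test_island_must_fit_gene_count(self):
        with pytest.raises(SpecError):
            SimulationSpec(n_genes=30, island=IslandSpec(20, 20, 18, (9, 9)))

    def test_operon_sizes_bounded_by_island(self):
        with pytest.raises(SpecError):
            IslandSpec(0, 10, 10, (6, 6))

    def test_regulon_in_island_bounded(self):
        with pytest.raises(SpecError):
            IslandSpec(0, 10, 4, (3, 3))  # fewer members than operon genes

    def test_single_operon_island_cannot_interleave(self):
        with pytest.raises(SpecError):
            IslandSpec(0, 10, 8, (8,))

    def test_negative_effect_rejected(self):
        with pytest.raises(SpecError):
            SimulationSpec(effect_size_nfix=-2)


class TestGenerateGenome:
    def test_bit_reproducible_for_fixed_seed(self, small_spec):
        a_ann, a_seq, a_truth = generate_genome(small_spec)
        b_ann, b_seq, b_truth = generate_genome(small_spec)
        assert a_seq == b_seq
        assert a_ann.genes == b_ann.genes
        assert a_truth.regulon_loci == b_truth.regulon_loci
        assert a_truth.operons == b_truth.operons
        assert a_truth.motif_positions == b_truth.motif_positions

    def test_zero_gene_spec_gives_empty_annotation_and_truth(self):
        spec = SimulationSpec(n_genes=0, island=None, n_regulon_outside=0)
        ann, seq, truth = generate_genome(spec)
        assert len(ann) == 0
        assert truth.regulon_loci == set()
        assert truth.operons == []

    def test_planted_counts_match_spec(self, small_dataset, small_spec):
        ann, _, truth = small_dataset
        isl = small_spec.island
        assert len(ann) == small_spec.n_genes
        assert len(truth.operons) == len(isl.operon_structure)
        assert tuple(len(m) for _, m in truth.operons) == isl.operon_structure
        assert len(truth.island_member_loci) == isl.n_regulon_in_island
        assert (
            len(truth.regulon_loci)
            == isl.n_regulon_in_island + small_spec.n_regulon_outside
        )
        # two motifs planted per operon leader
        assert len(truth.motif_positions) == 2 * len(isl.operon_structure)

    def test_planted_motifs_are_written_into_the_sequence(self, small_dataset):
        ann, seq, truth = small_dataset
        for m in truth.motif_positions:
            window = seq[m.start : m.end]
            if m.pattern == "NifA_UAS":
                assert window.startswith("TGT") and window.endswith("ACA")
            else:
                assert window.startswith("TGGCAC") and window.endswith("TTGC")

    def test_worked_example_architecture_is_the_default(self):
        spec = SimulationSpec()
        isl = spec.island
        assert isl.n_island_genes == 58
        assert isl.n_regulon_in_island == 52
        assert len(isl.operon_structure) == 11
        assert sum(isl.operon_structure) == 52
        assert spec.n_regulon_outside == 114


class TestGenerateExpression:
    def test_noiseless_limit_recovers_folds_exactly(self, small_spec):
        from dataclasses import replace

        spec = replace(small_spec, noise_sigma=0.0)
        _, _, truth = generate_genome(spec)
        matrix = generate_expression(truth, spec)
        folds = compute_fold_changes(matrix, ("nfix", "nexcess")).ratio
        shocks = compute_fold_changes(matrix, ("shock10", "nfix")).ratio
        for locus in truth.loci:
            assert folds[locus] == pytest.approx(truth.true_fold_nfix[locus], rel=1e-9)
            assert shocks[locus] == pytest.approx(truth.true_fold_shock[locus], rel=1e-9)

    def test_mean_regulon_fold_within_ten_percent_at_default_noise(self):
        # 200 regulon genes, sigma=0.2: the mean measured fold concentrates
        # near the planted effect (log-normal bias e^{sigma^2} ~ 1.04)
        spec = SimulationSpec(
            n_genes=500,
            island=IslandSpec(100, 58, 52, (5, 2, 10, 1, 7, 5, 6, 4, 1, 10, 1)),
            island_span_bp=None,
            n_regulon_outside=148,
            seed=13,
        )
        _, _, truth = generate_genome(spec)
        matrix = generate_expression(truth, spec)
        folds = compute_fold_changes(matrix, ("nfix", "nexcess")).ratio
        members = sorted(truth.regulon_loci)
        assert len(members) == 200
        mean_fold = folds[members].mean()
        assert abs(mean_fold - spec.effect_size_nfix) / spec.effect_size_nfix < 0.10

    def test_non_regulon_folds_concentrate_near_unity(self):
        spec = SimulationSpec(n_genes=500, island=None, n_regulon_outside=0, seed=14)
        _, _, truth = generate_genome(spec)
        matrix = generate_expression(truth, spec)
        folds = compute_fold_changes(matrix, ("nfix", "nexcess")).ratio
        assert 0.9 <= folds.median() <= 1.1

    def test_expression_bit_reproducible(self, small_spec, small_dataset):
        _, _, truth = small_dataset
        a = generate_expression(truth, small_spec)
        b = generate_expression(truth, small_spec)
        pd.testing.assert_frame_equal(a.values, b.values)


class TestGenerateOrthologs:
    def test_full_retention_keeps_whole_regulon(self, small_dataset, small_spec):
        from dataclasses import replace

        _, _, truth = small_dataset
        spec = replace(small_spec, ortholog_retention=1.0)
        orth = generate_orthologs(truth, spec, ["BH72", "AvoP"])
        assert core_subset(truth.regulon_loci, orth, ["BH72", "AvoP"]) == truth.regulon_loci

    def test_zero_retention_empties_core_subset(self, small_dataset, small_spec):
        from dataclasses import replace

        _, _, truth = small_dataset
        spec = replace(small_spec, ortholog_retention=0.0)
        orth = generate_orthologs(truth, spec, ["BH72", "AvoP"])
        assert core_subset(truth.regulon_loci, orth, ["BH72", "AvoP"]) == set()

    def test_core_subset_size_within_binomial_bounds(self):
        # 166 regulon genes, retention 0.6 in each of two references:
        # the core subset is Binomial(166, 0.36); check the 99% interval
        spec = SimulationSpec(seed=19)
        _, _, truth = generate_genome(spec)
        orth = generate_orthologs(truth, spec, ["BH72", "AvoP"])
        core = core_subset(truth.regulon_loci, orth, ["BH72", "AvoP"])
        n, p = len(truth.regulon_loci), spec.ortholog_retention**2
        lo, hi = stats.binom.ppf([0.005, 0.995], n, p)
        assert lo <= len(core) <= hi


class TestEvaluateRecovery:
    def test_perfect_calls_score_one(self, small_dataset):
        _, _, truth = small_dataset
        calls = {l: l in truth.regulon_loci for l in truth.loci}
        m = evaluate_recovery(calls, truth)
        assert (m.sensitivity, m.specificity, m.jaccard) == (1.0, 1.0, 1.0)

    def test_complement_calls_have_zero_sensitivity(self, small_dataset):
        _, _, truth = small_dataset
        calls = {l: l not in truth.regulon_loci for l in truth.loci}
        m = evaluate_recovery(calls, truth)
        assert m.sensitivity == 0.0
        assert m.jaccard == 0.0

    def test_universe_mismatch_rejected(self, small_dataset):
        _, _, truth = small_dataset
        with pytest.raises(ValueError):
            evaluate_recovery({"nope": True}, truth)

    def test_matches_bruteforce_confusion_matrix(self, small_dataset):
        _, _, truth = small_dataset
        rng = np.random.default_rng(8)
        for _ in range(10):
            calls = {l: bool(rng.random() < 0.3) for l in truth.loci}
            m = evaluate_recovery(calls, truth)
            tp = sum(1 for l in truth.loci if calls[l] and l in truth.regulon_loci)
            fp = sum(1 for l in truth.loci if calls[l] and l not in truth.regulon_loci)
            fn = sum(1 for l in truth.loci if not calls[l] and l in truth.regulon_loci)
            tn = len(truth.loci) - tp - fp - fn
            assert m.sensitivity == pytest.approx(tp / (tp + fn))
            assert m.specificity == pytest.approx(tn / (tn + fp))
            assert m.jaccard == pytest.approx(tp / (tp + fp + fn))
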