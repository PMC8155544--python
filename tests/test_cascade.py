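"""Five-stage prioritization cascade: stage rules, boundaries, audit, recurrence."""

import random

import pytest

from haystack import ExpressionProfile, FilterConfig, recurrence_histogram, run_cascade
from haystack import testis_fraction as fraction_in_testis  # aliased: bare name collides with test collection
from haystack.cascade import (
    call_passes_quality,
    stage1_effect_and_rarity,
    stage2_quality,
    stage3_genotype_maf,
    stage4_expression,
    stage5_control_exclusion,
)
from haystack.errors import ConfigurationError, DataError

from _factories import het_call, hom_call, make_variant

CFG = FilterConfig()


def profile(gene="G1", testis=10.0, peak_other=5.0):
    return ExpressionProfile(gene, {"testis": testis, "brain": peak_other, "liver": 1.0})


class TestTestisFraction:
    def test_testis_is_the_maximum(self):
        assert fraction_in_testis(profile(testis=60, peak_other=30)) == 1.0

    def test_half_of_maximum_is_exactly_half(self):
        assert fraction_in_testis(profile(testis=30, peak_other=60)) == pytest.approx(0.5)

    def test_all_zero_profile(self):
        assert fraction_in_testis(ExpressionProfile("G1", {"testis": 0.0, "brain": 0.0})) == 0.0

    def test_case_insensitive_testis_column(self):
        assert fraction_in_testis(ExpressionProfile("G1", {"Testis": 4.0, "brain": 8.0})) == 0.5

    def test_missing_testis_is_a_configuration_error(self):
        with pytest.raises(ConfigurationError):
            fraction_in_testis(ExpressionProfile("G1", {"brain": 8.0}))


class TestStage1:
    def test_novel_frameshift_kept(self):
        v = make_variant(consequence="frameshift_variant", maf=None)
        assert stage1_effect_and_rarity([v], CFG) == [v]

    def test_common_frameshift_removed(self):
        v = make_variant(consequence="frameshift_variant", maf=0.02)
        assert stage1_effect_and_rarity([v], CFG) == []

    def test_missense_removed_even_when_rare(self):
        v = make_variant(consequence="missense_variant", maf=0.0)
        assert stage1_effect_and_rarity([v], CFG) == []

    def test_maf_boundary_is_inclusive(self):
        v = make_variant(maf=0.01)
        assert stage1_effect_and_rarity([v], CFG) == [v]


class TestStage2Quality:
    @pytest.mark.parametrize(
        ("dp", "ad", "passes"),
        [
            (10, 4, True),  # all three thresholds exactly at the boundary
            (9, 4, False),  # depth below threshold despite good VAF
            (100, 30, False),  # VAF 0.30 < 0.40
            (10, 3, False),  # alt depth below threshold
            (30, 15, True),
        ],
    )
    def test_quality_boundaries(self, dp, ad, passes):
        assert call_passes_quality(het_call(dp=dp, ad=ad), CFG) is passes

    def test_call_without_depths_fails(self):
        assert call_passes_quality(het_call(dp=None, ad=None), CFG) is False

    def test_variant_survives_through_any_passing_carrier(self):
        v = make_variant(calls=[het_call("S1", dp=8, ad=4), het_call("S2", dp=20, ad=10)])
        pairs = stage2_quality([v], CFG)
        assert [p.call.sample_id for p in pairs] == ["S2"]


class TestStage3GenotypeMaf:
    def _pairs(self, variant):
        return stage2_quality([variant], CFG)

    def test_het_autosomal_above_het_cutoff_removed(self):
        v = make_variant(maf=0.0047, calls=[het_call()])
        assert stage3_genotype_maf(self._pairs(v), CFG) == []

    def test_het_novel_kept(self):
        v = make_variant(maf=None, calls=[het_call()])
        assert len(stage3_genotype_maf(self._pairs(v), CFG)) == 1

    def test_hom_autosomal_below_hom_cutoff_kept(self):
        v = make_variant(maf=0.009, calls=[hom_call()])
        assert len(stage3_genotype_maf(self._pairs(v), CFG)) == 1

    def test_x_linked_hom_uses_strict_cutoff(self):
        v = make_variant(chrom="X", maf=0.009, calls=[hom_call()])
        assert stage3_genotype_maf(self._pairs(v), CFG) == []


class TestStage4Expression:
    def test_fraction_exactly_half_fails_strict_gate(self):
        profiles = {"G1": profile(testis=30, peak_other=60)}
        kept, removed = stage4_expression({"G1"}, profiles, CFG)
        assert kept == set() and "G1" in removed

    def test_unprofiled_gene_removed_with_reason(self):
        kept, removed = stage4_expression({"G1"}, {}, CFG)
        assert kept == set()
        assert removed["G1"] == "no expression profile"

    def test_zero_threshold_disables_the_gate(self):
        cfg = FilterConfig(testis_fraction_min=0.0)
        profiles = {"G1": profile(testis=1.0, peak_other=100.0)}
        kept, removed = stage4_expression({"G1", "G2"}, profiles, cfg)
        assert kept == {"G1"} and removed == {"G2": "no expression profile"}


class TestStage5ControlExclusion:
    def test_quality_passing_control_lof_removes_gene(self):
        control = make_variant(consequence="stop_gained", calls=[het_call("C1", dp=30, ad=15)])
        kept, removed = stage5_control_exclusion({"G1"}, [control], CFG)
        assert kept == set() and "G1" in removed

    def test_control_missense_does_not_remove(self):
        control = make_variant(consequence="missense_variant", calls=[het_call("C1")])
        kept, _ = stage5_control_exclusion({"G1"}, [control], CFG)
        assert kept == {"G1"}

    def test_low_quality_control_lof_does_not_remove(self):
        control = make_variant(calls=[het_call("C1", dp=5, ad=2)])
        kept, _ = stage5_control_exclusion({"G1"}, [control], CFG)
        assert kept == {"G1"}

    def test_common_control_lof_still_removes(self):
        """No MAF gate on control evidence: frequency does not rescue a gene."""
        control = make_variant(maf=0.2, calls=[het_call("C1")])
        kept, _ = stage5_control_exclusion({"G1"}, [control], CFG)
        assert kept == set()


class TestRunCascade:
    def test_recovers_planted_truth(self, small_cohort):
        sc = small_cohort
        candidates, audit = run_cascade(sc.cases, sc.controls, sc.profiles)
        assert [c.gene for c in candidates] == sorted(sc.truth.planted)
        expected = sc.truth.expected_stage_counts(sc.cfg)
        observed = [(s.name, s.genes_in, s.genes_out) for s in audit.stages]
        assert observed == expected
        removed_at = {g: s.name for s in audit.stages for g in s.removed}
        for gene, stage in sc.truth.decoy_stages.items():
            assert removed_at[gene] == stage

    def test_audit_counts_are_monotone_and_chained(self, small_cohort):
        sc = small_cohort
        _, audit = run_cascade(sc.cases, sc.controls, sc.profiles)
        for prev, nxt in zip(audit.stages, audit.stages[1:]):
            assert nxt.genes_in == prev.genes_out
            assert nxt.genes_out <= nxt.genes_in

    def test_order_independence(self, small_cohort):
        sc = small_cohort
        shuffled = list(sc.cases)
        random.Random(0).shuffle(shuffled)
        c1, a1 = run_cascade(sc.cases, sc.controls, sc.profiles)
        c2, a2 = run_cascade(shuffled, sc.controls, sc.profiles)
        assert [c.gene for c in c1] == [c.gene for c in c2]
        assert a1.to_dict() == a2.to_dict()

    def test_empty_case_cohort_is_an_error(self, small_cohort):
        with pytest.raises(DataError):
            run_cascade([], small_cohort.controls, small_cohort.profiles)

    def test_empty_control_cohort_makes_stage5_a_noop(self, small_cohort):
        sc = small_cohort
        candidates, audit = run_cascade(sc.cases, [], sc.profiles)
        assert audit.stages[-1].genes_in == audit.stages[-1].genes_out
        # the control-hit decoy now survives alongside the planted genes
        genes = {c.gene for c in candidates}
        assert set(sc.truth.planted) <= genes

    def test_no_lof_cases_yield_empty_candidate_set(self, small_cohort):
        cases = [make_variant(consequence="missense_variant", calls=[het_call()])]
        candidates, audit = run_cascade(cases, small_cohort.controls, small_cohort.profiles)
        assert candidates == []
        assert audit.stages[0].genes_out == 0


class TestRecurrenceHistogram:
    def test_single_patient_genes(self, small_cohort):
        from haystack import CandidateGene

        candidates = [CandidateGene(f"G{i}", [], 1) for i in range(10)]
        hist = recurrence_histogram(candidates)
        assert hist.bins == {1: (10, 100.0)}

    def test_mixed_counts(self):
        from haystack import CandidateGene

        counts = [1, 1, 2, 4]
        hist = recurrence_histogram([CandidateGene(f"G{i}", [], c) for i, c in enumerate(counts)])
        assert hist.bins == {1: (2, 50.0), 2: (1, 25.0), 4: (1, 25.0)}
        assert sum(pct for _, pct in hist.bins.values()) == pytest.approx(100.0)

    def test_planted_recurrence_recovered(self, small_cohort):
        sc = small_cohort
        candidates, _ = run_cascade(sc.cases, sc.controls, sc.profiles)
        assert {c.gene: c.patient_count for c in candidates} == sc.truth.recurrence

    def test_empty_candidates(self):
        assert recurrence_histogram([]).bins == {}
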