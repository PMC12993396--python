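"""Inheritance inference and the filter cascade."""

import pytest

from pgr.cfa import (
    CfaThresholds,
    apply_cfa_filters,
    cohort_carrier_counts,
    find_compound_hets,
    infer_inheritance,
    run_cfa,
)
from pgr.types import (
    CandidateVariant,
    ClinvarClass,
    Cohort,
    Family,
    GenotypeCall,
    Impact,
    Individual,
    InheritanceCall,
    InheritancePattern,
    Sex,
    Variant,
    VariantAnnotation,
)
from reference_impl import naive_survivors


def make_trio(sex=Sex.MALE):
    members = {
        "P1": Individual("P1", sex, True, "F1", "M1"),
        "F1": Individual("F1", Sex.MALE, False),
        "M1": Individual("M1", Sex.FEMALE, False),
    }
    return Family("FAM1", members, "P1")


def gt(sample, dosage, hemi=False, depth=30, af=None, gq=90.0):
    if af is None:
        af = {0: 0.0, 1: 0.5, 2: 1.0, None: None}[dosage]
    return GenotypeCall(sample, dosage, hemizygous=hemi, depth=depth, alt_fraction=af, quality=gq)


V_AUTO = Variant("chr1", 100, "A", "G")
V_X = Variant("chrX", 100, "G", "A")


class TestInferInheritance:
    def test_trio_de_novo(self):
        call = infer_inheritance(V_AUTO, make_trio(), {"P1": gt("P1", 1), "F1": gt("F1", 0), "M1": gt("M1", 0)})
        assert call.pattern is InheritancePattern.DE_NOVO

    def test_trio_homozygous(self):
        call = infer_inheritance(V_AUTO, make_trio(), {"P1": gt("P1", 2), "F1": gt("F1", 1), "M1": gt("M1", 1)})
        assert call.pattern is InheritancePattern.HOMOZYGOUS

    def test_male_x_hemizygous_maternal(self):
        calls = {"P1": gt("P1", 1, hemi=True, af=1.0), "F1": gt("F1", 0), "M1": gt("M1", 1)}
        call = infer_inheritance(V_X, make_trio(), calls)
        assert call.pattern is InheritancePattern.HEMIZYGOUS
        assert call.parental_origin == "maternal"

    def test_inherited_from_unaffected_parent_is_unphased(self):
        call = infer_inheritance(V_AUTO, make_trio(), {"P1": gt("P1", 1), "F1": gt("F1", 1), "M1": gt("M1", 0)})
        assert call.pattern is InheritancePattern.INHERITED_UNPHASED
        assert call.parental_origin == "paternal"

    def test_affected_carrier_parent_segregates_dominant(self):
        fam = make_trio()
        fam.members["M1"] = Individual("M1", Sex.FEMALE, True)
        call = infer_inheritance(V_AUTO, fam, {"P1": gt("P1", 1), "F1": gt("F1", 0), "M1": gt("M1", 1)})
        assert call.pattern is InheritancePattern.SEGREGATING_DOMINANT

    def test_singleton_het_is_unknown(self):
        fam = Family("FAM3", {"P3": Individual("P3", Sex.FEMALE, True)}, "P3")
        call = infer_inheritance(V_AUTO, fam, {"P3": gt("P3", 1)})
        assert call.pattern is InheritancePattern.UNKNOWN

    def test_singleton_homozygous_recognised_from_genotype_alone(self):
        fam = Family("FAM3", {"P3": Individual("P3", Sex.FEMALE, True)}, "P3")
        call = infer_inheritance(V_AUTO, fam, {"P3": gt("P3", 2)})
        assert call.pattern is InheritancePattern.HOMOZYGOUS

    def test_missing_parent_genotype_in_trio_gives_unknown(self):
        calls = {"P1": gt("P1", 1), "F1": gt("F1", None), "M1": gt("M1", 0)}
        call = infer_inheritance(V_AUTO, make_trio(), calls)
        assert call.pattern is InheritancePattern.UNKNOWN


def _candidate(variant, pattern, origin=None, ann=None, dosage=1):
    return CandidateVariant(
        variant=variant,
        proband="P1",
        family="FAM1",
        genotype=gt("P1", dosage),
        family_genotypes={},
        annotation=ann or VariantAnnotation(gene="G1", impact_tier=Impact.MODERATE),
        inheritance=InheritanceCall(pattern=pattern, parental_origin=origin),
    )


class TestCompoundHets:
    def test_in_trans_pair_flagged(self):
        a = _candidate(Variant("chr1", 1, "A", "G"), InheritancePattern.INHERITED_UNPHASED, "maternal")
        b = _candidate(Variant("chr1", 2, "A", "G"), InheritancePattern.INHERITED_UNPHASED, "paternal")
        assert find_compound_hets([a, b], is_trio=True) == [(a, b)]

    def test_in_cis_pair_not_flagged(self):
        a = _candidate(Variant("chr1", 1, "A", "G"), InheritancePattern.INHERITED_UNPHASED, "maternal")
        b = _candidate(Variant("chr1", 2, "A", "G"), InheritancePattern.INHERITED_UNPHASED, "maternal")
        assert find_compound_hets([a, b], is_trio=True) == []

    def test_singleton_pair_is_provisional(self):
        a = _candidate(Variant("chr1", 1, "A", "G"), InheritancePattern.UNKNOWN)
        b = _candidate(Variant("chr1", 2, "A", "G"), InheritancePattern.UNKNOWN)
        assert find_compound_hets([a, b], is_trio=False) == [(a, b)]


def _clean_annotation(**kw):
    defaults = dict(
        gene="G1", impact_tier=Impact.HIGH, consequence="stop_gained",
        distance_to_exon=0, clinvar=ClinvarClass.ABSENT, gnomad_af=0.0, cohort_af=0.0,
        cadd_phred=35.0,
    )
    defaults.update(kw)
    return VariantAnnotation(**defaults)


class TestApplyFilters:
    def _run(self, ann, structure="trio", pattern=InheritancePattern.DE_NOVO,
             het=0, hom=0, overlap=False, **kw):
        cand = _candidate(V_AUTO, pattern, ann=ann)
        return apply_cfa_filters(cand, CfaThresholds(), structure, het, hom,
                                 phenotype_overlap=overlap, **kw)

    def test_clean_de_novo_stopgain_passes(self):
        decision = self._run(_clean_annotation())
        assert decision.passed and decision.reasons == []

    def test_af_two_percent_fails_frequency(self):
        assert "FREQUENCY" in self._run(_clean_annotation(gnomad_af=0.02)).reasons

    def test_het_carrier_count_31_fails(self):
        assert "HET_COUNT" in self._run(_clean_annotation(), het=31).reasons
        assert self._run(_clean_annotation(), het=30).passed

    def test_hom_count_3_fails(self):
        assert "HOM_COUNT" in self._run(_clean_annotation(), hom=3).reasons

    def test_low_impact_without_clinvar_fails_impact(self):
        ann = _clean_annotation(impact_tier=Impact.LOW, consequence="synonymous_variant")
        assert "IMPACT" in self._run(ann).reasons

    def test_clinvar_plp_rescues_low_impact_and_region(self):
        ann = _clean_annotation(
            impact_tier=Impact.LOW, clinvar=ClinvarClass.PATHOGENIC, distance_to_exon=50
        )
        assert self._run(ann).passed

    def test_benign_annotation_fails(self):
        assert "BENIGN" in self._run(_clean_annotation(clinvar=ClinvarClass.LIKELY_BENIGN)).reasons

    def test_unknown_inheritance_fails_in_trio_only(self):
        ann = _clean_annotation()
        trio = self._run(ann, pattern=InheritancePattern.UNKNOWN)
        assert "INHERITANCE" in trio.reasons

    def test_singleton_with_strong_evidence_and_overlap_passes(self):
        ann = _clean_annotation(impact_tier=Impact.MODERATE, gnomad_af=0.0005, cadd_phred=30.0)
        decision = self._run(ann, structure="singleton", pattern=InheritancePattern.UNKNOWN, overlap=True)
        assert decision.passed

    def test_singleton_without_support_fails_non_trio_evidence(self):
        ann = _clean_annotation(impact_tier=Impact.MODERATE, gnomad_af=0.0005, cadd_phred=12.0)
        decision = self._run(ann, structure="singleton", pattern=InheritancePattern.UNKNOWN)
        assert decision.reasons == ["NON_TRIO_EVIDENCE"]

    def test_quality_floor(self):
        cand = _candidate(V_AUTO, InheritancePattern.DE_NOVO, ann=_clean_annotation())
        cand.genotype = gt("P1", 1, depth=5)
        decision = apply_cfa_filters(cand, CfaThresholds(), "trio", 0, 0)
        assert "QUALITY" in decision.reasons


def test_empty_cohort_runs_to_empty_funnel():
    survivors, decisions, funnel = run_cfa(Cohort([], {}, {}, {}))
    assert survivors == [] and decisions == {}
    assert funnel.to_dict() == {"input_variants": 0, "post_screen": 0, "post_filter": 0}


def test_funnel_counts_non_increasing(small_bundle):
    _, _, funnel = run_cfa(small_bundle.loaded.cohort)
    assert funnel.input_variants >= funnel.post_screen >= 0
    assert funnel.input_variants >= funnel.post_filter >= 0


def test_every_rejection_carries_reasons(small_bundle):
    _, decisions, _ = run_cfa(small_bundle.loaded.cohort)
    for decision in decisions.values():
        assert decision.passed == (not decision.reasons)


def test_survivors_match_naive_reference(small_bundle):
    import pgr.pipeline as pipe

    loaded = small_bundle.loaded
    overlap = pipe.phenotype_overlap_fn(loaded)
    thresholds = CfaThresholds()
    survivors, _, _ = run_cfa(loaded.cohort, thresholds, overlap)
    ours = {(c.proband, c.variant.key) for c in survivors}
    theirs = naive_survivors(loaded.cohort, thresholds, overlap)
    assert ours == theirs


def test_planted_variants_pass_cfa(small_bundle):
    import pgr.pipeline as pipe

    loaded = small_bundle.loaded
    survivors, _, _ = run_cfa(loaded.cohort, CfaThresholds(), pipe.phenotype_overlap_fn(loaded))
    skeys = {(c.proband, c.variant.key) for c in survivors}
    planted = set(small_bundle.reported)
    assert planted <= skeys


def test_carrier_counts_count_probands(small_bundle):
    cohort = small_bundle.loaded.cohort
    thresholds = CfaThresholds()
    proband_ids = {f.proband_id for f in cohort.families}
    variant = next(iter(cohort.genotypes))
    het, hom = cohort_carrier_counts(cohort, variant, thresholds)
    expected_het = sum(
        1
        for s, c in cohort.genotypes[variant].items()
        if s in proband_ids and c.dosage == 1 and not c.hemizygous
    )
    assert het == expected_het
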