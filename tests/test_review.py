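"""First-pass screening rules, ACMG criteria and the Bayesian combiner."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from pgr.review import (
    AcmgCriterion,
    PopulationEvidence,
    ReviewConfig,
    STRENGTH_EXPONENT,
    aggregate_locus_evidence,
    assign_acmg_criteria,
    combine_tavtigian,
    first_pass_screen,
    second_pass_classify,
)
from pgr.types import (
    CandidateVariant,
    ClinvarClass,
    GenotypeCall,
    GeneRecord,
    HpoMatchFeatures,
    Impact,
    InheritanceCall,
    InheritancePattern,
    Moi,
    PhenotypeScores,
    Variant,
    VariantAnnotation,
)


def make_candidate(pattern=InheritancePattern.DE_NOVO, impact=Impact.MODERATE,
                   dosage=1, hemi=False, alt_fraction=None, partner=None, origin=None, **ann_kw):
    defaults = dict(gene="G1", impact_tier=impact, cadd_phred=30.0, revel=0.8,
                    alphamissense=0.7, spliceai=0.05)
    defaults.update(ann_kw)
    if alt_fraction is None:
        alt_fraction = 1.0 if (dosage == 2 or hemi) else 0.5
    return CandidateVariant(
        variant=Variant("chr1", 500, "A", "G"),
        proband="P1", family="FAM1",
        genotype=GenotypeCall("P1", dosage, hemizygous=hemi, depth=30,
                              alt_fraction=alt_fraction, quality=90.0),
        family_genotypes={},
        annotation=VariantAnnotation(**defaults),
        inheritance=InheritanceCall(pattern=pattern, partner=partner, parental_origin=origin),
    )


def make_gene(moi={"AD"}, **kw):
    defaults = dict(gene="G1", moi=frozenset(Moi(m) for m in moi), pli=0.5)
    defaults.update(kw)
    return GeneRecord(**defaults)


def evidence(**kw):
    defaults = dict(summed_ac=0, summed_af=0.0, hom_count=0, hemi_count=0,
                    controls_ac=0, non_neuro_ac=0)
    defaults.update(kw)
    return PopulationEvidence(**defaults)


GOOD_PHEN = PhenotypeScores(similarity=3.5, match=HpoMatchFeatures(2, 1, 1, 0))


class TestLocusAggregation:
    ROWS = [
        {"ref": "A", "alt": "G", "impact_tier": "MODERATE", "ac": 1, "af": 1e-5,
         "hom": 0, "hemi": 0, "controls_ac": 0, "non_neuro_ac": 0},
        {"ref": "A", "alt": "T", "impact_tier": "MODERATE", "ac": 2, "af": 2e-5,
         "hom": 1, "hemi": 0, "controls_ac": 1, "non_neuro_ac": 0},
        {"ref": "A", "alt": "C", "impact_tier": "LOW", "ac": 50, "af": 5e-4,
         "hom": 0, "hemi": 0, "controls_ac": 10, "non_neuro_ac": 5},
    ]

    def test_same_impact_alleles_summed(self):
        cand = make_candidate(gnomad_ac=1, gnomad_af=1e-5)
        ev = aggregate_locus_evidence(cand.variant, cand.annotation, self.ROWS)
        assert ev.summed_ac == 3
        assert ev.summed_af == pytest.approx(3e-5)
        assert ev.hom_count == 1

    def test_lower_impact_colocated_row_excluded(self):
        cand = make_candidate(gnomad_ac=1)
        ev = aggregate_locus_evidence(cand.variant, cand.annotation, self.ROWS)
        assert ev.controls_ac == 1  # the LOW row's 10 not included

    def test_sole_variant_falls_back_to_own_counts(self):
        cand = make_candidate(gnomad_ac=4, gnomad_af=3e-5, gnomad_hom=1)
        ev = aggregate_locus_evidence(cand.variant, cand.annotation, [])
        assert ev.summed_ac == 4 and ev.hom_count == 1


class TestFirstPass:
    def test_clean_de_novo_retained(self):
        d = first_pass_screen(make_candidate(), make_gene(), GOOD_PHEN, evidence())
        assert d.status == "retain" and d.reason == "none"

    def test_recessive_summed_af_above_rule_rejected(self):
        cand = make_candidate(pattern=InheritancePattern.HOMOZYGOUS, dosage=2)
        d = first_pass_screen(cand, make_gene(moi={"AR"}), GOOD_PHEN, evidence(summed_af=0.005))
        assert d.reason == "frequency_fail"

    def test_recessive_homhemi_above_two_rejected(self):
        cand = make_candidate(pattern=InheritancePattern.HOMOZYGOUS, dosage=2)
        d = first_pass_screen(cand, make_gene(moi={"AR"}), GOOD_PHEN, evidence(hom_count=3))
        assert d.reason == "frequency_fail"

    def test_recessive_homhemi_presence_needs_strong_match(self):
        cand = make_candidate(pattern=InheritancePattern.HOMOZYGOUS, dosage=2)
        weak = PhenotypeScores(similarity=1.2, match=HpoMatchFeatures(1, 0, 0, 0))
        d = first_pass_screen(cand, make_gene(moi={"AR"}), weak, evidence(hom_count=1))
        assert d.reason == "frequency_fail"
        d2 = first_pass_screen(cand, make_gene(moi={"AR"}), GOOD_PHEN, evidence(hom_count=1))
        assert d2.status == "retain"

    def test_dominant_ac_above_two_without_penetrance_rejected(self):
        weak = PhenotypeScores(similarity=2.0, match=HpoMatchFeatures(1, 0, 0, 0))
        d = first_pass_screen(make_candidate(), make_gene(), weak, evidence(summed_ac=3))
        assert d.reason == "frequency_fail"
        pen = make_gene(incomplete_penetrance=True)
        assert first_pass_screen(make_candidate(), pen, weak, evidence(summed_ac=3)).status == "retain"

    def test_ndd_dominant_controls_and_non_neuro_rules(self):
        ndd = make_gene(ndd=True)
        d = first_pass_screen(make_candidate(), ndd, GOOD_PHEN, evidence(controls_ac=3))
        assert d.reason == "frequency_fail"
        d2 = first_pass_screen(make_candidate(), ndd, GOOD_PHEN, evidence(non_neuro_ac=2))
        assert d2.reason == "frequency_fail"
        assert first_pass_screen(make_candidate(), ndd, GOOD_PHEN, evidence(non_neuro_ac=1)).status == "retain"

    def test_dominant_homhemi_presence_rejected(self):
        d = first_pass_screen(make_candidate(), make_gene(), GOOD_PHEN, evidence(hemi_count=1))
        assert d.reason == "frequency_fail"

    def test_de_novo_het_in_ar_only_gene_moi_inconsistent(self):
        d = first_pass_screen(make_candidate(), make_gene(moi={"AR"}), GOOD_PHEN, evidence())
        assert d.reason == "moi_inconsistent"

    def test_confirmed_compound_het_requires_recessive_gene(self):
        cand = make_candidate(
            pattern=InheritancePattern.COMPOUND_HET,
            partner=Variant("chr1", 600, "C", "T"), origin="maternal",
        )
        assert first_pass_screen(cand, make_gene(moi={"AR"}), GOOD_PHEN, evidence()).status == "retain"
        assert first_pass_screen(cand, make_gene(moi={"AD"}), GOOD_PHEN, evidence()).reason == "moi_inconsistent"

    def test_provisional_compound_het_keeps_dominant_reading(self):
        cand = make_candidate(
            pattern=InheritancePattern.COMPOUND_HET,
            partner=Variant("chr1", 600, "C", "T"), origin="unknown",
        )
        assert first_pass_screen(cand, make_gene(moi={"AD"}), GOOD_PHEN, evidence()).status == "retain"

    def test_susceptibility_only_gene_rejected(self):
        gene = make_gene(susceptibility_only=True)
        d = first_pass_screen(make_candidate(), gene, GOOD_PHEN, evidence())
        assert d.reason == "susceptibility_only"

    def test_phenotype_floor(self):
        poor = PhenotypeScores(similarity=0.2)
        d = first_pass_screen(make_candidate(), make_gene(), poor, evidence())
        assert d.reason == "phenotype_mismatch"

    def test_insilico_benign_consensus_rejected_first(self):
        cand = make_candidate(cadd_phred=4.0, revel=0.05, alphamissense=0.1, spliceai=0.01,
                              gnomad_af=0.005)
        d = first_pass_screen(cand, make_gene(moi={"AR"}), GOOD_PHEN, evidence(summed_af=0.005))
        assert d.reason == "insilico_benign"  # fires before the frequency clause

    def test_allele_balance_proxy_rejects_skewed_het(self):
        cand = make_candidate(alt_fraction=0.12)
        d = first_pass_screen(cand, make_gene(), GOOD_PHEN, evidence())
        assert d.reason == "quality_fail"

    def test_missing_gene_record_rejected_with_note(self):
        d = first_pass_screen(make_candidate(), None, GOOD_PHEN, evidence())
        assert d.reason == "moi_inconsistent" and "no gene record" in d.notes

    def test_decisions_independent_of_input_order(self, small_bundle):
        import pgr.pipeline as pipe
        from pgr.cfa import run_cfa

        loaded = small_bundle.loaded
        survivors, _, _ = run_cfa(loaded.cohort, phenotype_overlap=pipe.phenotype_overlap_fn(loaded))
        context = pipe.CandidateContext(loaded)

        def decide(cands):
            out = {}
            for c in cands:
                gene = loaded.cohort.genes.get(c.annotation.gene)
                phen = pipe.phenotype_scores(loaded, c.proband, c.annotation.gene)
                out[(c.proband, c.variant.key)] = first_pass_screen(
                    c, gene, phen, context.evidence(c)
                ).reason
            return out

        forward = decide(survivors[:80])
        backward = decide(list(reversed(survivors[:80])))
        assert forward == backward


class TestAcmgCriteria:
    def test_de_novo_stopgain_in_constrained_gene(self):
        cand = make_candidate(impact=Impact.HIGH)
        crits = assign_acmg_criteria(cand, make_gene(pli=0.99), evidence())
        codes = {c.code for c in crits}
        assert {"PVS1", "PS2", "PM2"} <= codes
        assert "PP3" in codes  # deleterious consensus

    def test_high_af_stand_alone_benign(self):
        cand = make_candidate(pattern=InheritancePattern.INHERITED_UNPHASED)
        crits = assign_acmg_criteria(cand, make_gene(), evidence(summed_af=0.06))
        assert {c.code for c in crits} >= {"BA1"}

    def test_benign_insilico_consensus_gives_bp4(self):
        cand = make_candidate(pattern=InheritancePattern.INHERITED_UNPHASED,
                              cadd_phred=3.0, revel=0.05, alphamissense=0.1, spliceai=0.0,
                              gnomad_af=0.002)
        crits = assign_acmg_criteria(cand, make_gene(), evidence(summed_af=0.002))
        assert "BP4" in {c.code for c in crits}

    def test_pm3_requires_plp_partner_in_recessive_gene(self):
        partner = Variant("chr1", 600, "C", "T")
        cand = make_candidate(pattern=InheritancePattern.COMPOUND_HET, partner=partner,
                              origin="maternal")
        with_plp = assign_acmg_criteria(cand, make_gene(moi={"AR"}), evidence(),
                                        partner_clinvar=ClinvarClass.PATHOGENIC)
        without = assign_acmg_criteria(cand, make_gene(moi={"AR"}), evidence(),
                                       partner_clinvar=ClinvarClass.ABSENT)
        assert "PM3" in {c.code for c in with_plp}
        assert "PM3" not in {c.code for c in without}


class TestTavtigianCombiner:
    def test_no_criteria_returns_prior_as_vus(self):
        res = combine_tavtigian(frozenset())
        assert res.posterior == pytest.approx(0.10)
        assert res.classification == "VUS" and not res.returnable

    def test_pvs1_pm2_classifies_pathogenic(self):
        res = combine_tavtigian(frozenset({AcmgCriterion("PVS1", "very_strong"),
                                           AcmgCriterion("PM2", "moderate")}))
        odds = 350.0 ** 1.25
        expected = odds * 0.1 / ((odds - 1) * 0.1 + 1)
        assert res.posterior == pytest.approx(expected)
        assert res.posterior == pytest.approx(0.9941, abs=5e-4)
        assert res.classification == "P" and res.returnable

    def test_pm2_alone_is_vus(self):
        res = combine_tavtigian(frozenset({AcmgCriterion("PM2", "moderate")}))
        assert res.posterior == pytest.approx(0.3246, abs=5e-4)
        assert res.classification == "VUS" and not res.returnable

    def test_ba1_forces_benign(self):
        res = combine_tavtigian(frozenset({AcmgCriterion("BA1", "stand_alone", benign=True),
                                           AcmgCriterion("PM2", "moderate")}))
        assert res.classification == "B"

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.tuples(
                st.sampled_from(["supporting", "moderate", "strong", "very_strong"]),
                st.booleans(),
            ),
            max_size=6,
        )
    )
    def test_matches_closed_form(self, strengths):
        criteria = frozenset(
            AcmgCriterion(f"C{i}", s, benign=b) for i, (s, b) in enumerate(strengths)
        )
        res = combine_tavtigian(criteria)
        exponent = sum(
            (-1 if c.benign else 1) * STRENGTH_EXPONENT[c.strength] for c in criteria
        )
        odds = 350.0 ** exponent
        expected = odds * 0.1 / ((odds - 1) * 0.1 + 1)
        assert abs(res.posterior - expected) < 1e-9


class TestSecondPass:
    def test_lp_posterior_returnable(self):
        res = combine_tavtigian(frozenset({AcmgCriterion("PS2", "strong"),
                                           AcmgCriterion("PM2", "moderate"),
                                           AcmgCriterion("PP3", "supporting")}))
        assert res.classification == "LP" and res.returnable
        d = second_pass_classify(make_candidate(), res, GOOD_PHEN)
        assert d.status == "retain"

    def test_documented_variant_rejected(self):
        res = combine_tavtigian(frozenset())
        d = second_pass_classify(make_candidate(), res, GOOD_PHEN,
                                 documented_keys={"chr1:500:A:G"})
        assert d.reason == "already_documented"

    def test_vus_leaning_plp_is_returnable(self):
        res = combine_tavtigian(frozenset({AcmgCriterion("PM2", "moderate"),
                                           AcmgCriterion("PM3", "moderate")}))
        assert res.classification == "VUS"
        assert res.posterior > 0.50 and res.returnable

    def test_stricter_phenotype_floor(self):
        res = combine_tavtigian(frozenset())
        mid = PhenotypeScores(similarity=1.2)
        d = second_pass_classify(make_candidate(), res, mid)
        assert d.reason == "phenotype_mismatch"


def test_all_rejection_reasons_reachable_on_synthetic_cohort(small_bundle):
    """Every codified rejection rule fires somewhere in the generated data."""
    import pgr.pipeline as pipe
    from pgr.cfa import run_cfa

    loaded = small_bundle.loaded
    survivors, _, _ = run_cfa(loaded.cohort, phenotype_overlap=pipe.phenotype_overlap_fn(loaded))
    context = pipe.CandidateContext(loaded)
    seen = set()
    for cand in survivors:
        gene = loaded.cohort.genes.get(cand.annotation.gene)
        phen = pipe.phenotype_scores(loaded, cand.proband, cand.annotation.gene)
        first = first_pass_screen(cand, gene, phen, context.evidence(cand))
        seen.add(first.reason)
        if first.status == "retain":
            second = second_pass_classify(
                cand, context.acmg(cand), phen, documented_keys=loaded.documented
            )
            seen.add(second.reason)
    expected = {
        "insilico_benign", "frequency_fail", "moi_inconsistent",
        "susceptibility_only", "phenotype_mismatch", "quality_fail",
        "already_documented", "none",
    }
    assert expected <= seen, f"missing: {expected - seen}"
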