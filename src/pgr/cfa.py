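"""Cohort Family Analysis: inheritance inference and the filter cascade.

The cascade keeps protein-affecting (HIGH/MODERATE impact, or ClinVar P/LP
within the exon-flank region rule), rare (AF <= 1.5%, het carriers <= 30,
hom carriers <= 2), non-benign variants whose inheritance is consistent
with de novo, homozygous, hemizygous, compound-heterozygous or
affected-segregating transmission.  Families without both parents (duos and
singletons) face a stricter branch: AF <= 0.1%, strong in-silico or
constraint evidence, and either patient-gene phenotype overlap or a
pathogenic ClinVar assertion.

Every rejected candidate carries explicit reason codes; nothing is dropped
silently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

from .types import (
    CandidateVariant,
    ClinvarClass,
    Cohort,
    Family,
    GenotypeCall,
    Impact,
    InheritanceCall,
    InheritancePattern,
    Sex,
    Variant,
)

_X_CHROMS = {"X", "chrX"}
_PLP = {ClinvarClass.PATHOGENIC, ClinvarClass.LIKELY_PATHOGENIC}
_BENIGN = {ClinvarClass.BENIGN, ClinvarClass.LIKELY_BENIGN}


@dataclass
class CfaThresholds:
    """Tunable cut-offs of the filter cascade (defaults are the cascade's
    standard operating point)."""

    max_af: float = 0.015
    max_het_count: int = 30
    max_hom_count: int = 2
    exon_flank_bp: int = 20
    non_trio_max_af: float = 0.001
    non_trio_min_cadd: float = 25.0
    non_trio_min_pli: float = 0.9
    non_trio_min_s_het: float = 0.05
    non_trio_min_spliceai: float = 0.5
    min_depth: int = 10
    min_gq: float = 20.0
    #: fold reference hom/hemi columns into the homozygote cap; off by
    #: default — at reference-population scale a hom cap of 2 would shadow
    #: the AF filter (review applies the reference hom/hemi rule instead)
    include_reference_counts: bool = False
    require_all_affected_carry: bool = True

    def __post_init__(self) -> None:
        if self.non_trio_max_af > self.max_af:
            raise ValueError("non_trio_max_af must not exceed max_af")


@dataclass
class FilterDecision:
    passed: bool
    reasons: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.passed != (not self.reasons):
            raise ValueError("passed must be equivalent to an empty reason list")


def _is_x(variant: Variant) -> bool:
    return variant.chrom in _X_CHROMS


def infer_inheritance(
    variant: Variant,
    family: Family,
    genotypes: dict[str, GenotypeCall],
    require_all_affected_carry: bool = True,
) -> InheritanceCall:
    """Classify how the proband's allele was transmitted.

    Trio logic: het with both parents reference is de novo; dosage 2 is
    homozygous; a het from exactly one carrier parent segregates dominantly
    when that parent is affected and is otherwise an inherited allele of
    unknown phase.  Male non-PAR chrX calls are hemizygous.  Duos and
    singletons only support homozygous/hemizygous calls from the genotype
    alone; everything else is unknown.
    """
    pro = family.proband
    g = genotypes.get(pro.id)
    if g is None or not (g.carries_alt or g.hemizygous):
        return InheritanceCall(pattern=InheritancePattern.UNKNOWN)

    if g.hemizygous or (_is_x(variant) and pro.sex is Sex.MALE and g.carries_alt):
        origin = None
        mother = family.members.get(pro.mother_id) if pro.mother_id else None
        if mother is not None:
            mg = genotypes.get(mother.id)
            if mg is not None and mg.dosage is not None:
                origin = "maternal" if mg.carries_alt else None
        return InheritanceCall(pattern=InheritancePattern.HEMIZYGOUS, parental_origin=origin or "unknown")

    parents = family.parents_present()
    parent_calls = {
        p.id: genotypes.get(p.id)
        for p in parents
    }
    typed = {pid: c for pid, c in parent_calls.items() if c is not None and c.dosage is not None}
    is_trio = len(parents) == 2 and len(typed) == 2

    if g.dosage == 2:
        return InheritanceCall(pattern=InheritancePattern.HOMOZYGOUS)

    if not is_trio:
        return InheritanceCall(pattern=InheritancePattern.UNKNOWN)

    carriers = [pid for pid, c in typed.items() if c.carries_alt]
    if g.dosage == 1 and not carriers:
        return InheritanceCall(pattern=InheritancePattern.DE_NOVO)
    if g.dosage == 1 and len(carriers) == 1:
        parent = family.members[carriers[0]]
        origin = "maternal" if parent.id == pro.mother_id else "paternal"
        if parent.affected:
            if require_all_affected_carry:
                affected = [m for m in family.members.values() if m.affected and m.id != pro.id]
                for m in affected:
                    mc = genotypes.get(m.id)
                    if mc is not None and mc.dosage is not None and not mc.carries_alt:
                        return InheritanceCall(
                            pattern=InheritancePattern.INHERITED_UNPHASED, parental_origin=origin
                        )
            return InheritanceCall(pattern=InheritancePattern.SEGREGATING_DOMINANT, parental_origin=origin)
        return InheritanceCall(pattern=InheritancePattern.INHERITED_UNPHASED, parental_origin=origin)
    if g.dosage == 1 and len(carriers) == 2:
        return InheritanceCall(pattern=InheritancePattern.INHERITED_UNPHASED, parental_origin="unknown")
    return InheritanceCall(pattern=InheritancePattern.UNKNOWN)


def find_compound_hets(candidates: list[CandidateVariant], is_trio: bool) -> list[tuple[CandidateVariant, CandidateVariant]]:
    """Pair heterozygous candidates of one proband within one gene.

    In trios a pair is in trans when the two alleles came from different
    parents (and neither parent carries both).  Without parental data any
    pair of hets is a provisional compound het of unknown phase; the
    uncertainty is carried forward rather than resolved.
    """
    hets = [c for c in candidates if c.genotype.dosage == 1 and not c.genotype.hemizygous]
    pairs: list[tuple[CandidateVariant, CandidateVariant]] = []
    for i in range(len(hets)):
        for j in range(i + 1, len(hets)):
            a, b = hets[i], hets[j]
            if is_trio:
                oa, ob = a.inheritance.parental_origin, b.inheritance.parental_origin
                if {oa, ob} == {"maternal", "paternal"}:
                    pairs.append((a, b))
            else:
                pairs.append((a, b))
    return pairs


def mark_compound_hets(by_gene: dict[str, list[CandidateVariant]], is_trio: bool) -> None:
    """Upgrade paired hets to ``compound_het`` in place (first partner wins
    when a variant pairs with several)."""
    for gene_cands in by_gene.values():
        for a, b in find_compound_hets(gene_cands, is_trio):
            for this, other in ((a, b), (b, a)):
                if this.inheritance.pattern is not InheritancePattern.COMPOUND_HET:
                    origin = this.inheritance.parental_origin if is_trio else "unknown"
                    this.inheritance = InheritanceCall(
                        pattern=InheritancePattern.COMPOUND_HET,
                        partner=other.variant,
                        parental_origin=origin,
                    )


def cohort_carrier_counts(
    cohort: Cohort, variant: Variant, thresholds: CfaThresholds
) -> tuple[int, int]:
    """Het and hom/hemi carrier counts for a variant.

    Heterozygous carriers are counted over the loaded cohort's probands
    (the carrier-count screen is an internal-cohort recurrence filter, at a
    different scale from reference-population allele frequency).  The
    homozygote cap additionally folds in the reference homozygote and
    hemizygote columns when configured.
    """
    het = hom = 0
    calls = cohort.genotypes.get(variant, {})
    for fam in cohort.families:
        c = calls.get(fam.proband_id)
        if c is None or c.dosage is None:
            continue
        if c.dosage == 2 or (c.hemizygous and c.dosage >= 1):
            hom += 1
        elif c.dosage == 1:
            het += 1
    if thresholds.include_reference_counts:
        ann = cohort.annotations.get(variant)
        if ann is not None:
            hom += ann.gnomad_hom + ann.gnomad_hemi
    return het, hom


def screen_reasons(candidate: CandidateVariant, thresholds: CfaThresholds) -> list[str]:
    """Initial screen: the exon-region rule and the genotype quality floor."""
    reasons = []
    ann = candidate.annotation
    if ann.distance_to_exon > thresholds.exon_flank_bp and ann.clinvar not in _PLP:
        reasons.append("REGION")
    g = candidate.genotype
    if (g.depth is not None and g.depth < thresholds.min_depth) or (
        g.quality is not None and g.quality < thresholds.min_gq
    ):
        reasons.append("QUALITY")
    return reasons


def apply_cfa_filters(
    candidate: CandidateVariant,
    thresholds: CfaThresholds,
    family_structure: str,
    het_count: int,
    hom_count: int,
    phenotype_overlap: bool = False,
    gene_pli: Optional[float] = None,
    gene_s_het: Optional[float] = None,
    auto_acmg_benign: bool = False,
) -> FilterDecision:
    """Apply the full cascade to one candidate; returns every failed clause.

    ``phenotype_overlap`` feeds the non-trio evidence clause and is supplied
    by the caller (at pipeline level it is exact+one-level HPO match >= 1).
    """
    if candidate.annotation is None:
        raise ValueError("candidate has no annotation attached")
    ann = candidate.annotation
    reasons = screen_reasons(candidate, thresholds)

    if ann.impact_tier not in (Impact.HIGH, Impact.MODERATE) and ann.clinvar not in _PLP:
        reasons.append("IMPACT")
    af = max(ann.gnomad_af, ann.cohort_af)
    if af > thresholds.max_af:
        reasons.append("FREQUENCY")
    if het_count > thresholds.max_het_count:
        reasons.append("HET_COUNT")
    if hom_count > thresholds.max_hom_count:
        reasons.append("HOM_COUNT")
    if ann.clinvar in _BENIGN or auto_acmg_benign:
        reasons.append("BENIGN")

    if family_structure == "trio":
        if candidate.inheritance.pattern is InheritancePattern.UNKNOWN:
            reasons.append("INHERITANCE")
    else:
        strong_insilico = (
            (ann.cadd_phred is not None and ann.cadd_phred >= thresholds.non_trio_min_cadd)
            or (gene_pli is not None and gene_pli >= thresholds.non_trio_min_pli)
            or (gene_s_het is not None and gene_s_het >= thresholds.non_trio_min_s_het)
            or (ann.spliceai is not None and ann.spliceai >= thresholds.non_trio_min_spliceai)
        )
        supported = phenotype_overlap or ann.clinvar in _PLP
        if not (af <= thresholds.non_trio_max_af and strong_insilico and supported):
            reasons.append("NON_TRIO_EVIDENCE")

    return FilterDecision(passed=not reasons, reasons=reasons)


@dataclass
class CfaFunnel:
    input_variants: int = 0
    post_screen: int = 0
    post_filter: int = 0

    def to_dict(self) -> dict[str, int]:
        return {
            "input_variants": self.input_variants,
            "post_screen": self.post_screen,
            "post_filter": self.post_filter,
        }


def collect_candidates(
    cohort: Cohort, thresholds: Optional[CfaThresholds] = None
) -> dict[str, list[CandidateVariant]]:
    """Assemble every proband-carried candidate with inheritance inferred
    and compound hets paired; keyed by family id (sorted variant order)."""
    thresholds = thresholds or CfaThresholds()
    sorted_variants = sorted(cohort.genotypes)
    out: dict[str, list[CandidateVariant]] = {}
    for family in cohort.families:
        proband = family.proband
        candidates: list[CandidateVariant] = []
        for variant in sorted_variants:
            calls = cohort.genotypes[variant]
            g = calls.get(proband.id)
            if g is None or not (g.carries_alt or (g.hemizygous and g.dosage and g.dosage >= 1)):
                continue
            ann = cohort.annotations.get(variant)
            if ann is None:
                continue
            cand = CandidateVariant(
                variant=variant,
                proband=proband.id,
                family=family.id,
                genotype=g,
                family_genotypes={m: calls[m] for m in family.members if m in calls},
                annotation=ann,
            )
            cand.inheritance = infer_inheritance(
                variant, family, calls, thresholds.require_all_affected_carry
            )
            candidates.append(cand)

        # Compound-het pairing among rare hets within each gene.
        by_gene: dict[str, list[CandidateVariant]] = {}
        for c in candidates:
            if max(c.annotation.gnomad_af, c.annotation.cohort_af) <= thresholds.max_af:
                by_gene.setdefault(c.annotation.gene, []).append(c)
        mark_compound_hets(by_gene, is_trio=(family.structure == "trio"))
        out[family.id] = candidates
    return out


def run_cfa(
    cohort: Cohort,
    thresholds: Optional[CfaThresholds] = None,
    phenotype_overlap: Optional[Callable[[str, str], bool]] = None,
) -> tuple[list[CandidateVariant], dict[tuple[str, str], FilterDecision], CfaFunnel]:
    """Run the cascade over every proband-carried variant in the cohort.

    Returns the surviving candidates, the per-(proband, variant-key)
    decisions, and the stage funnel.  ``phenotype_overlap(proband, gene)``
    supplies the non-trio phenotype-overlap clause; absent, overlap is
    treated as false.
    """
    thresholds = thresholds or CfaThresholds()
    funnel = CfaFunnel()
    survivors: list[CandidateVariant] = []
    decisions: dict[tuple[str, str], FilterDecision] = {}

    count_cache: dict[Variant, tuple[int, int]] = {}
    collected = collect_candidates(cohort, thresholds)

    for family in cohort.families:
        proband = family.proband
        structure = family.structure
        candidates = collected[family.id]
        funnel.input_variants += len(candidates)

        for cand in candidates:
            if not screen_reasons(cand, thresholds):
                funnel.post_screen += 1
            if cand.variant not in count_cache:
                count_cache[cand.variant] = cohort_carrier_counts(cohort, cand.variant, thresholds)
            het, hom = count_cache[cand.variant]
            gene = cohort.genes.get(cand.annotation.gene)
            overlap = bool(phenotype_overlap and phenotype_overlap(proband.id, cand.annotation.gene))
            decision = apply_cfa_filters(
                cand,
                thresholds,
                structure,
                het,
                hom,
                phenotype_overlap=overlap,
                gene_pli=gene.pli if gene else None,
                gene_s_het=gene.s_het if gene else None,
            )
            decisions[(proband.id, cand.variant.key)] = decision
            if decision.passed:
                survivors.append(cand)

    funnel.post_filter = len(survivors)
    return survivors, decisions, funnel
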