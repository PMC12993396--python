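"""Naive clause-by-clause reference implementation of the filter cascade.

Deliberately written as straight-line code, independent of the package's
cascade machinery, to serve as the oracle for survivor-set equivalence.
Only the domain types are shared.
"""

from __future__ import annotations

from pgr.types import Cohort, InheritancePattern, Sex


def _carries(call) -> bool:
    return call is not None and call.dosage is not None and call.dosage >= 1


def _is_x(chrom: str) -> bool:
    return chrom in ("X", "chrX")


def naive_inheritance(variant, family, calls) -> str:
    pro = family.proband
    g = calls.get(pro.id)
    if g is None or not _carries(g):
        return "unknown"
    if _is_x(variant.chrom) and pro.sex is Sex.MALE:
        return "hemizygous"
    if g.dosage == 2:
        return "homozygous"
    parents = family.parents_present()
    parent_calls = [calls.get(p.id) for p in parents]
    typed = [
        (p, c) for p, c in zip(parents, parent_calls) if c is not None and c.dosage is not None
    ]
    if len(parents) != 2 or len(typed) != 2:
        return "unknown"
    carriers = [p for p, c in typed if c.dosage >= 1]
    if len(carriers) == 0:
        return "de_novo"
    if len(carriers) == 1:
        if carriers[0].affected:
            return "segregating_dominant"
        return "inherited_unphased"
    return "inherited_unphased"


def naive_survivors(cohort: Cohort, thresholds, overlap_fn=None) -> set[tuple[str, str]]:
    """(proband, variant key) pairs that pass every clause."""
    # proband carrier counts per variant
    het_count: dict = {}
    hom_count: dict = {}
    proband_ids = {f.proband_id for f in cohort.families}
    for variant, calls in cohort.genotypes.items():
        het = hom = 0
        for sample, call in calls.items():
            if sample not in proband_ids or call.dosage is None:
                continue
            if call.dosage == 2 or (call.hemizygous and call.dosage >= 1):
                hom += 1
            elif call.dosage == 1:
                het += 1
        het_count[variant] = het
        hom_count[variant] = hom

    out = set()
    for family in cohort.families:
        pro = family.proband
        structure = family.structure
        for variant, calls in cohort.genotypes.items():
            g = calls.get(pro.id)
            if g is None or not _carries(g):
                continue
            ann = cohort.annotations.get(variant)
            if ann is None:
                continue
            gene = cohort.genes.get(ann.gene)

            # screen
            plp = ann.clinvar.value in ("pathogenic", "likely_pathogenic")
            if ann.distance_to_exon > thresholds.exon_flank_bp and not plp:
                continue
            if g.depth is not None and g.depth < thresholds.min_depth:
                continue
            if g.quality is not None and g.quality < thresholds.min_gq:
                continue
            # impact
            if ann.impact_tier.value not in ("HIGH", "MODERATE") and not plp:
                continue
            # frequency / counts / benign
            af = max(ann.gnomad_af, ann.cohort_af)
            if af > thresholds.max_af:
                continue
            if het_count[variant] > thresholds.max_het_count:
                continue
            hom = hom_count[variant]
            if thresholds.include_reference_counts:
                hom += ann.gnomad_hom + ann.gnomad_hemi
            if hom > thresholds.max_hom_count:
                continue
            if ann.clinvar.value in ("benign", "likely_benign"):
                continue
            # inheritance / non-trio evidence
            if structure == "trio":
                if naive_inheritance(variant, family, calls) == "unknown":
                    continue
            else:
                strong = False
                if ann.cadd_phred is not None and ann.cadd_phred >= thresholds.non_trio_min_cadd:
                    strong = True
                if gene is not None and gene.pli is not None and gene.pli >= thresholds.non_trio_min_pli:
                    strong = True
                if gene is not None and gene.s_het is not None and gene.s_het >= thresholds.non_trio_min_s_het:
                    strong = True
                if ann.spliceai is not None and ann.spliceai >= thresholds.non_trio_min_spliceai:
                    strong = True
                overlap = bool(overlap_fn and overlap_fn(pro.id, ann.gene))
                if not (af <= thresholds.non_trio_max_af and strong and (overlap or plp)):
                    continue
            out.add((pro.id, variant.key))
    return out
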