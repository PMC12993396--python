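"""Codified variant review: first-pass screening rules and second-pass
ACMG classification with Bayesian evidence combination.

The first pass encodes the automatable core of expert variant triage:
in-silico benign consensus, locus-level population frequency rules that
differ for recessive and dominant acting variants (with stricter screens
for dominant neurodevelopmental-disorder genes), mode-of-inheritance
consistency against the gene's known inheritance, susceptibility-only
exclusion, a phenotype-similarity floor, and an automated read-quality
proxy standing in for manual alignment inspection.

The second pass assigns a codified subset of ACMG criteria and combines
them through the Bayesian points framework: evidence strengths act as
exponents of a base odds of pathogenicity, the posterior is mapped to the
standard five classification bins, and VUS leaning P/LP are flagged
returnable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import pandas as pd

from .types import (
    CandidateVariant,
    ClinvarClass,
    GeneRecord,
    Impact,
    InheritancePattern,
    Moi,
    PhenotypeScores,
    Variant,
)

_PLP = {ClinvarClass.PATHOGENIC, ClinvarClass.LIKELY_PATHOGENIC}

STRENGTH_EXPONENT = {
    "supporting": 0.125,
    "moderate": 0.25,
    "strong": 0.5,
    "very_strong": 1.0,
    "stand_alone": 0.0,  # BA1 short-circuits classification instead
}

#: Benign-leaning cutoffs for the in-silico consensus (score below cutoff
#: counts as benign-leaning); deleterious cutoffs for PP3.
BENIGN_CUTOFFS = {"cadd_phred": 10.0, "revel": 0.2, "alphamissense": 0.34, "spliceai": 0.1}
DELETERIOUS_CUTOFFS = {"cadd_phred": 25.0, "revel": 0.7, "alphamissense": 0.56, "spliceai": 0.5}


@dataclass
class ReviewConfig:
    recessive_max_af: float = 0.001
    recessive_max_homhemi: int = 2
    dominant_max_ac: int = 2
    ndd_controls_max_ac: int = 2
    ndd_non_neuro_max_ac: int = 1
    similarity_floor: float = 1.0
    second_pass_similarity_floor: float = 1.5
    strong_phenotype_similarity: float = 3.0
    pm2_max_af: float = 1e-5
    bs1_max_af: float = 0.01
    ba1_min_af: float = 0.05
    het_alt_fraction_range: tuple[float, float] = (0.25, 0.75)
    hom_min_alt_fraction: float = 0.85
    min_depth: int = 10


@dataclass(frozen=True)
class PopulationEvidence:
    """Locus-level aggregates over same-impact alleles at the coordinate."""

    summed_ac: int
    summed_af: float
    hom_count: int
    hemi_count: int
    controls_ac: int
    non_neuro_ac: int


@dataclass(frozen=True)
class ReviewDecision:
    status: str  # "retain" | "reject"
    reason: str = "none"
    notes: str = ""

    def __post_init__(self) -> None:
        if (self.status == "retain") != (self.reason == "none"):
            raise ValueError("retain decisions must carry reason 'none'")


@dataclass(frozen=True)
class AcmgCriterion:
    code: str
    strength: str
    benign: bool = False


@dataclass
class AcmgResult:
    criteria: frozenset[AcmgCriterion]
    posterior: float
    classification: str  # P | LP | VUS | LB | B
    returnable: bool


@dataclass
class ReviewedCandidate:
    """A scored candidate carrying its review trail."""

    candidate: CandidateVariant
    score: float
    first_pass: ReviewDecision
    acmg: Optional[AcmgResult] = None
    second_pass: Optional[ReviewDecision] = None

    @property
    def retained(self) -> bool:
        return (
            self.first_pass.status == "retain"
            and self.second_pass is not None
            and self.second_pass.status == "retain"
        )


def build_locus_index(pop_df: pd.DataFrame) -> dict[tuple[str, int], list[dict]]:
    """Index population-table rows by coordinate for O(1) locus lookups."""
    index: dict[tuple[str, int], list[dict]] = {}
    for row in pop_df.to_dict("records"):
        index.setdefault((str(row["chrom"]), int(row["pos"])), []).append(row)
    return index


def aggregate_locus_evidence(
    variant: Variant,
    annotation,
    locus_rows: Iterable[Mapping],
) -> PopulationEvidence:
    """Sum allele counts and frequencies over all alleles at the variant's
    coordinate that share its impact tier (the candidate's own counts are
    always included)."""
    ac = af = hom = hemi = controls = non_neuro = 0
    af = 0.0
    own_seen = False
    for row in locus_rows:
        if row["impact_tier"] != annotation.impact_tier.value:
            continue
        ac += int(row["ac"])
        af += float(row["af"])
        hom += int(row["hom"])
        hemi += int(row["hemi"])
        controls += int(row["controls_ac"])
        non_neuro += int(row["non_neuro_ac"])
        if row["ref"] == variant.ref and row["alt"] == variant.alt:
            own_seen = True
    if not own_seen:
        ac += annotation.gnomad_ac
        af += annotation.gnomad_af
        hom += annotation.gnomad_hom
        hemi += annotation.gnomad_hemi
        controls += annotation.controls_ac
        non_neuro += annotation.non_neuro_ac
    return PopulationEvidence(
        summed_ac=ac, summed_af=af, hom_count=hom, hemi_count=hemi,
        controls_ac=controls, non_neuro_ac=non_neuro,
    )


def _insilico_votes(annotation, cutoffs: Mapping[str, float], below: bool) -> tuple[int, int]:
    """(votes, available) over the in-silico scores present on the record."""
    votes = available = 0
    for name, cut in cutoffs.items():
        value = getattr(annotation, name)
        if value is None:
            continue
        available += 1
        hit = value < cut if below else value >= cut
        votes += int(hit)
    return votes, available


def acting_mode(candidate: CandidateVariant, gene: Optional[GeneRecord]) -> str:
    """Whether the candidate acts recessively or dominantly for review
    thresholds.  Genotype configuration wins; gene inheritance breaks ties
    for single hets of unknown phase."""
    p = candidate.inheritance.pattern
    if p in (InheritancePattern.HOMOZYGOUS, InheritancePattern.COMPOUND_HET):
        return "recessive"
    if p is InheritancePattern.HEMIZYGOUS:
        if gene is not None and Moi.XLD in gene.moi and Moi.XLR not in gene.moi:
            return "dominant"
        return "recessive"
    if gene is not None and gene.moi and gene.moi <= {Moi.AR}:
        return "recessive"
    return "dominant"


def moi_compatible(candidate: CandidateVariant, gene: GeneRecord) -> bool:
    """Compatibility matrix between the observed inheritance configuration
    and the gene's disease inheritance modes."""
    moi = gene.moi
    if not moi:
        return False
    p = candidate.inheritance.pattern
    if p is InheritancePattern.DE_NOVO:
        return bool(moi & {Moi.AD, Moi.XLD})
    if p is InheritancePattern.HOMOZYGOUS:
        return Moi.AR in moi
    if p is InheritancePattern.HEMIZYGOUS:
        return bool(moi & {Moi.XLR, Moi.XLD})
    if p is InheritancePattern.COMPOUND_HET:
        if candidate.inheritance.parental_origin == "unknown":
            # Provisional non-trio pair: phase and de novo status are both
            # unconfirmed, so the dominant reading stays on the table.
            return bool(moi & {Moi.AR, Moi.AD, Moi.XLD})
        return Moi.AR in moi
    if p is InheritancePattern.SEGREGATING_DOMINANT:
        return bool(moi & {Moi.AD, Moi.XLD})
    if p is InheritancePattern.INHERITED_UNPHASED:
        # A transmitted het from an unaffected parent needs reduced
        # penetrance to explain a dominant disease.
        return bool(moi & {Moi.AD, Moi.XLD}) and gene.incomplete_penetrance
    # Unknown (duo/singleton het): plausible unconfirmed de novo.
    return bool(moi & {Moi.AD, Moi.XLD})


def quality_proxy_ok(candidate: CandidateVariant, config: ReviewConfig) -> bool:
    """Automated stand-in for manual read review: allele balance within the
    expected band for the genotype, and adequate depth."""
    g = candidate.genotype
    if g.depth is not None and g.depth < config.min_depth:
        return False
    if g.alt_fraction is None:
        return True
    if g.hemizygous or g.dosage == 2:
        return g.alt_fraction >= config.hom_min_alt_fraction
    lo, hi = config.het_alt_fraction_range
    return lo <= g.alt_fraction <= hi


def first_pass_screen(
    candidate: CandidateVariant,
    gene: Optional[GeneRecord],
    phen: PhenotypeScores,
    evidence: PopulationEvidence,
    config: Optional[ReviewConfig] = None,
) -> ReviewDecision:
    """Ordered first-pass screening; the first failing clause decides."""
    config = config or ReviewConfig()

    benign_votes, available = _insilico_votes(candidate.annotation, BENIGN_CUTOFFS, below=True)
    if available >= 2 and benign_votes > available / 2:
        return ReviewDecision("reject", "insilico_benign",
                              f"{benign_votes}/{available} scores benign-leaning")

    strong_match = phen.similarity >= config.strong_phenotype_similarity
    mode = acting_mode(candidate, gene)
    homhemi = evidence.hom_count + evidence.hemi_count
    if mode == "recessive":
        if evidence.summed_af > config.recessive_max_af:
            return ReviewDecision("reject", "frequency_fail",
                                  f"recessive summed AF {evidence.summed_af:.3g} > {config.recessive_max_af}")
        if homhemi > config.recessive_max_homhemi:
            return ReviewDecision("reject", "frequency_fail",
                                  f"hom/hemi count {homhemi} > {config.recessive_max_homhemi}")
        if homhemi > 0 and not strong_match:
            return ReviewDecision("reject", "frequency_fail",
                                  "hom/hemi presence without strong phenotype match")
    else:
        if homhemi > 0:
            return ReviewDecision("reject", "frequency_fail",
                                  "hom/hemi presence not allowed for dominant variants")
        penetrance = gene is not None and gene.incomplete_penetrance
        if gene is not None and gene.ndd:
            if evidence.controls_ac > config.ndd_controls_max_ac:
                return ReviewDecision("reject", "frequency_fail",
                                      f"controls AC {evidence.controls_ac} > {config.ndd_controls_max_ac}")
            if evidence.non_neuro_ac > config.ndd_non_neuro_max_ac and not penetrance:
                return ReviewDecision("reject", "frequency_fail",
                                      f"non-neuro AC {evidence.non_neuro_ac} > {config.ndd_non_neuro_max_ac}")
        elif evidence.summed_ac > config.dominant_max_ac and not penetrance and not strong_match:
            return ReviewDecision("reject", "frequency_fail",
                                  f"dominant summed AC {evidence.summed_ac} > {config.dominant_max_ac}")

    if gene is None:
        return ReviewDecision("reject", "moi_inconsistent", "no gene record available")
    if not moi_compatible(candidate, gene):
        return ReviewDecision("reject", "moi_inconsistent",
                              f"{candidate.inheritance.pattern.value} vs {sorted(m.value for m in gene.moi)}")

    if gene.susceptibility_only:
        return ReviewDecision("reject", "susceptibility_only")

    if phen.similarity < config.similarity_floor:
        return ReviewDecision("reject", "phenotype_mismatch",
                              f"similarity {phen.similarity:.2f} < {config.similarity_floor}")

    if not quality_proxy_ok(candidate, config):
        return ReviewDecision("reject", "quality_fail")

    return ReviewDecision("retain")


def assign_acmg_criteria(
    candidate: CandidateVariant,
    gene: Optional[GeneRecord],
    evidence: PopulationEvidence,
    config: Optional[ReviewConfig] = None,
    partner_clinvar: Optional[ClinvarClass] = None,
) -> frozenset[AcmgCriterion]:
    """Codified subset of ACMG criteria derivable from the loaded data."""
    config = config or ReviewConfig()
    ann = candidate.annotation
    out: set[AcmgCriterion] = set()

    if ann.impact_tier is Impact.HIGH and gene is not None and gene.pli is not None and gene.pli >= 0.9:
        out.add(AcmgCriterion("PVS1", "very_strong"))
    if candidate.inheritance.pattern is InheritancePattern.DE_NOVO:
        out.add(AcmgCriterion("PS2", "strong"))
    if evidence.summed_af <= config.pm2_max_af:
        out.add(AcmgCriterion("PM2", "moderate"))
    if (
        candidate.inheritance.pattern is InheritancePattern.COMPOUND_HET
        and gene is not None
        and Moi.AR in gene.moi
        and partner_clinvar in _PLP
    ):
        out.add(AcmgCriterion("PM3", "moderate"))

    del_votes, avail = _insilico_votes(ann, DELETERIOUS_CUTOFFS, below=False)
    ben_votes, _ = _insilico_votes(ann, BENIGN_CUTOFFS, below=True)
    if avail >= 2 and del_votes > avail / 2:
        out.add(AcmgCriterion("PP3", "supporting"))
    elif avail >= 2 and ben_votes > avail / 2:
        out.add(AcmgCriterion("BP4", "supporting", benign=True))

    if evidence.summed_af >= config.ba1_min_af:
        out.add(AcmgCriterion("BA1", "stand_alone", benign=True))
    elif evidence.summed_af > config.bs1_max_af:
        out.add(AcmgCriterion("BS1", "strong", benign=True))
    if evidence.hom_count + evidence.hemi_count > config.recessive_max_homhemi:
        out.add(AcmgCriterion("BS2", "strong", benign=True))
    return frozenset(out)


def combine_tavtigian(
    criteria: frozenset[AcmgCriterion],
    prior: float = 0.10,
    odds_vst: float = 350.0,
) -> AcmgResult:
    """Bayesian combination of criteria strengths.

    Combined odds are ``odds_vst`` raised to the signed sum of strength
    exponents (supporting 1/8, moderate 1/4, strong 1/2, very strong 1;
    benign criteria subtract).  Posterior = odds*prior / ((odds-1)*prior + 1).
    BA1 is stand-alone benign and forces class B.  Classification bins:
    P > 0.99, LP (0.90, 0.99], VUS [0.10, 0.90], LB [0.001, 0.10), B < 0.001.
    """
    for c in criteria:
        if c.strength not in STRENGTH_EXPONENT:
            raise ValueError(f"unknown criterion strength {c.strength!r}")
    if any(c.code == "BA1" for c in criteria):
        return AcmgResult(criteria=criteria, posterior=0.0, classification="B", returnable=False)

    exponent = 0.0
    for c in criteria:
        step = STRENGTH_EXPONENT[c.strength]
        exponent += -step if c.benign else step
    odds = odds_vst ** exponent
    posterior = odds * prior / ((odds - 1.0) * prior + 1.0)

    if posterior > 0.99:
        cls = "P"
    elif posterior > 0.90:
        cls = "LP"
    elif posterior >= 0.10:
        cls = "VUS"
    elif posterior >= 0.001:
        cls = "LB"
    else:
        cls = "B"
    returnable = cls in ("P", "LP") or (cls == "VUS" and posterior > 0.50)
    return AcmgResult(criteria=criteria, posterior=posterior, classification=cls, returnable=returnable)


def second_pass_classify(
    candidate: CandidateVariant,
    acmg: AcmgResult,
    phen: PhenotypeScores,
    config: Optional[ReviewConfig] = None,
    documented_keys: Iterable[str] = (),
) -> ReviewDecision:
    """Second-pass review: deduplicate against already-documented variants
    and apply the stricter phenotype floor; otherwise retain with the ACMG
    result attached by the caller."""
    config = config or ReviewConfig()
    if candidate.variant.key in set(documented_keys):
        return ReviewDecision("reject", "already_documented")
    if phen.similarity < config.second_pass_similarity_floor:
        return ReviewDecision("reject", "phenotype_mismatch",
                              f"similarity {phen.similarity:.2f} < {config.second_pass_similarity_floor}")
    return ReviewDecision("retain")
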