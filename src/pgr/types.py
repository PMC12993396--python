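"""Core domain types shared across the reanalysis pipeline.

Everything downstream of file parsing works on these containers: pedigree
members and families, normalised biallelic variants, per-sample genotype
calls, variant- and gene-level annotation records, phenotype profiles, and
the ``Cohort`` aggregate that ties them together.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


class Impact(str, Enum):
    """VEP-style impact tiers, ordered from most to least severe."""

    HIGH = "HIGH"
    MODERATE = "MODERATE"
    LOW = "LOW"
    MODIFIER = "MODIFIER"


class ClinvarClass(str, Enum):
    PATHOGENIC = "pathogenic"
    LIKELY_PATHOGENIC = "likely_pathogenic"
    VUS = "VUS"
    CONFLICTING = "conflicting"
    LIKELY_BENIGN = "likely_benign"
    BENIGN = "benign"
    ABSENT = "absent"


class Moi(str, Enum):
    """Mode of inheritance of a gene-disease association."""

    AD = "AD"
    AR = "AR"
    XLD = "XLD"
    XLR = "XLR"


class InheritancePattern(str, Enum):
    DE_NOVO = "de_novo"
    HOMOZYGOUS = "homozygous"
    HEMIZYGOUS = "hemizygous"
    COMPOUND_HET = "compound_het"
    SEGREGATING_DOMINANT = "segregating_dominant"
    INHERITED_UNPHASED = "inherited_unphased"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class Individual:
    """A pedigree member.

    ``father_id``/``mother_id`` are ``None`` when the parent is absent from
    the pedigree (PED column 0).
    """

    id: str
    sex: Sex = Sex.UNKNOWN
    affected: bool = False
    father_id: Optional[str] = None
    mother_id: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("individual id must be nonempty")
        if self.id in (self.father_id, self.mother_id):
            raise ValueError(f"individual {self.id!r} is its own parent")


@dataclass
class Family:
    """A pedigree family with a designated proband.

    ``structure`` follows the data-availability convention: *trio* when the
    proband and both parents are present, *duo* for exactly one parent,
    *singleton* for the proband alone; anything else is *other*.
    """

    id: str
    members: dict[str, Individual]
    proband_id: str

    def __post_init__(self) -> None:
        if self.proband_id not in self.members:
            raise ValueError(f"proband {self.proband_id!r} not a member of family {self.id!r}")

    @property
    def proband(self) -> Individual:
        return self.members[self.proband_id]

    def parents_present(self) -> list[Individual]:
        pro = self.proband
        out = []
        for pid in (pro.father_id, pro.mother_id):
            if pid is not None and pid in self.members:
                out.append(self.members[pid])
        return out

    @property
    def structure(self) -> str:
        n = len(self.parents_present())
        extra = len(self.members) - 1 - n
        if extra > 0:
            return "other"
        if n == 2:
            return "trio"
        if n == 1:
            return "duo"
        return "singleton"


@dataclass(frozen=True, order=True)
class Variant:
    """A normalised biallelic variant (1-based position, ACGT alleles)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    build: str = "synthetic-1"

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("pos must be >= 1")
        if not self.ref or not self.alt or self.ref == self.alt:
            raise ValueError("ref and alt must be nonempty and differ")

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"

    @classmethod
    def from_key(cls, key: str, build: str = "synthetic-1") -> "Variant":
        chrom, pos, ref, alt = key.split(":")
        return cls(chrom, int(pos), ref, alt, build)


@dataclass(frozen=True)
class GenotypeCall:
    """A single sample's call at a variant.

    ``dosage`` is the alt-allele count (0/1/2) or ``None`` for a missing
    genotype.  ``hemizygous`` marks single-allele calls (male X outside the
    pseudoautosomal regions).
    """

    sample: str
    dosage: Optional[int]
    hemizygous: bool = False
    depth: Optional[int] = None
    alt_fraction: Optional[float] = None
    quality: Optional[float] = None

    def __post_init__(self) -> None:
        if self.alt_fraction is not None and not (0.0 <= self.alt_fraction <= 1.0):
            raise ValueError("alt_fraction must be within [0, 1]")

    @property
    def carries_alt(self) -> bool:
        return self.dosage is not None and self.dosage >= 1


@dataclass
class VariantAnnotation:
    """Functional and population annotation for one variant.

    Missing in-silico scores stay ``None``; imputation is deferred to
    feature encoding so filters never mistake missing for passing.
    """

    gene: str
    consequence: str = "missense_variant"
    impact_tier: Impact = Impact.MODERATE
    distance_to_exon: int = 0
    clinvar: ClinvarClass = ClinvarClass.ABSENT
    cadd_phred: Optional[float] = None
    revel: Optional[float] = None
    alphamissense: Optional[float] = None
    spliceai: Optional[float] = None
    misfit_d: Optional[float] = None
    gnomad_af: float = 0.0
    cohort_af: float = 0.0
    gnomad_ac: int = 0
    gnomad_hom: int = 0
    gnomad_hemi: int = 0
    controls_ac: int = 0
    non_neuro_ac: int = 0

    def __post_init__(self) -> None:
        for name in ("gnomad_af", "cohort_af"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("gnomad_ac", "gnomad_hom", "gnomad_hemi", "controls_ac", "non_neuro_ac"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class GeneRecord:
    """OMIM-style gene record: inheritance modes, flags, disease phenotype
    terms and constraint scores."""

    gene: str
    moi: frozenset[Moi] = frozenset()
    susceptibility_only: bool = False
    ndd: bool = False
    disease_terms: frozenset[str] = frozenset()
    pli: Optional[float] = None
    s_het: Optional[float] = None
    s_coef: Optional[float] = None
    misfit_s: Optional[float] = None
    incomplete_penetrance: bool = False


@dataclass
class PhenotypeProfile:
    """Manually curated and NLP-extracted HPO term sets for one proband.

    ``combined_terms`` is the union after obsolete-term removal; ancestor
    redundancy is deliberately left in place (the downstream scorer consumes
    counts and no collapsing rule is imposed).
    """

    manual_terms: frozenset[str]
    nlp_terms: frozenset[str]
    combined_terms: frozenset[str]


@dataclass(frozen=True)
class HpoMatchFeatures:
    """Counts of patient/gene HPO term matches.

    ``ic2_count`` / ``ic4_count`` count exact matches whose information
    content reaches 2 / 4 nats; they are not bounded by the one-level count.
    """

    exact_count: int = 0
    one_level_count: int = 0
    ic2_count: int = 0
    ic4_count: int = 0

    def __post_init__(self) -> None:
        for f in (self.exact_count, self.one_level_count, self.ic2_count, self.ic4_count):
            if f < 0:
                raise ValueError("match counts must be >= 0")


@dataclass
class PhenotypeScores:
    """Phenotype relevance of a gene for a proband: the built-in
    best-match-average similarity plus optional externally supplied scores."""

    similarity: float = 0.0
    hpo3: Optional[float] = None
    amelie: Optional[float] = None
    shepherd: Optional[float] = None
    match: HpoMatchFeatures = field(default_factory=HpoMatchFeatures)


@dataclass
class InheritanceCall:
    pattern: InheritancePattern = InheritancePattern.UNKNOWN
    partner: Optional[Variant] = None
    parental_origin: Optional[str] = None  # "maternal" | "paternal" | "unknown"

    def __post_init__(self) -> None:
        if self.pattern is InheritancePattern.COMPOUND_HET and self.partner is None:
            raise ValueError("compound_het calls require a partner variant")


@dataclass
class CandidateVariant:
    """A proband's variant joined to genotypes, annotation and inheritance."""

    variant: Variant
    proband: str
    family: str
    genotype: GenotypeCall
    family_genotypes: dict[str, GenotypeCall]
    annotation: VariantAnnotation
    inheritance: InheritanceCall = field(default_factory=InheritanceCall)

    def __post_init__(self) -> None:
        if not (self.genotype.carries_alt or self.genotype.hemizygous):
            raise ValueError("candidate proband must carry the alternate allele")


@dataclass
class Cohort:
    """All loaded inputs for one pipeline run."""

    families: list[Family]
    genotypes: dict[Variant, dict[str, GenotypeCall]]
    annotations: dict[Variant, VariantAnnotation]
    genes: dict[str, GeneRecord]
    profiles: dict[str, PhenotypeProfile] = field(default_factory=dict)

    def probands(self) -> list[tuple[Family, Individual]]:
        return [(f, f.proband) for f in self.families]

    def family_of(self, sample: str) -> Optional[Family]:
        for f in self.families:
            if sample in f.members:
                return f
        return None

    def validate(self) -> None:
        members = {m for f in self.families for m in f.members}
        for v, calls in self.genotypes.items():
            for s in calls:
                if s not in members:
                    raise ValueError(f"genotype sample {s!r} not in any family ({v.key})")
        for v in self.annotations:
            if v not in self.genotypes or not self.genotypes[v]:
                raise ValueError(f"annotated variant {v.key} has no genotypes")


def parse_optional_float(text: str) -> Optional[float]:
    """TSV convention: '.' or empty string means missing."""
    text = text.strip()
    if text in ("", "."):
        return None
    value = float(text)
    if math.isnan(value):
        return None
    return value
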