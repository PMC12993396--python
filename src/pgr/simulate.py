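"""Seeded generator of complete synthetic pipeline inputs.

Emits, for one cohort: a phenotype ontology (OBO), a gene panel with
inheritance modes and disease-term annotations (TSV), pedigrees (PED), a
multi-sample VCF with Mendelian transmission on two autosomes and an
X-like chromosome, per-variant annotation and population tables (TSV),
per-proband phenotype profiles (JSON), an already-documented variant list,
and a ground-truth record of every planted causal variant.

Planted causal variants are constructed to satisfy every filter clause:
de novo heterozygous for dominant genes, homozygous or properly phased
compound het for recessive genes, maternally inherited hemizygous for
X-linked recessive genes, with near-zero population frequency, damaging
impact and in-silico scores, and proband phenotype terms drawn from the
causal gene's disease annotations.  Background variants share a panel of
population sites with a frequency spectrum spanning the filter thresholds,
and a small set of engineered decoy variants exercises each review
rejection rule.

All output is byte-deterministic for a given seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

log = logging.getLogger(__name__)

_ACGT = ("A", "C", "G", "T")
_AN_REFERENCE = 120_000  # nominal reference-population allele number


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    Defaults approximate the clinical regime at desk scale: a few hundred
    probands, mostly trios, a heavily imbalanced positive:negative training
    ratio, and NLP phenotype sets that are noisy copies of the curated ones.
    """

    n_families: int = 300
    structure_mix: tuple[float, float, float] = (0.65, 0.12, 0.23)  # trio, duo, singleton
    n_genes: int = 60
    moi_mix: tuple[float, float, float] = (0.50, 0.35, 0.15)  # AD, AR, XLR
    n_background_sites: int = 1400
    causal_fraction: float = 0.30
    vus_like_fraction: float = 0.30
    phenotype_dropout: float = 0.20
    phenotype_spurious_terms: int = 2
    missing_genotype_rate: float = 0.005
    ontology_depth: int = 5
    ontology_branching: int = 8
    seed: int = 1

    def __post_init__(self) -> None:
        for mix in (self.structure_mix, self.moi_mix):
            if abs(sum(mix) - 1.0) > 1e-9:
                raise ValueError("mixture proportions must sum to 1")


@dataclass
class SyntheticCohort:
    """Paths of the emitted files plus the in-memory ground truth."""

    out_dir: Path
    vcf: Path
    ped: Path
    variants_tsv: Path
    genes_tsv: Path
    population_tsv: Path
    profiles_json: Path
    obo: Path
    truth_json: Path
    documented_tsv: Path
    truth: dict[str, Optional[dict]]
    config: SimulationConfig


# ---------------------------------------------------------------------------
# Ontology


def simulate_ontology(depth: int, branching: int, seed: int, path: Optional[Path] = None) -> str:
    """Generate a rooted phenotype DAG as OBO text.

    The root sits at level 1, two broad categories at level 2, and
    ``branching`` level-3 anchors below them — the branch heads used by the
    pruning experiment.  Each anchor carries a small subtree down to
    ``depth``; a few nodes get a second parent (diamonds) and a few
    obsolete stub terms are appended.
    """
    if depth < 4:
        raise ValueError("depth must be >= 4 so level-3 branches exist")
    rng = np.random.default_rng(seed)
    counter = [0]

    def new_id() -> str:
        counter[0] += 1
        return f"HP:{counter[0]:07d}"

    root = new_id()
    terms: list[tuple[str, str, list[str], bool]] = [(root, "Phenotypic abnormality", [], False)]
    level2 = [new_id() for _ in range(2)]
    for i, t in enumerate(level2):
        terms.append((t, f"Category {i + 1}", [root], False))
    anchors = []
    for i in range(branching):
        t = new_id()
        anchors.append(t)
        terms.append((t, f"Branch {i + 1}", [level2[i % 2]], False))

    level_nodes = {3: anchors}
    for lvl in range(4, depth + 1):
        level_nodes[lvl] = []
        for parent in level_nodes[lvl - 1]:
            for _ in range(int(rng.integers(2, 4))):
                t = new_id()
                level_nodes[lvl].append(t)
                parents = [parent]
                # Occasional diamond: a second parent one level up.
                if rng.random() < 0.06:
                    pool = [p for p in level_nodes[lvl - 1] if p != parent]
                    if pool:
                        parents.append(pool[int(rng.integers(len(pool)))])
                terms.append((t, f"Term {t[3:]}", parents, False))

    for _ in range(3):
        terms.append((new_id(), "obsolete term", [], True))

    lines = ["format-version: 1.2", "ontology: synthetic-phenotype", ""]
    for tid, name, parents, obsolete in terms:
        lines.append("[Term]")
        lines.append(f"id: {tid}")
        lines.append(f"name: {name}")
        for p in parents:
            lines.append(f"is_a: {p}")
        if obsolete:
            lines.append("is_obsolete: true")
        lines.append("")
    text = "\n".join(lines)
    if path is not None:
        Path(path).write_text(text)
    return text


# ---------------------------------------------------------------------------
# Gene panel


@dataclass
class _Gene:
    name: str
    moi: str  # "AD" | "AR" | "XLR"
    chrom: str
    start: int
    anchor: str
    disease_terms: list[str]
    susceptibility_only: bool
    ndd: bool
    incomplete_penetrance: bool
    pli: float
    s_het: float
    s_coef: float
    misfit_s: float


def _branch_members(ontology, anchor: str) -> list[str]:
    """Level>=3 descendants-or-self of an anchor, sorted."""
    out = [
        t
        for t in ontology.parents
        if t not in ontology.obsolete
        and anchor in ontology.ancestors_or_self(t)
        and ontology.level(t) >= 3
    ]
    return sorted(out)


def simulate_gene_panel(ontology, config: SimulationConfig, rng: np.random.Generator) -> list[_Gene]:
    """Assign each gene an inheritance mode, a phenotype branch (all its
    disease terms share one level-3 anchor), and constraint scores
    correlated with dominance."""
    anchors = sorted(t for t in ontology.parents if t not in ontology.obsolete and ontology.level(t) == 3)
    members = {a: _branch_members(ontology, a) for a in anchors}
    moi_labels = ("AD", "AR", "XLR")
    genes: list[_Gene] = []
    auto_pos = {"chr1": 0, "chr2": 0}
    x_pos = [0]
    for i in range(config.n_genes):
        moi = moi_labels[int(rng.choice(3, p=list(config.moi_mix)))]
        if moi == "XLR":
            chrom = "chrX"
            x_pos[0] += 1
            start = 1 + (x_pos[0] - 1) * 100_000
        else:
            chrom = "chr1" if i % 2 == 0 else "chr2"
            auto_pos[chrom] += 1
            start = 1 + (auto_pos[chrom] - 1) * 100_000
        anchor = anchors[i % len(anchors)]
        pool = members[anchor]
        k = int(rng.integers(3, min(7, len(pool)) + 1))
        disease = sorted(rng.choice(pool, size=k, replace=False).tolist())
        dominant = moi in ("AD", "XLR")
        if moi == "AD":
            pli = float(rng.uniform(0.9, 1.0))
            s_het = float(rng.uniform(0.05, 0.3))
        else:
            pli = float(rng.uniform(0.0, 0.5))
            s_het = float(rng.uniform(0.001, 0.05))
        genes.append(
            _Gene(
                name=f"GENE{i + 1:03d}",
                moi=moi,
                chrom=chrom,
                start=start,
                anchor=anchor,
                disease_terms=disease,
                susceptibility_only=bool(rng.random() < 0.10),
                ndd=bool(rng.random() < 0.30),
                incomplete_penetrance=bool(rng.random() < 0.05),
                pli=pli,
                s_het=s_het,
                s_coef=float(rng.uniform(0.05, 0.5)) if dominant else float(rng.uniform(0.0, 0.1)),
                misfit_s=float(rng.uniform(0.0, 1.0)),
            )
        )
    return genes


# ---------------------------------------------------------------------------
# Variant records


@dataclass
class _SimVariant:
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    impact: str
    consequence: str
    distance_to_exon: int
    clinvar: str
    cadd: Optional[float]
    revel: Optional[float]
    alphamissense: Optional[float]
    spliceai: Optional[float]
    misfit_d: Optional[float]
    gnomad_af: float
    gnomad_ac: int
    gnomad_hom: int
    gnomad_hemi: int
    controls_ac: int
    non_neuro_ac: int
    cohort_af_override: Optional[float] = None
    sim_af: float = 0.0  # frequency used to draw cohort genotypes
    # genotypes keyed by sample id; dosage -1 encodes a missing call
    forced: dict[str, int] = field(default_factory=dict)
    forced_altfrac: dict[str, float] = field(default_factory=dict)
    lowdepth: set[str] = field(default_factory=set)

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"


class _PositionAllocator:
    def __init__(self) -> None:
        self.next_offset: dict[str, int] = {}

    def take(self, gene: _Gene) -> int:
        off = self.next_offset.get(gene.name, 0)
        self.next_offset[gene.name] = off + 1
        return gene.start + off * 7


def _alleles(rng: np.random.Generator) -> tuple[str, str]:
    ref = _ACGT[int(rng.integers(4))]
    alt = _ACGT[int(rng.integers(4))]
    while alt == ref:
        alt = _ACGT[int(rng.integers(4))]
    return ref, alt


def _consequence(impact: str) -> str:
    return {
        "HIGH": "stop_gained",
        "MODERATE": "missense_variant",
        "LOW": "synonymous_variant",
        "MODIFIER": "intron_variant",
    }[impact]


def _damaging_scores(rng: np.random.Generator, vus_like: bool, min_cadd: float = 0.0) -> dict:
    """In-silico scores for a planted causal variant."""
    if vus_like:
        cadd = float(rng.uniform(max(18.0, min_cadd), 28.0))
        revel = float(rng.uniform(0.4, 0.7))
        am = float(rng.uniform(0.35, 0.6))
    else:
        cadd = float(rng.uniform(max(28.0, min_cadd), 40.0))
        revel = float(rng.uniform(0.75, 0.99))
        am = float(rng.uniform(0.6, 0.98))
    return {
        "cadd": cadd,
        "revel": revel,
        "alphamissense": am,
        "spliceai": float(rng.uniform(0.0, 0.2)),
        "misfit_d": float(rng.uniform(0.5, 0.95)),
    }


def _background_scores(rng: np.random.Generator) -> dict:
    def maybe(v: float) -> Optional[float]:
        return None if rng.random() < 0.10 else v

    return {
        "cadd": maybe(float(rng.uniform(0.0, 28.0))),
        "revel": maybe(float(rng.beta(1.5, 4.0))),
        "alphamissense": maybe(float(rng.beta(1.5, 4.0))),
        "spliceai": maybe(float(rng.beta(1.0, 12.0))),
        "misfit_d": maybe(float(rng.uniform(0.0, 0.6))),
    }


# ---------------------------------------------------------------------------
# Cohort generation


def simulate_cohort(config: SimulationConfig, out_dir: str | Path) -> SyntheticCohort:
    """Generate and write a complete synthetic cohort; see module docstring."""
    from . import ontology as onto_mod

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    obo_path = out_dir / "ontology.obo"
    simulate_ontology(config.ontology_depth, config.ontology_branching, config.seed, obo_path)
    ontology = onto_mod.load_obo(obo_path)
    all_level3 = sorted(
        t for t in ontology.parents if t not in ontology.obsolete and ontology.level(t) >= 3
    )

    genes = simulate_gene_panel(ontology, config, rng)
    by_anchor: dict[str, list[_Gene]] = {}
    for g in genes:
        by_anchor.setdefault(g.anchor, []).append(g)

    # Families -----------------------------------------------------------
    structures = rng.choice(3, size=config.n_families, p=list(config.structure_mix))
    families = []
    for i in range(config.n_families):
        fam = f"FAM{i + 1:04d}"
        pro = f"P{i + 1:04d}"
        father = f"F{i + 1:04d}"
        mother = f"M{i + 1:04d}"
        sex = "male" if rng.random() < 0.5 else "female"
        s = ("trio", "duo", "singleton")[int(structures[i])]
        duo_parent = None
        if s == "duo":
            duo_parent = "mother" if rng.random() < 0.7 else "father"
        families.append(
            {"id": fam, "proband": pro, "father": father, "mother": mother,
             "sex": sex, "structure": s, "duo_parent": duo_parent}
        )

    def emitted_samples(f: dict) -> list[str]:
        out = [f["proband"]]
        if f["structure"] == "trio":
            out += [f["father"], f["mother"]]
        elif f["structure"] == "duo":
            out.append(f["father"] if f["duo_parent"] == "father" else f["mother"])
        return out

    samples = [s for f in families for s in emitted_samples(f)]
    sex_of = {}
    for f in families:
        sex_of[f["proband"]] = f["sex"]
        sex_of[f["father"]] = "male"
        sex_of[f["mother"]] = "female"

    alloc = _PositionAllocator()
    variants: list[_SimVariant] = []

    # Background site panel ----------------------------------------------
    site_class = rng.choice(3, size=config.n_background_sites, p=[0.60, 0.20, 0.20])
    for j in range(config.n_background_sites):
        gene = genes[int(rng.integers(len(genes)))]
        pos = alloc.take(gene)
        ref, alt = _alleles(rng)
        cls = int(site_class[j])
        if cls == 0:      # rare: candidate-negative territory
            af = float(np.exp(rng.uniform(np.log(1.5e-3), np.log(9e-3))))
        elif cls == 1:    # borderline low-frequency
            af = float(np.exp(rng.uniform(np.log(1e-3), np.log(1.5e-2))))
        else:             # common: fails the frequency screen
            af = float(rng.uniform(0.016, 0.20))
        impact = str(rng.choice(["MODERATE", "HIGH", "LOW", "MODIFIER"], p=[0.62, 0.23, 0.10, 0.05]))
        distance = 0 if rng.random() < 0.90 else int(rng.integers(21, 100))
        clin_roll = rng.random()
        if clin_roll < 0.04:
            clinvar = "benign" if rng.random() < 0.5 else "likely_benign"
        elif clin_roll < 0.06:
            clinvar = "VUS"
        elif clin_roll < 0.07:
            clinvar = "conflicting"
        else:
            clinvar = "absent"
        sc = _background_scores(rng)
        ac = int(round(af * _AN_REFERENCE))
        hom = int(rng.binomial(max(ac // 2, 0), af)) if ac else 0
        variants.append(
            _SimVariant(
                chrom=gene.chrom, pos=pos, ref=ref, alt=alt, gene=gene.name,
                impact=impact, consequence=_consequence(impact), distance_to_exon=distance,
                clinvar=clinvar, cadd=sc["cadd"], revel=sc["revel"],
                alphamissense=sc["alphamissense"], spliceai=sc["spliceai"],
                misfit_d=sc["misfit_d"], gnomad_af=af, gnomad_ac=ac, gnomad_hom=hom,
                gnomad_hemi=int(rng.integers(0, 2)) if gene.chrom == "chrX" and ac > 10 else 0,
                controls_ac=ac // 2, non_neuro_ac=ac // 3, sim_af=af,
            )
        )

    # Engineered count-filter sites: annotation lag keeps the recorded
    # frequencies under the cascade's AF ceiling while the live cohort (or
    # the reference homozygote column) exceeds the carrier-count caps.
    autosomal_genes = [g for g in genes if g.chrom != "chrX"]
    het_carrier_fams = families[: min(34, len(families))]
    for j in range(4):
        gene = autosomal_genes[int(rng.integers(len(autosomal_genes)))]
        ref, alt = _alleles(rng)
        forced = {}
        for f in het_carrier_fams:
            forced[f["proband"]] = 1
            forced[f["father"]] = 1  # transmitted, keeps trios Mendelian
        variants.append(
            _SimVariant(
                chrom=gene.chrom, pos=alloc.take(gene), ref=ref, alt=alt, gene=gene.name,
                impact="MODERATE", consequence="missense_variant", distance_to_exon=0,
                clinvar="absent", **{k: v for k, v in _background_scores(rng).items()},
                gnomad_af=0.012, gnomad_ac=int(0.012 * _AN_REFERENCE), gnomad_hom=0,
                gnomad_hemi=0, controls_ac=100, non_neuro_ac=80,
                sim_af=0.0, cohort_af_override=0.012, forced=forced,
            )
        )
    hom_carrier_fams = families[: min(4, len(families))]
    for j in range(4):
        gene = autosomal_genes[int(rng.integers(len(autosomal_genes)))]
        ref, alt = _alleles(rng)
        forced = {}
        for f in hom_carrier_fams:
            forced[f["proband"]] = 2
            forced[f["father"]] = 1
            forced[f["mother"]] = 1
        variants.append(
            _SimVariant(
                chrom=gene.chrom, pos=alloc.take(gene), ref=ref, alt=alt, gene=gene.name,
                impact="MODERATE", consequence="missense_variant", distance_to_exon=0,
                clinvar="absent", **{k: v for k, v in _background_scores(rng).items()},
                gnomad_af=0.010, gnomad_ac=int(0.010 * _AN_REFERENCE),
                gnomad_hom=int(rng.integers(4, 9)), gnomad_hemi=0,
                controls_ac=60, non_neuro_ac=40, sim_af=0.0,
                cohort_af_override=0.010, forced=forced,
            )
        )

    # Planted causal variants ---------------------------------------------
    causal_pool = [g for g in genes if not g.susceptibility_only]
    truth: dict[str, Optional[dict]] = {}
    reported_labels: dict[tuple[str, str], str] = {}
    documented_keys: list[str] = []

    causal_flags = rng.random(config.n_families) < config.causal_fraction
    for i, f in enumerate(families):
        pro = f["proband"]
        if not causal_flags[i]:
            truth[pro] = None
            continue
        is_non_trio = f["structure"] != "trio"
        gene = causal_pool[int(rng.integers(len(causal_pool)))]
        if gene.moi == "XLR" and f["sex"] != "male":
            fallback = [g for g in causal_pool if g.moi != "XLR"]
            gene = fallback[int(rng.integers(len(fallback)))]
            log.info("family %s: XLR gene infeasible for female proband; resampled", f["id"])
        vus_like = rng.random() < config.vus_like_fraction
        min_cadd = 25.5 if is_non_trio else 0.0
        label = "VUS" if vus_like else ("pathogenic" if rng.random() < 0.35 else "likely_pathogenic")

        def planted(impact: str, forced: dict[str, int], hemi_scores: bool = False) -> _SimVariant:
            ref, alt = _alleles(rng)
            sc = _damaging_scores(rng, vus_like, min_cadd)
            clin = "absent"
            if not vus_like and rng.random() < 0.30:
                clin = "likely_pathogenic" if rng.random() < 0.6 else "pathogenic"
            elif vus_like and rng.random() < 0.20:
                clin = "VUS"
            # Private variant: the internal frequency column models a
            # database snapshot that excludes the index family, hence 0.
            return _SimVariant(
                chrom=gene.chrom, pos=alloc.take(gene), ref=ref, alt=alt, gene=gene.name,
                impact=impact, consequence=_consequence(impact), distance_to_exon=0,
                clinvar=clin, cadd=sc["cadd"], revel=sc["revel"],
                alphamissense=sc["alphamissense"], spliceai=sc["spliceai"],
                misfit_d=sc["misfit_d"], gnomad_af=0.0, gnomad_ac=0, gnomad_hom=0,
                gnomad_hemi=0, controls_ac=0, non_neuro_ac=0, sim_af=0.0, forced=forced,
                cohort_af_override=0.0,
            )

        keys: list[str] = []
        if gene.moi == "AD":
            impact = "HIGH" if (not vus_like and rng.random() < 0.5) else "MODERATE"
            v = planted(impact, {pro: 1, f["father"]: 0, f["mother"]: 0})
            variants.append(v)
            keys = [v.key]
            pattern = "de_novo"
        elif gene.moi == "AR":
            comphet = f["structure"] == "trio" and rng.random() < 0.5
            if comphet:
                v1 = planted("MODERATE", {pro: 1, f["father"]: 0, f["mother"]: 1})
                v2 = planted("MODERATE", {pro: 1, f["father"]: 1, f["mother"]: 0})
                variants += [v1, v2]
                keys = [v1.key, v2.key]
                pattern = "compound_het"
            else:
                v = planted("MODERATE", {pro: 2, f["father"]: 1, f["mother"]: 1})
                variants.append(v)
                keys = [v.key]
                pattern = "homozygous"
        else:  # XLR, male proband
            v = planted("MODERATE", {pro: 1, f["father"]: 0, f["mother"]: 1})
            variants.append(v)
            keys = [v.key]
            pattern = "hemizygous"

        # What inheritance inference can conclude from the emitted family
        # data: a de novo event in a duo/singleton is real but unverifiable.
        expected_call = pattern
        if is_non_trio and pattern == "de_novo":
            expected_call = "unknown"
        truth[pro] = {
            "causal_keys": keys, "gene": gene.name, "pattern": pattern,
            "expected_call": expected_call, "label": label,
        }
        for k in keys:
            reported_labels[(pro, k)] = label

    # Mark a couple of planted variants as already documented in the EHR.
    causal_probands = sorted(p for p, t in truth.items() if t)
    for p in causal_probands[:2]:
        documented_keys.append(truth[p]["causal_keys"][0])

    # Review-rule decoys ---------------------------------------------------
    trios = [f for f in families if f["structure"] == "trio"]
    decoy_kinds = [
        "hom_recessive_af", "dominant_ac", "dominant_hom", "ndd_controls",
        "susceptibility", "moi_mismatch", "quality", "insilico_benign",
    ]
    gene_by = {
        "AD": [g for g in genes if g.moi == "AD" and not g.susceptibility_only],
        "AR": [g for g in genes if g.moi == "AR" and not g.susceptibility_only],
        "NDD": [g for g in genes if g.moi == "AD" and g.ndd and not g.susceptibility_only
                and not g.incomplete_penetrance],
        "SUSC": [g for g in genes if g.susceptibility_only],
    }
    di = 0
    for kind in decoy_kinds:
        for _ in range(4):
            if di >= len(trios):
                break
            f = trios[di]
            di += 1
            pro = f["proband"]
            sc = _damaging_scores(rng, vus_like=False)
            base = dict(
                distance_to_exon=0, clinvar="absent", cadd=sc["cadd"], revel=sc["revel"],
                alphamissense=sc["alphamissense"], spliceai=sc["spliceai"], misfit_d=sc["misfit_d"],
                gnomad_af=0.0, gnomad_ac=0, gnomad_hom=0, gnomad_hemi=0,
                controls_ac=0, non_neuro_ac=0, sim_af=0.0, cohort_af_override=0.0,
            )
            forced_dn = {pro: 1, f["father"]: 0, f["mother"]: 0}
            if kind == "hom_recessive_af":
                gene = gene_by["AR"][int(rng.integers(len(gene_by["AR"])))]
                af = 0.005
                base.update(gnomad_af=af, gnomad_ac=int(af * _AN_REFERENCE))
                forced = {pro: 2, f["father"]: 1, f["mother"]: 1}
            elif kind == "dominant_ac":
                gene = gene_by["AD"][int(rng.integers(len(gene_by["AD"])))]
                base.update(gnomad_ac=6, gnomad_af=6 / _AN_REFERENCE)
                forced = forced_dn
            elif kind == "dominant_hom":
                gene = gene_by["AD"][int(rng.integers(len(gene_by["AD"])))]
                base.update(gnomad_ac=2, gnomad_af=2 / _AN_REFERENCE, gnomad_hom=1)
                forced = forced_dn
            elif kind == "ndd_controls":
                pool = gene_by["NDD"] or gene_by["AD"]
                gene = pool[int(rng.integers(len(pool)))]
                base.update(gnomad_ac=4, gnomad_af=4 / _AN_REFERENCE, controls_ac=4)
                forced = forced_dn
            elif kind == "susceptibility":
                if not gene_by["SUSC"]:
                    continue
                gene = gene_by["SUSC"][int(rng.integers(len(gene_by["SUSC"])))]
                forced = forced_dn
            elif kind == "moi_mismatch":
                gene = gene_by["AR"][int(rng.integers(len(gene_by["AR"])))]
                forced = forced_dn
            elif kind == "quality":
                # same phenotype branch as the proband so the similarity
                # floor is cleared and the allele-balance proxy decides
                anchor = (
                    next(g for g in genes if g.name == truth[pro]["gene"]).anchor
                    if truth.get(pro)
                    else genes[0].anchor
                )
                pool = [g for g in by_anchor.get(anchor, []) if g.moi == "AD" and not g.susceptibility_only]
                if not pool:
                    continue
                gene = pool[int(rng.integers(len(pool)))]
                forced = forced_dn
            else:  # insilico_benign
                gene = gene_by["AD"][int(rng.integers(len(gene_by["AD"])))]
                base.update(cadd=4.0, revel=0.05, alphamissense=0.08, spliceai=0.01, misfit_d=0.05)
                forced = forced_dn
            ref, alt = _alleles(rng)
            v = _SimVariant(
                chrom=gene.chrom, pos=alloc.take(gene), ref=ref, alt=alt, gene=gene.name,
                impact="MODERATE", consequence="missense_variant", forced=forced, **base,
            )
            if kind == "quality":
                v.forced_altfrac = {pro: 0.12}
            variants.append(v)

    # Phenotype profiles ---------------------------------------------------
    profiles: dict[str, dict[str, list[str]]] = {}
    gene_lookup = {g.name: g for g in genes}
    for f in families:
        pro = f["proband"]
        t = truth.get(pro)
        if t:
            gene = gene_lookup[t["gene"]]
            k = int(rng.integers(2, min(4, len(gene.disease_terms)) + 1))
            manual = set(rng.choice(gene.disease_terms, size=k, replace=False).tolist())
            other = [x for x in all_level3 if gene.anchor not in ontology.ancestors_or_self(x)]
            n_noise = int(rng.integers(1, 3))
            manual |= set(rng.choice(other, size=n_noise, replace=False).tolist())
        else:
            n_terms = int(rng.integers(3, 6))
            manual = set(rng.choice(all_level3, size=n_terms, replace=False).tolist())
        nlp = {t for t in manual if rng.random() >= config.phenotype_dropout}
        spurious_pool = [x for x in all_level3 if x not in manual]
        if config.phenotype_spurious_terms and spurious_pool:
            nlp |= set(
                rng.choice(spurious_pool, size=min(config.phenotype_spurious_terms, len(spurious_pool)),
                           replace=False).tolist()
            )
        profiles[pro] = {"manual": sorted(manual), "nlp": sorted(nlp)}

    # Genotypes ------------------------------------------------------------
    variants.sort(key=lambda v: (v.chrom, v.pos, v.alt))
    n_fam = len(families)
    dosage_rows: list[dict[str, int]] = []
    for v in variants:
        dosages: dict[str, int] = {}
        af = v.sim_af
        if af > 0:
            if v.chrom == "chrX":
                father_alleles = rng.binomial(1, af, size=n_fam)
                mother_gt = rng.binomial(2, af, size=n_fam)
                m_tx = (rng.random(n_fam) < mother_gt / 2.0).astype(int)
                for i, f in enumerate(families):
                    dosages[f["father"]] = int(father_alleles[i])
                    dosages[f["mother"]] = int(mother_gt[i])
                    if f["sex"] == "male":
                        dosages[f["proband"]] = int(m_tx[i])
                    else:
                        dosages[f["proband"]] = int(father_alleles[i] + m_tx[i])
            else:
                father_gt = rng.binomial(2, af, size=n_fam)
                mother_gt = rng.binomial(2, af, size=n_fam)
                f_tx = (rng.random(n_fam) < father_gt / 2.0).astype(int)
                m_tx = (rng.random(n_fam) < mother_gt / 2.0).astype(int)
                for i, f in enumerate(families):
                    dosages[f["father"]] = int(father_gt[i])
                    dosages[f["mother"]] = int(mother_gt[i])
                    dosages[f["proband"]] = int(f_tx[i] + m_tx[i])
        dosages.update(v.forced)
        # Sporadic missing calls (never on planted/decoy genotypes); a
        # parent's missing call leaves trio inheritance unresolvable, which
        # the cascade rejects explicitly.
        miss = rng.random(len(samples)) < config.missing_genotype_rate
        for s, m in zip(samples, miss):
            if m and s not in v.forced and dosages.get(s, 0) == 0:
                dosages[s] = -1
        # Sporadic low-depth carrier calls exercise the quality floor.
        for s in samples:
            if dosages.get(s, 0) > 0 and s not in v.forced and rng.random() < 0.02:
                v.lowdepth.add(s)
        dosage_rows.append(dosages)

    # Realised cohort frequency over emitted samples.
    cohort_af: list[float] = []
    for v, dosages in zip(variants, dosage_rows):
        alleles = carried = 0
        for s in samples:
            d = dosages.get(s, 0)
            if d < 0:
                continue
            ploidy = 1 if (v.chrom == "chrX" and sex_of[s] == "male") else 2
            alleles += ploidy
            carried += min(d, ploidy)
        cohort_af.append(carried / alleles if alleles else 0.0)

    # Output ---------------------------------------------------------------
    ped_path = out_dir / "cohort.ped"
    with open(ped_path, "w") as fh:
        for f in families:
            sex_code = {"male": "1", "female": "2"}
            present = set(emitted_samples(f))
            fa = f["father"] if f["father"] in present else "0"
            mo = f["mother"] if f["mother"] in present else "0"
            fh.write(f"{f['id']}\t{f['proband']}\t{fa}\t{mo}\t{sex_code[f['sex']]}\t2\n")
            if fa != "0":
                fh.write(f"{f['id']}\t{fa}\t0\t0\t1\t1\n")
            if mo != "0":
                fh.write(f"{f['id']}\t{mo}\t0\t0\t2\t1\n")

    vcf_path = out_dir / "cohort.vcf"
    _write_vcf(vcf_path, variants, dosage_rows, samples, sex_of, rng)

    variants_tsv = out_dir / "variants.tsv"
    _write_variant_table(variants_tsv, variants, cohort_af)

    genes_tsv = out_dir / "genes.tsv"
    with open(genes_tsv, "w") as fh:
        fh.write("gene\tmoi\tsusceptibility_only\tndd\tdisease_terms\tpli\ts_het\ts_coef\tmisfit_s\tincomplete_penetrance\n")
        for g in genes:
            fh.write(
                f"{g.name}\t{g.moi}\t{int(g.susceptibility_only)}\t{int(g.ndd)}\t"
                f"{';'.join(g.disease_terms)}\t{g.pli:.4f}\t{g.s_het:.4f}\t{g.s_coef:.4f}\t"
                f"{g.misfit_s:.4f}\t{int(g.incomplete_penetrance)}\n"
            )

    population_tsv = out_dir / "population.tsv"
    _write_population_table(population_tsv, variants, rng)

    profiles_json = out_dir / "profiles.json"
    with open(profiles_json, "w") as fh:
        json.dump(profiles, fh, indent=1, sort_keys=True)
        fh.write("\n")

    truth_json = out_dir / "truth.json"
    with open(truth_json, "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
        fh.write("\n")

    documented_tsv = out_dir / "documented.tsv"
    with open(documented_tsv, "w") as fh:
        fh.write("key\n")
        for k in documented_keys:
            fh.write(k + "\n")

    return SyntheticCohort(
        out_dir=out_dir, vcf=vcf_path, ped=ped_path, variants_tsv=variants_tsv,
        genes_tsv=genes_tsv, population_tsv=population_tsv, profiles_json=profiles_json,
        obo=obo_path, truth_json=truth_json, documented_tsv=documented_tsv,
        truth=truth, config=config,
    )


def _format_call(
    dosage: int, ploidy: int, altfrac: Optional[float], rng: np.random.Generator,
    lowdepth: bool = False,
) -> str:
    if dosage < 0:
        return "./.:.:.:." if ploidy == 2 else ".:.:.:."
    depth = int(rng.integers(4, 9)) if lowdepth else int(rng.integers(20, 45))
    if ploidy == 1:
        gt = str(min(dosage, 1))
        frac = altfrac if altfrac is not None else (0.98 if dosage else 0.0)
    else:
        gt = ["0/0", "0/1", "1/1"][dosage]
        if altfrac is not None:
            frac = altfrac
        elif dosage == 0:
            frac = 0.0
        elif dosage == 1:
            frac = float(np.clip(rng.normal(0.5, 0.06), 0.28, 0.72))
        else:
            frac = float(rng.uniform(0.93, 1.0))
    alt_reads = int(round(depth * frac))
    return f"{gt}:{depth - alt_reads},{alt_reads}:{depth}:{int(rng.integers(60, 100))}"


def _write_vcf(path: Path, variants, dosage_rows, samples, sex_of, rng) -> None:
    ref_call = "0/0:30,0:30:99"
    ref_call_hap = "0:30,0:30:99"
    lines = [
        "##fileformat=VCFv4.2",
        "##contig=<ID=chr1,length=10000000>",
        "##contig=<ID=chr2,length=10000000>",
        "##contig=<ID=chrX,length=10000000>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples),
    ]
    for v, dosages in zip(variants, dosage_rows):
        cells = []
        for s in samples:
            ploidy = 1 if (v.chrom == "chrX" and sex_of[s] == "male") else 2
            d = dosages.get(s, 0)
            if d == 0 and s not in v.forced_altfrac:
                cells.append(ref_call if ploidy == 2 else ref_call_hap)
            else:
                cells.append(_format_call(d, ploidy, v.forced_altfrac.get(s), rng, s in v.lowdepth))
        lines.append(
            f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t100\tPASS\t.\tGT:AD:DP:GQ\t" + "\t".join(cells)
        )
    path.write_text("\n".join(lines) + "\n")


def _fmt_opt(x: Optional[float]) -> str:
    return "." if x is None else f"{x:.4f}"


def _write_variant_table(path: Path, variants, cohort_af) -> None:
    cols = (
        "key\tgene\tconsequence\timpact_tier\tdistance_to_exon\tclinvar\tcadd_phred\trevel\t"
        "alphamissense\tspliceai\tmisfit_d\tgnomad_af\tcohort_af\tgnomad_ac\tgnomad_hom\t"
        "gnomad_hemi\tcontrols_ac\tnon_neuro_ac\n"
    )
    with open(path, "w") as fh:
        fh.write(cols)
        for v, caf in zip(variants, cohort_af):
            caf_out = v.cohort_af_override if v.cohort_af_override is not None else caf
            fh.write(
                f"{v.key}\t{v.gene}\t{v.consequence}\t{v.impact}\t{v.distance_to_exon}\t{v.clinvar}\t"
                f"{_fmt_opt(v.cadd)}\t{_fmt_opt(v.revel)}\t{_fmt_opt(v.alphamissense)}\t"
                f"{_fmt_opt(v.spliceai)}\t{_fmt_opt(v.misfit_d)}\t{v.gnomad_af:.6g}\t{caf_out:.6g}\t"
                f"{v.gnomad_ac}\t{v.gnomad_hom}\t{v.gnomad_hemi}\t{v.controls_ac}\t{v.non_neuro_ac}\n"
            )


def _write_population_table(path: Path, variants, rng) -> None:
    """One row per cohort variant plus occasional co-located same-impact
    alleles so locus-level aggregation has work to do."""
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tref\talt\timpact_tier\tac\tan\taf\thom\themi\tcontrols_ac\tnon_neuro_ac\n")
        for v in variants:
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.ref}\t{v.alt}\t{v.impact}\t{v.gnomad_ac}\t{_AN_REFERENCE}\t"
                f"{v.gnomad_af:.6g}\t{v.gnomad_hom}\t{v.gnomad_hemi}\t{v.controls_ac}\t{v.non_neuro_ac}\n"
            )
            if v.gnomad_af > 0 and rng.random() < 0.10:
                alt2 = next(b for b in _ACGT if b not in (v.ref, v.alt))
                ac2 = max(1, v.gnomad_ac // 4)
                fh.write(
                    f"{v.chrom}\t{v.pos}\t{v.ref}\t{alt2}\t{v.impact}\t{ac2}\t{_AN_REFERENCE}\t"
                    f"{ac2 / _AN_REFERENCE:.6g}\t0\t0\t{ac2 // 2}\t{ac2 // 3}\n"
                )
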