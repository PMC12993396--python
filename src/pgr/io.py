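"""Readers and writers for the standard formats the pipeline touches.

Input side: 6-column PED pedigrees, multi-sample VCF (via pysam), tab
separated annotation / gene / population tables, and per-proband phenotype
profile JSON.  Output side: per-proband machine-readable JSON reports plus a
TSV summary with the stage-count funnel.

TSV convention throughout: header row, tab-delimited, '.' or empty cell
means missing.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
import pysam

from .types import (
    ClinvarClass,
    Cohort,
    Family,
    GenotypeCall,
    GeneRecord,
    Impact,
    Individual,
    Moi,
    PhenotypeProfile,
    Sex,
    Variant,
    VariantAnnotation,
    parse_optional_float,
)

log = logging.getLogger(__name__)

_SEX_CODES = {"1": Sex.MALE, "2": Sex.FEMALE, "0": Sex.UNKNOWN}
_X_CHROMS = {"X", "chrX"}

#: Pseudoautosomal intervals on chrX as (start, end) 1-based inclusive.
#: Empty by default: the synthetic build carries no PAR and real-data users
#: supply their build's intervals explicitly.
DEFAULT_PAR_INTERVALS: tuple[tuple[int, int], ...] = ()


class PedigreeError(ValueError):
    pass


def read_pedigree(path: str | Path, proband_override: Optional[dict[str, str]] = None) -> list[Family]:
    """Parse a 6-column PED file into :class:`Family` objects.

    The proband defaults to the first affected non-founder of each family
    (first affected member when all are founders); ``proband_override`` maps
    family id to an explicit proband sample id.
    """
    rows: dict[str, list[Individual]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 6:
                raise PedigreeError(f"{path}:{lineno}: expected 6 columns, got {len(fields)}")
            fam, ind, father, mother, sex, phen = fields
            if sex not in _SEX_CODES or phen not in ("0", "1", "2"):
                raise PedigreeError(f"{path}:{lineno}: bad sex/phenotype code")
            rows.setdefault(fam, []).append(
                Individual(
                    id=ind,
                    sex=_SEX_CODES[sex],
                    affected=(phen == "2"),
                    father_id=None if father == "0" else father,
                    mother_id=None if mother == "0" else mother,
                )
            )

    families = []
    for fam_id, members in rows.items():
        by_id = {m.id: m for m in members}
        for m in members:
            for pid in (m.father_id, m.mother_id):
                if pid is not None and pid not in by_id:
                    # Parent referenced but not genotyped: treat as unavailable.
                    warnings.warn(f"family {fam_id}: parent {pid} of {m.id} absent from pedigree")
        proband = None
        if proband_override and fam_id in proband_override:
            proband = proband_override[fam_id]
            if proband not in by_id:
                raise PedigreeError(f"override proband {proband!r} not in family {fam_id!r}")
        else:
            affected = [m for m in members if m.affected]
            non_founders = [m for m in affected if m.father_id or m.mother_id]
            pick = non_founders or affected
            if not pick:
                raise PedigreeError(f"family {fam_id!r} has no affected member to use as proband")
            proband = pick[0].id
        families.append(Family(id=fam_id, members=by_id, proband_id=proband))
    return families


def _in_par(pos: int, par: Iterable[tuple[int, int]]) -> bool:
    return any(lo <= pos <= hi for lo, hi in par)


def read_cohort_vcf(
    path: str | Path,
    families: list[Family],
    par_intervals: Iterable[tuple[int, int]] = DEFAULT_PAR_INTERVALS,
) -> dict[Variant, dict[str, GenotypeCall]]:
    """Load a multi-sample VCF into per-variant genotype maps.

    Multi-allelic sites are expanded into biallelic records (every filter is
    per-allele).  Male non-PAR chrX calls are flagged hemizygous.  Records
    with non-ACGT alleles are skipped with a warning.
    """
    sex_of = {m.id: m.sex for f in families for m in f.members.values()}
    vf = pysam.VariantFile(str(path))
    vcf_samples = set(vf.header.samples)
    missing = sorted(s for s in sex_of if s not in vcf_samples)
    if missing:
        raise ValueError(f"pedigree samples absent from VCF: {', '.join(missing)}")

    out: dict[Variant, dict[str, GenotypeCall]] = {}
    for rec in vf:
        for alt_idx, alt in enumerate(rec.alts or (), start=1):
            if any(b not in "ACGT" for b in rec.ref) or any(b not in "ACGT" for b in alt):
                log.warning("skipping non-ACGT record %s:%d %s>%s", rec.chrom, rec.pos, rec.ref, alt)
                continue
            variant = Variant(rec.chrom, rec.pos, rec.ref, alt)
            is_x = rec.chrom in _X_CHROMS and not _in_par(rec.pos, par_intervals)
            calls: dict[str, GenotypeCall] = {}
            for sample in sex_of:
                sc = rec.samples[sample]
                gt = sc.get("GT")
                alleles = [a for a in (gt or ()) if a is not None]
                if not alleles:
                    calls[sample] = GenotypeCall(sample=sample, dosage=None)
                    continue
                dosage = sum(1 for a in alleles if a == alt_idx)
                hemi = is_x and sex_of[sample] is Sex.MALE and len(alleles) == 1
                ad = sc.get("AD")
                depth = sc.get("DP")
                alt_frac = None
                if ad is not None and len(ad) > alt_idx and ad[0] is not None:
                    total = sum(a for a in ad if a is not None)
                    if depth is None:
                        depth = total
                    if total > 0:
                        alt_frac = (ad[alt_idx] or 0) / total
                gq = sc.get("GQ")
                calls[sample] = GenotypeCall(
                    sample=sample,
                    dosage=dosage,
                    hemizygous=hemi,
                    depth=depth,
                    alt_fraction=alt_frac,
                    quality=float(gq) if gq is not None else None,
                )
            out[variant] = calls
    return out


_IMPACTS = {i.value for i in Impact}


def read_annotation_tables(
    variant_tsv: str | Path, gene_tsv: str | Path
) -> tuple[dict[Variant, VariantAnnotation], dict[str, GeneRecord]]:
    """Read the per-variant annotation table (keyed chrom:pos:ref:alt) and
    the gene table (keyed by symbol)."""
    vdf = pd.read_csv(variant_tsv, sep="\t", dtype=str, keep_default_na=False)
    if vdf["key"].duplicated().any():
        dup = vdf.loc[vdf["key"].duplicated(), "key"].iloc[0]
        raise ValueError(f"duplicate variant key in annotation table: {dup}")
    annotations: dict[Variant, VariantAnnotation] = {}
    for row in vdf.itertuples(index=False):
        if row.impact_tier not in _IMPACTS:
            raise ValueError(f"unknown impact tier {row.impact_tier!r} for {row.key}")
        annotations[Variant.from_key(row.key)] = VariantAnnotation(
            gene=row.gene,
            consequence=row.consequence,
            impact_tier=Impact(row.impact_tier),
            distance_to_exon=int(row.distance_to_exon),
            clinvar=ClinvarClass(row.clinvar),
            cadd_phred=parse_optional_float(row.cadd_phred),
            revel=parse_optional_float(row.revel),
            alphamissense=parse_optional_float(row.alphamissense),
            spliceai=parse_optional_float(row.spliceai),
            misfit_d=parse_optional_float(row.misfit_d),
            gnomad_af=float(row.gnomad_af),
            cohort_af=float(row.cohort_af),
            gnomad_ac=int(row.gnomad_ac),
            gnomad_hom=int(row.gnomad_hom),
            gnomad_hemi=int(row.gnomad_hemi),
            controls_ac=int(row.controls_ac),
            non_neuro_ac=int(row.non_neuro_ac),
        )

    gdf = pd.read_csv(gene_tsv, sep="\t", dtype=str, keep_default_na=False)
    if gdf["gene"].duplicated().any():
        dup = gdf.loc[gdf["gene"].duplicated(), "gene"].iloc[0]
        raise ValueError(f"duplicate gene in gene table: {dup}")
    genes: dict[str, GeneRecord] = {}
    for row in gdf.itertuples(index=False):
        moi = frozenset(Moi(m) for m in row.moi.split(";") if m)
        terms = frozenset(t for t in row.disease_terms.split(";") if t)
        genes[row.gene] = GeneRecord(
            gene=row.gene,
            moi=moi,
            susceptibility_only=row.susceptibility_only == "1",
            ndd=row.ndd == "1",
            disease_terms=terms,
            pli=parse_optional_float(row.pli),
            s_het=parse_optional_float(row.s_het),
            s_coef=parse_optional_float(row.s_coef),
            misfit_s=parse_optional_float(row.misfit_s),
            incomplete_penetrance=row.incomplete_penetrance == "1",
        )
    return annotations, genes


def read_population_table(path: str | Path) -> pd.DataFrame:
    """Population table used for locus-level evidence aggregation at review.

    Columns: chrom, pos, ref, alt, impact_tier, ac, an, af, hom, hemi,
    controls_ac, non_neuro_ac.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str, "impact_tier": str})
    required = {"chrom", "pos", "ref", "alt", "impact_tier", "ac", "an", "af", "hom", "hemi", "controls_ac", "non_neuro_ac"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"population table missing columns: {sorted(missing)}")
    return df


def read_profiles(path: str | Path) -> dict[str, tuple[frozenset[str], frozenset[str]]]:
    """Phenotype profile JSON: {sample: {"manual": [...], "nlp": [...]}}.

    Returns raw (manual, nlp) term sets; obsolete filtering and combination
    happen in :func:`pgr.ontology.combine_profiles` once an ontology is
    loaded.
    """
    with open(path) as fh:
        raw = json.load(fh)
    return {
        sample: (frozenset(entry.get("manual", ())), frozenset(entry.get("nlp", ())))
        for sample, entry in raw.items()
    }


def write_internal_report(
    out_dir: str | Path,
    candidates: list,
    stage_counts,
    max_variants_per_proband: int = 2,
    run_seed: Optional[int] = None,
) -> tuple[Path, Path]:
    """Write the internal report: per-proband JSON records plus a TSV summary.

    Each proband's record lists at most ``max_variants_per_proband`` retained
    variants, highest score first.  An empty candidate list still yields
    valid files carrying the funnel counts.  ``candidates`` are
    ``ReviewedCandidate`` objects from :mod:`pgr.review`.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    by_proband: dict[str, list] = {}
    for c in candidates:
        by_proband.setdefault(c.candidate.proband, []).append(c)

    records = {}
    rows = []
    for proband in sorted(by_proband):
        ranked = sorted(by_proband[proband], key=lambda c: (-c.score, c.candidate.variant.key))
        top = ranked[:max_variants_per_proband]
        records[proband] = [
            {
                "variant": c.candidate.variant.key,
                "gene": c.candidate.annotation.gene,
                "score": round(c.score, 6),
                "inheritance": c.candidate.inheritance.pattern.value,
                "gnomad_af": c.candidate.annotation.gnomad_af,
                "acmg_class": c.acmg.classification if c.acmg else None,
                "acmg_posterior": round(c.acmg.posterior, 6) if c.acmg else None,
                "acmg_criteria": sorted(cr.code for cr in c.acmg.criteria) if c.acmg else [],
                "returnable": bool(c.acmg.returnable) if c.acmg else False,
            }
            for c in top
        ]
        for entry in records[proband]:
            rows.append({"proband": proband, **entry, "acmg_criteria": ";".join(entry["acmg_criteria"])})

    payload = {
        "run_seed": run_seed,
        "stage_counts": stage_counts.to_dict() if hasattr(stage_counts, "to_dict") else dict(stage_counts),
        "probands": records,
    }
    json_path = out_dir / "report.json"
    with open(json_path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")

    tsv_path = out_dir / "report.tsv"
    cols = ["proband", "variant", "gene", "score", "inheritance", "gnomad_af",
            "acmg_class", "acmg_posterior", "acmg_criteria", "returnable"]
    pd.DataFrame(rows, columns=cols).to_csv(tsv_path, sep="\t", index=False)
    return json_path, tsv_path
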