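"""End-to-end orchestration of the reanalysis pipeline.

``load_inputs`` reads every input format into one context object;
``run_pgr`` drives the funnel (filter cascade -> phenotype scoring ->
feature encoding -> neural-network score -> 0.5 threshold -> first-pass
screen -> second-pass ACMG classification -> internal reports) and records
per-stage variant and proband counts; ``pruning_experiment`` implements the
phenotype-branch ablation with its rank-sum statistics; and
``accounting_summary`` turns raw stage counts into the rational yield
figures used in reporting.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from . import cfa as cfa_mod
from . import io as io_mod
from . import ontology as onto_mod
from . import review as review_mod
from .features import (
    FeatureSchema,
    FeatureVector,
    LabeledDataset,
    assemble_training_set,
    encode,
)
from .scoring import TrainedModel, VariantScoringResults
from .stats import benjamini_hochberg, wilcoxon_rank_sum  # noqa: F401  (re-exported)
from .types import CandidateVariant, Cohort, PhenotypeProfile, PhenotypeScores

log = logging.getLogger(__name__)


@dataclass
class StageCounts:
    """Variant and proband counts surviving each pipeline stage."""

    input_variants: int = 0
    post_cfa: int = 0
    post_score_threshold: int = 0
    post_first_pass: int = 0
    post_second_pass: int = 0
    probands: dict[str, int] = field(default_factory=dict)

    def variant_funnel(self) -> list[int]:
        return [
            self.input_variants,
            self.post_cfa,
            self.post_score_threshold,
            self.post_first_pass,
            self.post_second_pass,
        ]

    def validate_monotone(self) -> None:
        f = self.variant_funnel()
        if any(a < b for a, b in zip(f, f[1:])):
            raise ValueError(f"stage counts must be non-increasing: {f}")

    def to_dict(self) -> dict:
        return {
            "input_variants": self.input_variants,
            "post_cfa": self.post_cfa,
            "post_score_threshold": self.post_score_threshold,
            "post_first_pass": self.post_first_pass,
            "post_second_pass": self.post_second_pass,
            "probands": dict(sorted(self.probands.items())),
        }


@dataclass
class LoadedInputs:
    """Everything one pipeline run needs, loaded and cross-validated."""

    cohort: Cohort
    ontology: onto_mod.Ontology
    ic_map: dict[str, float]
    locus_index: dict[tuple[str, int], list[dict]]
    documented: frozenset[str]
    schema: FeatureSchema


def load_inputs(data_dir: str | Path, par_intervals: Iterable[tuple[int, int]] = ()) -> LoadedInputs:
    """Load a data directory laid out as the synthetic generator emits it
    (cohort.ped / cohort.vcf / variants.tsv / genes.tsv / population.tsv /
    profiles.json / ontology.obo / optional documented.tsv)."""
    data_dir = Path(data_dir)
    families = io_mod.read_pedigree(data_dir / "cohort.ped")
    genotypes = io_mod.read_cohort_vcf(data_dir / "cohort.vcf", families, par_intervals)
    annotations, genes = io_mod.read_annotation_tables(
        data_dir / "variants.tsv", data_dir / "genes.tsv"
    )
    cohort = Cohort(families=families, genotypes=genotypes, annotations=annotations, genes=genes)
    cohort.validate()

    ontology = onto_mod.load_obo(data_dir / "ontology.obo")
    corpus = onto_mod.AnnotationCorpus(
        {g.gene: frozenset(g.disease_terms) for g in genes.values() if g.disease_terms}
    )
    ic_map = onto_mod.information_content(ontology, corpus)

    raw_profiles = io_mod.read_profiles(data_dir / "profiles.json")
    for sample, (manual, nlp) in raw_profiles.items():
        cohort.profiles[sample] = onto_mod.combine_profiles(manual, nlp, ontology)

    pop_df = io_mod.read_population_table(data_dir / "population.tsv")
    locus_index = review_mod.build_locus_index(pop_df)

    documented: frozenset[str] = frozenset()
    doc_path = data_dir / "documented.tsv"
    if doc_path.exists():
        documented = frozenset(pd.read_csv(doc_path, sep="\t")["key"].astype(str))

    return LoadedInputs(
        cohort=cohort, ontology=ontology, ic_map=ic_map,
        locus_index=locus_index, documented=documented, schema=FeatureSchema(),
    )


# ---------------------------------------------------------------------------
# Per-candidate context


def phenotype_scores(
    loaded: LoadedInputs,
    proband: str,
    gene: str,
    terms: Optional[frozenset[str]] = None,
) -> PhenotypeScores:
    """Built-in phenotype relevance of ``gene`` for ``proband``.

    ``terms`` overrides the proband's combined profile (used by the pruning
    experiment); an empty patient or gene term set scores zero.
    """
    record = loaded.cohort.genes.get(gene)
    gene_terms = record.disease_terms if record else frozenset()
    if terms is None:
        profile = loaded.cohort.profiles.get(proband)
        terms = profile.combined_terms if profile else frozenset()
    if not terms or not gene_terms:
        return PhenotypeScores()
    sim = onto_mod.similarity(terms, gene_terms, loaded.ontology, loaded.ic_map)
    match = onto_mod.match_features(terms, gene_terms, loaded.ontology, loaded.ic_map)
    return PhenotypeScores(similarity=sim, match=match)


def phenotype_overlap_fn(loaded: LoadedInputs):
    """Cached (proband, gene) -> bool overlap used by the non-trio clause:
    at least one exact or one-level HPO match."""
    cache: dict[tuple[str, str], bool] = {}

    def overlap(proband: str, gene: str) -> bool:
        key = (proband, gene)
        if key not in cache:
            ph = phenotype_scores(loaded, proband, gene)
            cache[key] = (ph.match.exact_count + ph.match.one_level_count) >= 1
        return cache[key]

    return overlap


def locus_evidence(loaded: LoadedInputs, candidate: CandidateVariant) -> review_mod.PopulationEvidence:
    rows = loaded.locus_index.get((candidate.variant.chrom, candidate.variant.pos), [])
    return review_mod.aggregate_locus_evidence(candidate.variant, candidate.annotation, rows)


def auto_acmg(
    loaded: LoadedInputs,
    candidate: CandidateVariant,
    evidence: review_mod.PopulationEvidence,
    config: Optional[review_mod.ReviewConfig] = None,
) -> review_mod.AcmgResult:
    partner_clinvar = None
    if candidate.inheritance.partner is not None:
        partner_ann = loaded.cohort.annotations.get(candidate.inheritance.partner)
        if partner_ann is not None:
            partner_clinvar = partner_ann.clinvar
    gene = loaded.cohort.genes.get(candidate.annotation.gene)
    criteria = review_mod.assign_acmg_criteria(candidate, gene, evidence, config, partner_clinvar)
    return review_mod.combine_tavtigian(criteria)


class CandidateContext:
    """Caches locus evidence, automated ACMG results and encodings for the
    candidates of one loaded cohort."""

    def __init__(self, loaded: LoadedInputs, review_config: Optional[review_mod.ReviewConfig] = None):
        self.loaded = loaded
        self.review_config = review_config or review_mod.ReviewConfig()
        self._evidence: dict[tuple[str, str], review_mod.PopulationEvidence] = {}
        self._acmg: dict[tuple[str, str], review_mod.AcmgResult] = {}

    def evidence(self, cand: CandidateVariant) -> review_mod.PopulationEvidence:
        key = (cand.proband, cand.variant.key)
        if key not in self._evidence:
            self._evidence[key] = locus_evidence(self.loaded, cand)
        return self._evidence[key]

    def acmg(self, cand: CandidateVariant) -> review_mod.AcmgResult:
        key = (cand.proband, cand.variant.key)
        if key not in self._acmg:
            self._acmg[key] = auto_acmg(self.loaded, cand, self.evidence(cand), self.review_config)
        return self._acmg[key]

    def encode(self, cand: CandidateVariant, terms: Optional[frozenset[str]] = None) -> FeatureVector:
        phen = phenotype_scores(self.loaded, cand.proband, cand.annotation.gene, terms)
        gene = self.loaded.cohort.genes.get(cand.annotation.gene)
        return encode(cand, phen, gene, self.acmg(cand).classification, self.loaded.schema)


# ---------------------------------------------------------------------------
# Training-set assembly


def build_training_dataset(
    loaded: LoadedInputs,
    reported: Mapping[tuple[str, str], str],
    thresholds: Optional[cfa_mod.CfaThresholds] = None,
    context: Optional[CandidateContext] = None,
) -> LabeledDataset:
    """Positives are the reported variants with their reported class (kept
    even when they fail the cascade); negatives are cascade survivors not
    reported for the same probands."""
    context = context or CandidateContext(loaded)
    survivors, _, _ = cfa_mod.run_cfa(loaded.cohort, thresholds, phenotype_overlap_fn(loaded))
    all_cands = {
        (c.proband, c.variant.key): c
        for fam_cands in cfa_mod.collect_candidates(loaded.cohort, thresholds).values()
        for c in fam_cands
    }
    survivor_rows = [
        (c.proband, c.variant.key, context.encode(c)) for c in survivors
    ]
    reported_rows = []
    for (proband, key), label in sorted(reported.items()):
        cand = all_cands.get((proband, key))
        if cand is None:
            warnings.warn(f"reported variant {key} not resolvable for {proband}; excluded")
            continue
        reported_rows.append((proband, key, label, context.encode(cand)))
    return assemble_training_set(survivor_rows, reported_rows)


# ---------------------------------------------------------------------------
# The full run


@dataclass
class RunResult:
    reviewed: list[review_mod.ReviewedCandidate]
    stage_counts: StageCounts
    report_json: Optional[Path]
    report_tsv: Optional[Path]
    scores: dict[tuple[str, str], float]


def run_pgr(
    loaded: LoadedInputs,
    model: TrainedModel,
    out_dir: Optional[str | Path] = None,
    seed: Optional[int] = None,
    cfa_thresholds: Optional[cfa_mod.CfaThresholds] = None,
    review_config: Optional[review_mod.ReviewConfig] = None,
) -> RunResult:
    """Run the full pipeline and (optionally) write the internal reports."""
    context = CandidateContext(loaded, review_config)
    survivors, _, funnel = cfa_mod.run_cfa(
        loaded.cohort, cfa_thresholds, phenotype_overlap_fn(loaded)
    )
    counts = StageCounts(input_variants=funnel.input_variants, post_cfa=len(survivors))
    counts.probands["input"] = len(loaded.cohort.families)
    counts.probands["post_cfa"] = len({c.proband for c in survivors})

    scores_map: dict[tuple[str, str], float] = {}
    reviewed: list[review_mod.ReviewedCandidate] = []
    if survivors:
        X = np.vstack([context.encode(c).values for c in survivors])
        scores = model.predict_scores(X)
        flags = model.flags(scores)
        for c, s in zip(survivors, scores):
            scores_map[(c.proband, c.variant.key)] = float(s)

        flagged = [c for c, f in zip(survivors, flags) if f]
        counts.post_score_threshold = len(flagged)
        counts.probands["post_score_threshold"] = len({c.proband for c in flagged})

        for cand, score in [(c, scores_map[(c.proband, c.variant.key)]) for c in flagged]:
            gene = loaded.cohort.genes.get(cand.annotation.gene)
            phen = phenotype_scores(loaded, cand.proband, cand.annotation.gene)
            first = review_mod.first_pass_screen(
                cand, gene, phen, context.evidence(cand), context.review_config
            )
            rc = review_mod.ReviewedCandidate(candidate=cand, score=score, first_pass=first)
            if first.status == "retain":
                rc.acmg = context.acmg(cand)
                rc.second_pass = review_mod.second_pass_classify(
                    cand, rc.acmg, phen, context.review_config, loaded.documented
                )
            reviewed.append(rc)

        first_retained = [r for r in reviewed if r.first_pass.status == "retain"]
        counts.post_first_pass = len(first_retained)
        counts.probands["post_first_pass"] = len({r.candidate.proband for r in first_retained})
        final = [r for r in reviewed if r.retained]
        counts.post_second_pass = len(final)
        counts.probands["post_second_pass"] = len({r.candidate.proband for r in final})
    else:
        final = []

    counts.validate_monotone()
    report_json = report_tsv = None
    if out_dir is not None:
        report_json, report_tsv = io_mod.write_internal_report(
            out_dir, [r for r in reviewed if r.retained], counts, run_seed=seed
        )
    return RunResult(
        reviewed=reviewed, stage_counts=counts,
        report_json=report_json, report_tsv=report_tsv, scores=scores_map,
    )


# ---------------------------------------------------------------------------
# Phenotype-branch pruning experiment


@dataclass
class PruningResult:
    """Per-(proband, branch, variant) score deltas plus pooled rank-sum
    comparisons (BH-adjusted across the comparison family)."""

    records: pd.DataFrame
    nlp_records: pd.DataFrame
    tests: pd.DataFrame

    def mean_delta(self, group: str, causal_branch: Optional[bool] = None) -> float:
        df = self.records[self.records["group"] == group]
        if causal_branch is not None:
            df = df[df["gene_branch_overlap"] == causal_branch]
        return float(df["delta"].mean()) if len(df) else float("nan")


def pruning_experiment(
    loaded: LoadedInputs,
    results: VariantScoringResults,
    thresholds: Optional[cfa_mod.CfaThresholds] = None,
    min_branches: int = 2,
) -> PruningResult:
    """Ablate one phenotype branch at a time and re-score.

    For each validation-set reported variant (split into true positives and
    false negatives at the 0.5 threshold), the proband's manual terms are
    partitioned by third-level ancestor; each branch is removed in turn,
    phenotype features are rebuilt from the pruned profile, the candidate
    is re-encoded and re-scored, and the score delta (pruned - original) is
    recorded together with whether the branch overlaps the variant gene's
    disease annotations.  Probands with fewer branches than ``min_branches``
    are skipped.  TP-vs-FN delta distributions are compared with two-sided
    rank-sum tests and Benjamini-Hochberg adjusted; an extra comparison
    contrasts manual-only with combined (manual+NLP) profiles.
    """
    model = results.model
    context = CandidateContext(loaded)
    all_cands = {
        (c.proband, c.variant.key): c
        for fam_cands in cfa_mod.collect_candidates(loaded.cohort, thresholds).values()
        for c in fam_cands
    }

    val = results.validation_set
    called = results.validation_scores >= results.config.threshold
    rows = []
    for i in range(len(val.labels)):
        if val.labels[i] == "negative":
            continue
        rows.append((val.groups[i], val.keys[i], "TP" if called[i] else "FN"))

    records, nlp_records = [], []
    pending: list[tuple[dict, FeatureVector]] = []
    for proband, key, group in rows:
        cand = all_cands.get((proband, key))
        profile = loaded.cohort.profiles.get(proband)
        if cand is None or profile is None:
            continue
        branches = onto_mod.third_level_partition(profile.manual_terms, loaded.ontology)
        branches = [b for b in branches if b.anchor is not None]
        if len(branches) < min_branches:
            log.info("proband %s: %d branch(es); pruning skipped", proband, len(branches))
            continue
        gene_terms = (
            loaded.cohort.genes[cand.annotation.gene].disease_terms
            if cand.annotation.gene in loaded.cohort.genes
            else frozenset()
        )
        base = {"proband": proband, "variant": key, "group": group}
        pending.append(({**base, "kind": "original"}, context.encode(cand)))
        pending.append(({**base, "kind": "manual"}, context.encode(cand, profile.manual_terms)))
        for b in branches:
            pruned = onto_mod.prune_branch(profile, b)
            meta = {
                **base,
                "kind": "pruned",
                "branch": b.anchor,
                "gene_branch_overlap": bool(b.members & gene_terms),
            }
            pending.append((meta, context.encode(cand, pruned.combined_terms)))

    if not pending:
        empty = pd.DataFrame()
        return PruningResult(records=empty, nlp_records=empty, tests=empty)

    X = np.vstack([fv.values for _, fv in pending])
    scores = model.predict_scores(X)
    by_kind: dict[tuple[str, str, str], float] = {}
    for (meta, _), s in zip(pending, scores):
        if meta["kind"] in ("original", "manual"):
            by_kind[(meta["proband"], meta["variant"], meta["kind"])] = float(s)
    for (meta, _), s in zip(pending, scores):
        pk = (meta["proband"], meta["variant"])
        if meta["kind"] == "pruned":
            orig = by_kind[(*pk, "original")]
            records.append(
                {
                    "proband": meta["proband"], "variant": meta["variant"],
                    "group": meta["group"], "branch": meta["branch"],
                    "gene_branch_overlap": meta["gene_branch_overlap"],
                    "original": orig, "pruned": float(s), "delta": float(s) - orig,
                }
            )
        elif meta["kind"] == "manual":
            orig = by_kind[(*pk, "original")]
            nlp_records.append(
                {
                    "proband": meta["proband"], "variant": meta["variant"],
                    "group": meta["group"], "combined": orig,
                    "manual_only": float(s), "delta": float(s) - orig,
                }
            )

    rec_df = pd.DataFrame(records)
    nlp_df = pd.DataFrame(nlp_records)

    comparisons = []

    def compare(name: str, a: np.ndarray, b: np.ndarray) -> None:
        if len(a) and len(b):
            _, p = wilcoxon_rank_sum(a, b)
            comparisons.append({"comparison": name, "n_a": len(a), "n_b": len(b), "p": p})

    tp = rec_df[rec_df["group"] == "TP"]
    fn = rec_df[rec_df["group"] == "FN"]
    compare("tp_vs_fn_pruning_delta", tp["delta"].to_numpy(), fn["delta"].to_numpy())
    compare(
        "tp_causal_vs_disjoint_branch",
        tp[tp["gene_branch_overlap"]]["delta"].to_numpy(),
        tp[~tp["gene_branch_overlap"]]["delta"].to_numpy(),
    )
    if len(nlp_df):
        compare(
            "tp_vs_fn_nlp_effect",
            nlp_df[nlp_df["group"] == "TP"]["delta"].to_numpy(),
            nlp_df[nlp_df["group"] == "FN"]["delta"].to_numpy(),
        )
    tests = pd.DataFrame(comparisons)
    if len(tests):
        tests["q"] = benjamini_hochberg(tests["p"].to_numpy())
    return PruningResult(records=rec_df, nlp_records=nlp_df, tests=tests)


# ---------------------------------------------------------------------------
# Accounting


@dataclass(frozen=True)
class Fraction:
    numerator: int
    denominator: int
    percent: float

    def __post_init__(self) -> None:
        if not (0 <= self.numerator <= self.denominator):
            raise ValueError("numerator must lie in [0, denominator]")


def accounting_summary(counts: Mapping[str, tuple[int, int]], decimals: int = 0) -> dict[str, Fraction]:
    """Named (numerator, denominator) pairs -> rational fractions with the
    percentage rounded to the requested display precision."""
    out = {}
    for name, (num, den) in counts.items():
        if den <= 0:
            raise ValueError(f"{name}: denominator must be positive")
        out[name] = Fraction(num, den, round(100.0 * num / den, decimals))
    return out
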