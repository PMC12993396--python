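"""Deterministic encoding of candidates into the 43-slot feature vector.

The scorer consumes a fixed, ordered numeric encoding of each candidate:
five categorical families expanded one-hot (inheritance configuration 6,
gene inheritance modes 4, impact tier 4, ClinVar class 7, automated ACMG
class 5) plus 17 numeric slots covering genotype evidence (allele fraction,
depth), population frequency (gnomAD, internal cohort), phenotype scores
(three external-score slots with the built-in similarity as fallback, the
exact+one-level HPO match count and the IC>=2 exact-match count), in-silico
predictors (CADD PHRED, REVEL, AlphaMissense, SpliceAI, MisFit D) and gene
constraint (S_coef, S_het, pLI).

Missing numeric values are carried as NaN with a parallel mask and imputed
with per-column training medians inside the standardizer, so encoding stays
pure and dataset-independent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .types import (
    CandidateVariant,
    ClinvarClass,
    GeneRecord,
    Impact,
    InheritancePattern,
    Moi,
    PhenotypeScores,
)

SCHEMA_VERSION = "1"

_INHERITANCE_LEVELS = [
    "de_novo", "homozygous", "hemizygous", "compound_het",
    "segregating_dominant", "inherited_unphased",
]
_MOI_LEVELS = ["AD", "AR", "XLD", "XLR"]
_IMPACT_LEVELS = ["HIGH", "MODERATE", "LOW", "MODIFIER"]
_CLINVAR_LEVELS = [
    "pathogenic", "likely_pathogenic", "VUS", "conflicting",
    "likely_benign", "benign", "absent",
]
_ACMG_LEVELS = ["P", "LP", "VUS", "LB", "B"]
_NUMERIC = [
    "vaf", "depth", "gnomad_af", "cohort_af",
    "hpo3", "amelie", "shepherd", "hpo_match_count", "hpo_ic2_count",
    "cadd_phred", "revel", "alphamissense", "spliceai", "misfit_d",
    "s_coef", "s_het", "pli",
]


@dataclass(frozen=True)
class FeatureEntry:
    name: str
    source: str      # categorical family or numeric field name
    encoding: str    # "one_hot_level" | "binary" | "numeric"
    level: Optional[str] = None


def _default_entries() -> tuple[FeatureEntry, ...]:
    entries: list[FeatureEntry] = []
    for lvl in _INHERITANCE_LEVELS:
        entries.append(FeatureEntry(f"inheritance={lvl}", "inheritance", "one_hot_level", lvl))
    for lvl in _MOI_LEVELS:
        entries.append(FeatureEntry(f"gene_moi={lvl}", "gene_moi", "binary", lvl))
    for lvl in _IMPACT_LEVELS:
        entries.append(FeatureEntry(f"impact={lvl}", "impact", "one_hot_level", lvl))
    for lvl in _CLINVAR_LEVELS:
        entries.append(FeatureEntry(f"clinvar={lvl}", "clinvar", "one_hot_level", lvl))
    for lvl in _ACMG_LEVELS:
        entries.append(FeatureEntry(f"acmg_auto={lvl}", "acmg_auto", "one_hot_level", lvl))
    for name in _NUMERIC:
        entries.append(FeatureEntry(name, name, "numeric"))
    return tuple(entries)


@dataclass(frozen=True)
class FeatureSchema:
    """The ordered 43-entry feature schema."""

    version: str = SCHEMA_VERSION
    entries: tuple[FeatureEntry, ...] = field(default_factory=_default_entries)

    def __post_init__(self) -> None:
        if len(self.entries) != 43:
            raise ValueError(f"schema must have exactly 43 entries, got {len(self.entries)}")
        names = [e.name for e in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("schema entry names must be unique")

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    def to_json(self) -> dict:
        return {
            "version": self.version,
            "entries": [
                {"name": e.name, "source": e.source, "encoding": e.encoding, "level": e.level}
                for e in self.entries
            ],
        }


@dataclass(frozen=True)
class FeatureVector:
    values: np.ndarray        # length 43, NaN for missing
    missing_mask: np.ndarray  # parallel booleans

    def __post_init__(self) -> None:
        if self.values.shape != (43,) or self.missing_mask.shape != (43,):
            raise ValueError("feature vector must have 43 slots")


def encode(
    candidate: CandidateVariant,
    phen: PhenotypeScores,
    gene: Optional[GeneRecord],
    acmg_auto_class: Optional[str],
    schema: Optional[FeatureSchema] = None,
) -> FeatureVector:
    """Encode one candidate; pure and deterministic.

    External phenotype scores (HPO3/AMELIE/SHEPHERD slots) fall back to the
    built-in similarity when not supplied; genuinely missing numerics
    become NaN with the mask bit set.
    """
    schema = schema or FeatureSchema()
    ann = candidate.annotation
    g = candidate.genotype

    categorical = {
        "inheritance": candidate.inheritance.pattern.value,
        "impact": ann.impact_tier.value,
        "clinvar": ann.clinvar.value,
        "acmg_auto": acmg_auto_class,
    }
    moi = {m.value for m in gene.moi} if gene is not None else set()
    numeric: dict[str, Optional[float]] = {
        "vaf": g.alt_fraction,
        "depth": float(g.depth) if g.depth is not None else None,
        "gnomad_af": ann.gnomad_af,
        "cohort_af": ann.cohort_af,
        "hpo3": phen.hpo3 if phen.hpo3 is not None else phen.similarity,
        "amelie": phen.amelie if phen.amelie is not None else phen.similarity,
        "shepherd": phen.shepherd if phen.shepherd is not None else phen.similarity,
        "hpo_match_count": float(phen.match.exact_count + phen.match.one_level_count),
        "hpo_ic2_count": float(phen.match.ic2_count),
        "cadd_phred": ann.cadd_phred,
        "revel": ann.revel,
        "alphamissense": ann.alphamissense,
        "spliceai": ann.spliceai,
        "misfit_d": ann.misfit_d,
        "s_coef": gene.s_coef if gene is not None else None,
        "s_het": gene.s_het if gene is not None else None,
        "pli": gene.pli if gene is not None else None,
    }

    values = np.empty(43)
    mask = np.zeros(43, dtype=bool)
    for i, entry in enumerate(schema.entries):
        if entry.encoding == "one_hot_level":
            if entry.source not in categorical:
                raise ValueError(f"schema entry {entry.name!r}: unknown source {entry.source!r}")
            values[i] = 1.0 if categorical[entry.source] == entry.level else 0.0
        elif entry.encoding == "binary":
            if entry.source != "gene_moi":
                raise ValueError(f"schema entry {entry.name!r}: unknown source {entry.source!r}")
            values[i] = 1.0 if entry.level in moi else 0.0
        elif entry.encoding == "numeric":
            if entry.source not in numeric:
                raise ValueError(f"schema entry {entry.name!r}: unknown source {entry.source!r}")
            v = numeric[entry.source]
            if v is None:
                values[i] = np.nan
                mask[i] = True
            else:
                values[i] = float(v)
        else:
            raise ValueError(f"schema entry {entry.name!r}: unknown encoding {entry.encoding!r}")
    return FeatureVector(values=values, missing_mask=mask)


@dataclass
class StandardizationParams:
    """Training medians (for NaN imputation) and z-score parameters."""

    median: np.ndarray
    mean: np.ndarray
    sd: np.ndarray


def fit_standardizer(rows: np.ndarray) -> StandardizationParams:
    """Fit per-column medians and population-moment z-score parameters.

    Constant columns record sd 1 so standardization stays invertible.
    """
    rows = np.asarray(rows, dtype=float)
    if rows.ndim != 2 or rows.shape[0] < 2:
        raise ValueError("standardizer needs at least 2 rows")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        median = np.nanmedian(rows, axis=0)
    median = np.where(np.isnan(median), 0.0, median)
    imputed = np.where(np.isnan(rows), median, rows)
    mean = imputed.mean(axis=0)
    sd = imputed.std(axis=0)  # population sd
    sd = np.where(sd <= 0.0, 1.0, sd)
    return StandardizationParams(median=median, mean=mean, sd=sd)


def apply_standardizer(params: StandardizationParams, rows: np.ndarray) -> np.ndarray:
    rows = np.asarray(rows, dtype=float)
    imputed = np.where(np.isnan(rows), params.median, rows)
    return (imputed - params.mean) / params.sd


def invert_standardizer(params: StandardizationParams, rows: np.ndarray) -> np.ndarray:
    return np.asarray(rows, dtype=float) * params.sd + params.mean


POSITIVE_LABELS = ("pathogenic", "likely_pathogenic", "VUS")


@dataclass
class LabeledDataset:
    """Feature rows with labels and proband group keys for leakage-safe
    splitting."""

    X: np.ndarray
    labels: list[str]
    groups: list[str]
    keys: list[str]  # variant keys, parallel to rows

    def __post_init__(self) -> None:
        n = self.X.shape[0]
        if not (len(self.labels) == len(self.groups) == len(self.keys) == n):
            raise ValueError("dataset columns must be parallel")
        bad = set(self.labels) - set(POSITIVE_LABELS) - {"negative"}
        if bad:
            raise ValueError(f"unknown labels: {sorted(bad)}")

    @property
    def y(self) -> np.ndarray:
        return np.array([lbl in POSITIVE_LABELS for lbl in self.labels], dtype=int)

    def subset(self, idx: Sequence[int]) -> "LabeledDataset":
        idx = list(idx)
        return LabeledDataset(
            X=self.X[idx],
            labels=[self.labels[i] for i in idx],
            groups=[self.groups[i] for i in idx],
            keys=[self.keys[i] for i in idx],
        )


def assemble_training_set(
    survivor_rows: Iterable[tuple[str, str, FeatureVector]],
    reported_rows: Iterable[tuple[str, str, str, FeatureVector]],
) -> LabeledDataset:
    """Build the training set from filter survivors and reported variants.

    ``survivor_rows`` are (proband, variant_key, vector) triples for every
    cascade survivor; ``reported_rows`` add (proband, variant_key, label,
    vector) for clinically reported variants.  Reported rows are positives
    with their reported class even when they did not survive the cascade
    (their vectors are supplied explicitly); survivors not reported for the
    same probands are the negatives.
    """
    reported = list(reported_rows)
    reported_keys = {(p, k) for p, k, _, _ in reported}
    X_rows, labels, groups, keys = [], [], [], []
    for proband, key, vec in survivor_rows:
        if (proband, key) in reported_keys:
            continue
        X_rows.append(vec.values)
        labels.append("negative")
        groups.append(proband)
        keys.append(key)
    for proband, key, label, vec in reported:
        X_rows.append(vec.values)
        labels.append(label)
        groups.append(proband)
        keys.append(key)
    if not X_rows:
        raise ValueError("empty training set")
    return LabeledDataset(X=np.vstack(X_rows), labels=labels, groups=groups, keys=keys)
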