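"""The variant-scoring neural network (VS-NN).

A feed-forward network maps the standardized 43-feature encoding to a
pathogenicity score in [0, 1]; candidates scoring >= 0.5 (inclusive) are
flagged for manual review.  Training follows the clinical-reanalysis
protocol: clinically reported P/LP/VUS variants are positives, cascade
survivors absent from reports are negatives, 30% of the data (grouped by
proband, stratified by label) is held out for validation, and after
evaluation the final model is retrained on the full dataset.

Organised as a model/results pair: :class:`VariantScoringModel` is built
from a :class:`~pgr.features.LabeledDataset`; ``fit()`` returns a
:class:`VariantScoringResults` carrying the validation report, the final
retrained network, prediction and feature-contrast methods and a
``summary()`` table.
"""

from __future__ import annotations

import pickle
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.neural_network import MLPClassifier

from . import stats as pgr_stats
from .features import (
    FeatureSchema,
    FeatureVector,
    LabeledDataset,
    StandardizationParams,
    apply_standardizer,
    fit_standardizer,
)

POSITIVE_CLASSES = {"pathogenic", "likely_pathogenic", "VUS"}
PLP_CLASSES = {"pathogenic", "likely_pathogenic"}


@dataclass
class ModelConfig:
    hidden_sizes: tuple[int, ...] = (64, 16)
    activation: str = "relu"
    epochs: int = 200
    batch_size: int = 64
    learning_rate: float = 1e-3
    class_weight: Optional[float] = None  # None: negatives/positives, capped at 20
    seed: int = 0
    threshold: float = 0.5
    validation_fraction: float = 0.30

    def __post_init__(self) -> None:
        if not (0.0 < self.threshold < 1.0):
            raise ValueError("threshold must lie in (0, 1)")


def split_dataset(
    dataset: LabeledDataset, fraction: float = 0.30, seed: int = 0
) -> tuple[LabeledDataset, LabeledDataset]:
    """Grouped, stratified train/validation split.

    No proband's rows straddle the split; probands are stratified by
    whether they contribute positive rows so label proportions carry over.
    Raises when the achieved validation fraction misses the target by more
    than two percentage points.
    """
    rng = np.random.default_rng(seed)
    rows_by_group: dict[str, list[int]] = {}
    for i, g in enumerate(dataset.groups):
        rows_by_group.setdefault(g, []).append(i)
    y = dataset.y
    strata: dict[bool, list[str]] = {True: [], False: []}
    for g, idx in rows_by_group.items():
        strata[bool(y[idx].any())].append(g)

    val_idx: list[int] = []
    for has_pos in (True, False):
        groups = sorted(strata[has_pos])
        rng.shuffle(groups)
        stratum_rows = sum(len(rows_by_group[g]) for g in groups)
        target = fraction * stratum_rows
        taken = 0
        for g in groups:
            size = len(rows_by_group[g])
            # take the group only if it moves the stratum closer to target
            if abs(taken + size - target) <= abs(taken - target):
                val_idx.extend(rows_by_group[g])
                taken += size

    achieved = len(val_idx) / len(dataset.labels)
    if abs(achieved - fraction) > 0.02:
        raise ValueError(
            f"cannot hit validation fraction {fraction:.2f} with these groups "
            f"(achieved {achieved:.3f}); too few probands per stratum"
        )
    val_set = set(val_idx)
    train_idx = [i for i in range(len(dataset.labels)) if i not in val_set]
    return dataset.subset(train_idx), dataset.subset(sorted(val_set))


@dataclass
class TrainedModel:
    """The trained network plus everything needed to reproduce its scores:
    the standardizer fitted on its training rows, the schema version and
    the configuration."""

    net: MLPClassifier
    standardizer: StandardizationParams
    config: ModelConfig
    schema_version: str = "1"

    def predict_scores(self, X: np.ndarray | Sequence[FeatureVector]) -> np.ndarray:
        if not isinstance(X, np.ndarray):
            X = np.vstack([fv.values for fv in X])
        if X.ndim == 1:
            X = X.reshape(1, -1)
        if X.shape[1] != len(self.standardizer.mean):
            raise ValueError(
                f"feature width {X.shape[1]} does not match schema ({len(self.standardizer.mean)})"
            )
        Z = apply_standardizer(self.standardizer, X)
        scores = self.net.predict_proba(Z)[:, 1]
        return np.clip(scores, 0.0, 1.0)

    def flags(self, scores: np.ndarray) -> np.ndarray:
        return scores >= self.config.threshold  # inclusive at the threshold

    def save(self, path: str | Path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @staticmethod
    def load(path: str | Path) -> "TrainedModel":
        with open(path, "rb") as fh:
            return pickle.load(fh)


def _fit_net(X: np.ndarray, y: np.ndarray, config: ModelConfig) -> tuple[MLPClassifier, StandardizationParams]:
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    standardizer = fit_standardizer(X)
    Z = apply_standardizer(standardizer, X)

    # MLPClassifier has no class weighting; replicate positives to an
    # effective weight to counter the ~20:1 negative imbalance.
    weight = config.class_weight
    if weight is None:
        n_pos = int(y.sum())
        weight = min(20.0, (len(y) - n_pos) / max(1, n_pos))
    reps = max(1, int(round(weight)))
    pos_idx = np.flatnonzero(y == 1)
    if reps > 1 and len(pos_idx):
        Z = np.vstack([Z, np.repeat(Z[pos_idx], reps - 1, axis=0)])
        y = np.concatenate([y, np.repeat(y[pos_idx], reps - 1)])

    net = MLPClassifier(
        hidden_layer_sizes=config.hidden_sizes,
        activation=config.activation,
        solver="adam",
        learning_rate_init=config.learning_rate,
        batch_size=min(config.batch_size, len(y)),
        max_iter=config.epochs,
        random_state=config.seed,
        early_stopping=True,
        n_iter_no_change=15,
        validation_fraction=0.1,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # convergence chatter
        net.fit(Z, y)
    return net, standardizer


def train_model(train_set: LabeledDataset, config: Optional[ModelConfig] = None) -> TrainedModel:
    """Train on the given rows only; the standardizer is fitted on the same
    rows (no validation leakage)."""
    config = config or ModelConfig()
    net, standardizer = _fit_net(train_set.X, train_set.y, config)
    return TrainedModel(net=net, standardizer=standardizer, config=config)


def retrain_full(dataset: LabeledDataset, config: Optional[ModelConfig] = None) -> TrainedModel:
    """Retrain on the complete dataset (the production model, built after
    validation metrics are recorded)."""
    return train_model(dataset, config)


@dataclass
class EvaluationReport:
    """Per-class and pooled precision/recall/AUC with confusion counts.

    True positives are reported variants scoring at or above the threshold;
    false negatives are reported variants scoring below it; false positives
    are unreported variants scoring at or above it.
    """

    threshold: float
    metrics: dict[str, dict[str, Optional[float]]]
    confusion: dict[str, dict[str, int]]

    def summary(self) -> str:
        lines = [f"VS-NN evaluation (threshold >= {self.threshold})"]
        header = f"{'class':<8} {'precision':>9} {'recall':>7} {'auc':>7} {'TP':>5} {'FN':>5} {'FP':>5}"
        lines.append(header)
        for cls in ("pooled", "P/LP", "VUS"):
            m, c = self.metrics[cls], self.confusion[cls]
            fmt = lambda v: "   --" if v is None else f"{v:7.3f}"
            lines.append(
                f"{cls:<8} {fmt(m['precision']):>9} {fmt(m['recall']):>7} {fmt(m['auc']):>7} "
                f"{c['TP']:>5} {c['FN']:>5} {c['FP']:>5}"
            )
        return "\n".join(lines)


def _rank_auc(pos_scores: np.ndarray, neg_scores: np.ndarray) -> Optional[float]:
    if len(pos_scores) == 0 or len(neg_scores) == 0:
        return None
    from scipy.stats import rankdata

    allv = np.concatenate([pos_scores, neg_scores])
    ranks = rankdata(allv)
    r_pos = ranks[: len(pos_scores)].sum()
    u = r_pos - len(pos_scores) * (len(pos_scores) + 1) / 2
    return float(u / (len(pos_scores) * len(neg_scores)))


def evaluate_model(
    scores: np.ndarray, labels: Sequence[str], threshold: float = 0.5
) -> EvaluationReport:
    """Evaluate scores against reported-variant labels.

    Classes: ``pooled`` treats any reported class as positive; ``P/LP`` and
    ``VUS`` restrict the positives while sharing the negative pool.
    Precision is reported missing when nothing is called positive; AUC is a
    rank statistic and missing when a class is absent.
    """
    scores = np.asarray(scores, dtype=float)
    labels = list(labels)
    if len(scores) != len(labels):
        raise ValueError("scores and labels must align")
    neg = np.array([l == "negative" for l in labels])
    called = scores >= threshold

    def one(pos_mask: np.ndarray) -> tuple[dict, dict]:
        tp = int(np.sum(pos_mask & called))
        fn = int(np.sum(pos_mask & ~called))
        fp = int(np.sum(neg & called))
        precision = tp / (tp + fp) if (tp + fp) else None
        recall = tp / (tp + fn) if (tp + fn) else None
        auc = _rank_auc(scores[pos_mask], scores[neg])
        return (
            {"precision": precision, "recall": recall, "auc": auc},
            {"TP": tp, "FN": fn, "FP": fp},
        )

    pooled = np.array([l in POSITIVE_CLASSES for l in labels])
    plp = np.array([l in PLP_CLASSES for l in labels])
    vus = np.array([l == "VUS" for l in labels])
    metrics, confusion = {}, {}
    for name, mask in (("pooled", pooled), ("P/LP", plp), ("VUS", vus)):
        metrics[name], confusion[name] = one(mask)
    return EvaluationReport(threshold=threshold, metrics=metrics, confusion=confusion)


def feature_contrast(
    tp_rows: np.ndarray,
    fn_rows: np.ndarray,
    feature_names: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Per-feature two-sided rank-sum contrast between true-positive and
    false-negative rows, Benjamini-Hochberg adjusted, sorted by q.

    ``direction`` is the sign of the TP-minus-FN median shift.  Groups
    smaller than 3 yield an empty table with a warning.
    """
    tp_rows = np.asarray(tp_rows, dtype=float)
    fn_rows = np.asarray(fn_rows, dtype=float)
    if len(tp_rows) == 0 or len(fn_rows) == 0:
        raise ValueError("both groups must be nonempty")
    if len(tp_rows) < 3 or len(fn_rows) < 3:
        warnings.warn("groups smaller than 3: rank-sum tests skipped")
        return pd.DataFrame(columns=["feature", "p", "q", "direction"])
    names = list(feature_names) if feature_names is not None else [
        f"f{i}" for i in range(tp_rows.shape[1])
    ]
    pvals, dirs = [], []
    for j in range(tp_rows.shape[1]):
        a = tp_rows[:, j][~np.isnan(tp_rows[:, j])]
        b = fn_rows[:, j][~np.isnan(fn_rows[:, j])]
        if len(a) < 3 or len(b) < 3 or (len(set(a)) == 1 and set(a) == set(b)):
            pvals.append(1.0)
            dirs.append(0)
            continue
        _, p = pgr_stats.wilcoxon_rank_sum(a, b)
        pvals.append(p)
        dirs.append(int(np.sign(np.median(a) - np.median(b))))
    q = pgr_stats.benjamini_hochberg(pvals)
    df = pd.DataFrame({"feature": names, "p": pvals, "q": q, "direction": dirs})
    return df.sort_values(["q", "p", "feature"], kind="stable").reset_index(drop=True)


@dataclass
class VariantScoringResults:
    """Fit results: validation metrics plus the final full-data model."""

    model: TrainedModel
    validation_report: EvaluationReport
    validation_scores: np.ndarray
    validation_set: LabeledDataset
    config: ModelConfig
    schema: FeatureSchema = field(default_factory=FeatureSchema)

    def predict_scores(self, X) -> np.ndarray:
        return self.model.predict_scores(X)

    def tp_fn_rows(self) -> tuple[np.ndarray, np.ndarray, list[int], list[int]]:
        """Validation rows split into true positives and false negatives."""
        y = self.validation_set.y.astype(bool)
        called = self.validation_scores >= self.config.threshold
        tp_idx = list(np.flatnonzero(y & called))
        fn_idx = list(np.flatnonzero(y & ~called))
        return (
            self.validation_set.X[tp_idx],
            self.validation_set.X[fn_idx],
            tp_idx,
            fn_idx,
        )

    def feature_contrast(self) -> pd.DataFrame:
        tp, fn, _, _ = self.tp_fn_rows()
        return feature_contrast(tp, fn, self.schema.names)

    def summary(self) -> str:
        lines = [
            "Variant scoring model",
            f"  architecture : MLP {self.config.hidden_sizes}, {self.config.activation}",
            f"  training rows: {len(self.validation_set.labels)} validation "
            f"(fraction {self.config.validation_fraction:.0%} of full set)",
            f"  seed         : {self.config.seed}",
            "",
            self.validation_report.summary(),
        ]
        return "\n".join(lines)


class VariantScoringModel:
    """Scoring model over a labeled dataset of encoded candidates.

    ``fit`` performs the full protocol: grouped stratified 30% holdout,
    training with standardization fitted on the training rows only,
    validation metrics at the 0.5 threshold, then a retrain on the complete
    dataset for the production scorer.
    """

    def __init__(self, dataset: LabeledDataset, config: Optional[ModelConfig] = None,
                 schema: Optional[FeatureSchema] = None) -> None:
        self.dataset = dataset
        self.config = config or ModelConfig()
        self.schema = schema or FeatureSchema()

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, feature_columns: Sequence[str],
                       label_column: str = "label", group_column: str = "proband",
                       config: Optional[ModelConfig] = None) -> "VariantScoringModel":
        ds = LabeledDataset(
            X=df[list(feature_columns)].to_numpy(dtype=float),
            labels=df[label_column].tolist(),
            groups=df[group_column].astype(str).tolist(),
            keys=[str(i) for i in df.index],
        )
        return cls(ds, config=config)

    def fit(self) -> VariantScoringResults:
        cfg = self.config
        train_set, val_set = split_dataset(self.dataset, cfg.validation_fraction, cfg.seed)
        interim = train_model(train_set, cfg)
        val_scores = interim.predict_scores(val_set.X)
        report = evaluate_model(val_scores, val_set.labels, cfg.threshold)
        final = retrain_full(self.dataset, cfg)
        return VariantScoringResults(
            model=final,
            validation_report=report,
            validation_scores=val_scores,
            validation_set=val_set,
            config=cfg,
            schema=self.schema,
        )
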