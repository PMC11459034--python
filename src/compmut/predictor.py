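"""Composite-mutation status prediction with a weighted two-model ensemble.

For a designated composite gene, each sample is described by two feature
blocks built from its *significant* co-genes only:

- a binary block — presence/absence of a driver-level event in each co-gene
  (the co-mutation pattern, carrying the complementary relationship);
- a distance block — the genome-normalized distance from each co-gene to the
  composite gene when the event is present, with an absent-event sentinel of
  1.0 (maximally distant), carrying the chromosomal-disruption signal.

Each block trains its own random forest (100 trees, ecosystem defaults
otherwise) on a stratified 2/3 train / 1/3 test split.  The two class
probabilities are combined as 0.75·P(binary model) + 0.25·P(distance model);
the class with the highest weighted score is the predicted label, with exact
ties resolved to the negative (non-composite) class.  Performance is
summarized by the confusion matrix, accuracy, balanced accuracy, precision,
TPR/FPR/specificity, the ROC step curve and its trapezoidal AUC, and a
feature-shuffling robustness sweep over fractions 10%…100%.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split

from .chrom_disruption import normalized_distance
from .composite_caller import extract_driver_events
from .io_formats import Cohort, GenomeLayout, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "ModelConfig",
    "FeatureMatrices",
    "ConfusionMatrix",
    "PerformanceReport",
    "TrainResult",
    "ShuffleReport",
    "SingleClassError",
    "build_feature_matrices",
    "train_model",
    "ensemble_predict",
    "evaluate",
    "train_ensemble",
    "shuffle_robustness",
    "SHUFFLE_FRACTIONS",
]

#: The ten feature-shuffling fractions, 10% to 100%.
SHUFFLE_FRACTIONS: tuple[float, ...] = tuple(round(0.1 * k, 1) for k in range(1, 11))

ABSENT_DISTANCE_SENTINEL = 1.0


class SingleClassError(ValidationError):
    """Labels contain a single class; training or ROC is undefined."""


@dataclass(frozen=True)
class ModelConfig:
    """Training and ensemble configuration.

    ``n_trees`` is pinned at 100; ``train_fraction`` at 2/3; the ensemble
    weights at (0.75, 0.25) for (binary co-mutation model, distance model).
    All other random-forest hyperparameters follow scikit-learn defaults.
    """

    n_trees: int = 100
    train_fraction: float = 2 / 3
    seed: int = 0
    ensemble_weights: tuple[float, float] = (0.75, 0.25)

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValidationError("train_fraction must be in (0, 1)")
        if abs(sum(self.ensemble_weights) - 1.0) > 1e-12:
            raise ValidationError("ensemble weights must sum to 1")

    def hyperparameters(self) -> dict:
        """Effective hyperparameters, for run metadata."""
        rf = RandomForestClassifier(n_estimators=self.n_trees)
        return rf.get_params()


@dataclass
class FeatureMatrices:
    """Binary and distance feature blocks with aligned labels."""

    binary: pd.DataFrame
    distance: pd.DataFrame
    labels: pd.Series  # 1 = composite, 0 = non-composite
    composite_gene: str
    excluded_features: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (
            self.binary.index.equals(self.distance.index)
            and self.binary.index.equals(self.labels.index)
        ):
            raise ValidationError("feature blocks and labels must share sample order")
        if not self.binary.columns.equals(self.distance.columns):
            raise ValidationError("feature blocks must share feature names")


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class PerformanceReport:
    """Classification metrics.

    accuracy = (TP+TN)/total; balanced accuracy = (TPR + specificity)/2;
    precision = TP/(TP+FP); TPR (= recall = sensitivity) = TP/(TP+FN);
    FPR = FP/(TN+FP); specificity = TN/(TN+FP).  The ROC is the step curve
    obtained by sweeping the ensemble score threshold; AUC is its trapezoidal
    integral (equal to the Mann–Whitney concordance probability).
    """

    accuracy: float
    balanced_accuracy: float
    precision: float
    tpr: float
    fpr: float
    specificity: float
    auc: float
    roc_points: pd.DataFrame  # columns fpr, tpr, one row per threshold


@dataclass
class TrainResult:
    """Held-out predictions and performance of a trained ensemble."""

    config: ModelConfig
    test_index: pd.Index
    y_test: pd.Series
    scores: pd.DataFrame  # sample-indexed: p_binary, p_distance, score, predicted
    confusion: ConfusionMatrix
    report: PerformanceReport


@dataclass
class ShuffleReport:
    """Ensemble performance after shuffling growing fractions of features."""

    fractions: tuple[float, ...]
    reports: dict[float, PerformanceReport]
    seed: int


def build_feature_matrices(
    cohort: Cohort,
    calls: pd.DataFrame,
    composite_gene: str,
    co_genes: list[str],
    events: pd.DataFrame | None = None,
    layout: GenomeLayout | None = None,
) -> FeatureMatrices:
    """Build the binary and distance feature blocks for one composite gene.

    Samples are restricted to tumor types that carry at least one composite
    call in ``composite_gene``.  The binary feature is 1 iff the sample has a
    driver-level event in the co-gene; the distance feature is the normalized
    distance from co-gene to composite gene when present, else the sentinel
    1.0.  The composite gene itself is excluded from the feature list (label
    leakage guard), with a log line.
    """
    layout = layout or cohort.layout
    features = [g for g in dict.fromkeys(co_genes)]
    excluded = [g for g in features if g == composite_gene]
    if excluded:
        logger.info(
            "build_feature_matrices: excluded target gene %s from features",
            composite_gene,
        )
        features = [g for g in features if g != composite_gene]
    if not features:
        raise ValidationError("no co-gene features left after exclusions")

    gene_calls = calls[calls["gene"] == composite_gene]
    tt = cohort.tumor_type_of()
    bearing_types = set(tt.reindex(gene_calls["sample_id"]).dropna())
    if not bearing_types:
        raise ValidationError(
            f"no tumor type carries composite calls in {composite_gene!r}"
        )
    sample_ids = pd.Index(
        sorted(s for s in cohort.sample_ids if tt[s] in bearing_types)
    )

    if events is None:
        events = extract_driver_events(cohort)
    presence = set(zip(events["sample_id"], events["gene"]))
    binary = pd.DataFrame(
        [[int((s, g) in presence) for g in features] for s in sample_ids],
        index=sample_ids,
        columns=features,
    )
    dist_of = {
        g: normalized_distance(g, composite_gene, cohort.annotations, layout)
        for g in features
    }
    distance = pd.DataFrame(
        np.where(
            binary.to_numpy(dtype=bool),
            np.array([dist_of[g] for g in features])[None, :],
            ABSENT_DISTANCE_SENTINEL,
        ),
        index=sample_ids,
        columns=features,
    )
    labels = pd.Series(0, index=sample_ids, name="composite")
    labels[labels.index.isin(set(gene_calls["sample_id"]))] = 1
    return FeatureMatrices(
        binary=binary,
        distance=distance,
        labels=labels,
        composite_gene=composite_gene,
        excluded_features=excluded,
    )


def train_model(
    x_train: pd.DataFrame,
    y_train: pd.Series,
    config: ModelConfig,
    seed_offset: int = 0,
) -> RandomForestClassifier:
    """Fit a 100-tree random forest; all other hyperparameters default."""
    if y_train.nunique() < 2:
        raise SingleClassError("training labels contain a single class")
    rf = RandomForestClassifier(
        n_estimators=config.n_trees, random_state=config.seed + seed_offset
    )
    rf.fit(x_train.to_numpy(), y_train.to_numpy())
    return rf


def _proba_positive(model: RandomForestClassifier, x: pd.DataFrame) -> np.ndarray:
    pos = int(np.flatnonzero(model.classes_ == 1)[0])
    return model.predict_proba(x.to_numpy())[:, pos]


def ensemble_predict(
    p_binary: pd.Series | np.ndarray,
    p_distance: pd.Series | np.ndarray,
    config: ModelConfig | None = None,
) -> pd.DataFrame:
    """Weighted-average ensemble of the two models' class probabilities.

    The positive-class score is w₁·p_binary + w₂·p_distance (defaults 0.75 and
    0.25); the negative-class score is its complement.  The predicted label is
    the class with the higher score; an exact tie resolves to the negative
    (non-composite) class.
    """
    config = config or ModelConfig()
    pb = pd.Series(p_binary)
    pdist = pd.Series(p_distance)
    if len(pb) != len(pdist) or not pb.index.equals(pdist.index):
        raise ValidationError("ensemble inputs must cover the same samples")
    if ((pb < 0) | (pb > 1) | (pdist < 0) | (pdist > 1)).any():
        raise ValidationError("probabilities must lie in [0, 1]")
    w1, w2 = config.ensemble_weights
    score = w1 * pb + w2 * pdist
    predicted = (score > 0.5).astype(int)  # tie (score == 0.5) -> negative
    return pd.DataFrame(
        {"p_binary": pb, "p_distance": pdist, "score": score, "predicted": predicted}
    )


def evaluate(
    y_true: pd.Series | np.ndarray,
    scores: pd.Series | np.ndarray,
    predicted: pd.Series | np.ndarray,
) -> tuple[ConfusionMatrix, PerformanceReport]:
    """Confusion matrix, scalar metrics, ROC curve and AUC.

    Scalar metrics come from the predicted labels; the ROC sweeps the score
    threshold over all observed score values, and the AUC is the trapezoidal
    integral of the resulting step curve.
    """
    y = np.asarray(y_true, dtype=int)
    s = np.asarray(scores, dtype=float)
    yhat = np.asarray(predicted, dtype=int)
    if not (len(y) == len(s) == len(yhat)):
        raise ValidationError("labels, scores and predictions must align")
    n_pos, n_neg = int((y == 1).sum()), int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise SingleClassError("ROC undefined: need both classes in test labels")

    tp = int(((y == 1) & (yhat == 1)).sum())
    fp = int(((y == 0) & (yhat == 1)).sum())
    tn = int(((y == 0) & (yhat == 0)).sum())
    fn = int(((y == 1) & (yhat == 0)).sum())
    cm = ConfusionMatrix(tp=tp, fp=fp, tn=tn, fn=fn)

    accuracy = (tp + tn) / cm.total
    tpr = tp / (tp + fn)
    specificity = tn / (tn + fp)
    fpr = fp / (tn + fp)
    balanced = (tpr + specificity) / 2
    precision = tp / (tp + fp) if (tp + fp) else float("nan")

    # ROC: predict positive when score >= threshold, threshold descending
    thresholds = np.unique(s)[::-1]
    roc_fpr = [0.0]
    roc_tpr = [0.0]
    for t in thresholds:
        pos = s >= t
        roc_tpr.append(float((pos & (y == 1)).sum() / n_pos))
        roc_fpr.append(float((pos & (y == 0)).sum() / n_neg))
    roc = pd.DataFrame({"fpr": roc_fpr, "tpr": roc_tpr})
    auc = float(np.trapezoid(roc["tpr"], roc["fpr"]))

    report = PerformanceReport(
        accuracy=float(accuracy),
        balanced_accuracy=float(balanced),
        precision=float(precision),
        tpr=float(tpr),
        fpr=float(fpr),
        specificity=float(specificity),
        auc=auc,
        roc_points=roc,
    )
    return cm, report


def _stratified_split(
    labels: pd.Series, config: ModelConfig
) -> tuple[pd.Index, pd.Index]:
    if labels.nunique() < 2:
        raise SingleClassError("labels contain a single class; cannot split")
    train_idx, test_idx = train_test_split(
        labels.index,
        test_size=1 - config.train_fraction,
        stratify=labels,
        random_state=config.seed,
    )
    return pd.Index(sorted(train_idx)), pd.Index(sorted(test_idx))


def train_ensemble(features: FeatureMatrices, config: ModelConfig) -> TrainResult:
    """Train both random forests on one stratified split and evaluate the
    weighted ensemble on the held-out third."""
    train_idx, test_idx = _stratified_split(features.labels, config)
    y_train = features.labels.loc[train_idx]
    y_test = features.labels.loc[test_idx]

    rf_binary = train_model(features.binary.loc[train_idx], y_train, config)
    rf_distance = train_model(
        features.distance.loc[train_idx], y_train, config, seed_offset=1
    )
    p_binary = pd.Series(
        _proba_positive(rf_binary, features.binary.loc[test_idx]), index=test_idx
    )
    p_distance = pd.Series(
        _proba_positive(rf_distance, features.distance.loc[test_idx]), index=test_idx
    )
    scores = ensemble_predict(p_binary, p_distance, config)
    cm, report = evaluate(y_test, scores["score"], scores["predicted"])
    return TrainResult(
        config=config,
        test_index=test_idx,
        y_test=y_test,
        scores=scores,
        confusion=cm,
        report=report,
    )


def _shuffle_columns(
    matrix: pd.DataFrame, fraction: float, rng: np.random.Generator
) -> pd.DataFrame:
    """Permute a uniformly chosen ``fraction`` of columns, each independently
    across samples."""
    n_cols = matrix.shape[1]
    k = int(round(fraction * n_cols))
    if k == 0:
        return matrix.copy()
    chosen = rng.choice(n_cols, size=k, replace=False)
    out = matrix.copy()
    for j in chosen:
        out.iloc[:, j] = rng.permutation(out.iloc[:, j].to_numpy())
    return out


def shuffle_robustness(
    features: FeatureMatrices,
    config: ModelConfig,
    fractions: tuple[float, ...] = SHUFFLE_FRACTIONS,
) -> ShuffleReport:
    """Retrain and re-evaluate the ensemble after shuffling 10%…100% of
    feature columns (independently per block and per column), reporting the
    performance at each fraction."""
    reports: dict[float, PerformanceReport] = {}
    for step, fraction in enumerate(fractions):
        rng = np.random.default_rng([config.seed, step])
        shuffled = FeatureMatrices(
            binary=_shuffle_columns(features.binary, fraction, rng),
            distance=_shuffle_columns(features.distance, fraction, rng),
            labels=features.labels,
            composite_gene=features.composite_gene,
        )
        reports[fraction] = train_ensemble(shuffled, config).report
    return ShuffleReport(fractions=tuple(fractions), reports=reports, seed=config.seed)
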