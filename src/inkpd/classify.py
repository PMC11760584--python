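"""eCOA-tuned AdaBoost per feature family, adaptive weighted fusion, metrics.

Each feature family (kinematic, pressure, angle, moment) gets its own
boosted classifier, tuned by the escape Coati Optimization Algorithm over
the four AdaBoost hyperparameters (tree depth d in [1, 30], minimum split
fraction m in [e^-4, 1], number of estimators n in [1, 100], learning rate
r in [e^-6, 10]); the objective is 1 minus the stratified 3-fold inner-CV
accuracy on the training rows. Family class-probability vectors are then
combined by adaptive weighted fusion: for sample i the weight of family k
is n_i^c / N_k where n_i^c counts the families whose predicted class
agrees with family k's and N_k is the number of families; the fused
probability is the weighted sum and the prediction its argmax. The outer
evaluation is a stratified 5-fold cross-validation in which selection,
tuning and training all see only the training fold.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from . import ecoa
from .boosting import SammeAdaBoost
from .features import FeatureTable
from .selection import rf_select

__all__ = [
    "AdaBoostParams",
    "FamilyPrediction",
    "FusionResult",
    "MetricsReport",
    "PipelineConfig",
    "default_search_space",
    "tune_adaboost",
    "train_family",
    "fuse_predictions",
    "compute_metrics",
    "run_cv",
]


@dataclasses.dataclass(frozen=True)
class AdaBoostParams:
    """The four tuned AdaBoost hyperparameters, each within its search box."""

    max_depth: int
    min_samples_split: float
    n_estimators: int
    learning_rate: float

    RANGES = {
        "max_depth": (1, 30),
        "min_samples_split": (math.exp(-4), 1.0),
        "n_estimators": (1, 100),
        "learning_rate": (math.exp(-6), 10.0),
    }

    def __post_init__(self) -> None:
        for field, (lo, hi) in self.RANGES.items():
            v = getattr(self, field)
            if not lo <= v <= hi:
                raise ValueError(f"{field}={v} outside [{lo}, {hi}]")

    def build(self) -> SammeAdaBoost:
        return SammeAdaBoost(self.max_depth, self.min_samples_split,
                             self.n_estimators, self.learning_rate)


def default_search_space() -> ecoa.SearchSpace:
    r = AdaBoostParams.RANGES
    return ecoa.SearchSpace(
        lower=np.array([r["max_depth"][0], r["min_samples_split"][0],
                        r["n_estimators"][0], r["learning_rate"][0]]),
        upper=np.array([r["max_depth"][1], r["min_samples_split"][1],
                        r["n_estimators"][1], r["learning_rate"][1]]),
        integer=np.array([True, False, True, False]),
    )


@dataclasses.dataclass
class FamilyPrediction:
    """Per-sample class probabilities and argmax classes of one family."""

    family: str
    classes: np.ndarray
    proba: np.ndarray  # (n_samples, n_classes)

    def __post_init__(self) -> None:
        if np.any(self.proba < -1e-9):
            raise ValueError("probabilities must be non-negative")
        if not np.allclose(self.proba.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("probability rows must sum to 1")

    @property
    def predicted(self) -> np.ndarray:
        return np.argmax(self.proba, axis=1)


@dataclasses.dataclass
class FusionResult:
    classes: np.ndarray
    weights: np.ndarray  # (n_samples, n_families)
    proba: np.ndarray  # fused scores (n_samples, n_classes); unnormalised
    predicted: np.ndarray  # class codes (argmax of proba)


@dataclasses.dataclass
class MetricsReport:
    accuracy: float
    sensitivity: float
    specificity: float
    auc: float
    per_class: pd.DataFrame
    confusion: np.ndarray
    per_fold: pd.DataFrame | None = None

    def as_dict(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "auc": self.auc,
        }


def _inner_cv_accuracy(X: np.ndarray, y: np.ndarray, params: AdaBoostParams,
                       folds: list[tuple[np.ndarray, np.ndarray]]) -> float:
    correct = 0
    for tr, te in folds:
        clf = params.build().fit(X[tr], y[tr])
        correct += int(np.sum(clf.predict(X[te]) == y[te]))
    return correct / len(y)


def tune_adaboost(
    features: np.ndarray,
    labels: np.ndarray,
    space: ecoa.SearchSpace | None = None,
    n_coatis: int = 50,
    n_iterations: int = 10,
    inner_folds: int = 3,
    seed: int = 0,
) -> tuple[AdaBoostParams, float]:
    """eCOA search over the AdaBoost hyperparameter box.

    Minimises 1 minus the stratified ``inner_folds``-fold CV accuracy on
    the given rows. Returns the best parameters and the best inner-CV
    accuracy found.
    """
    X = np.ascontiguousarray(features, dtype=np.float32)
    y = np.asarray(labels)
    classes, y_codes = np.unique(y, return_inverse=True)
    if len(classes) < 2:
        raise ValueError("need at least two classes to tune")
    space = space or default_search_space()
    skf = StratifiedKFold(inner_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(X, y_codes))

    def objective(x: np.ndarray) -> float:
        params = AdaBoostParams(int(x[0]), float(x[1]), int(x[2]), float(x[3]))
        return 1.0 - _inner_cv_accuracy(X, y_codes, params, folds)

    result = ecoa.minimize(objective, space, n_coatis=n_coatis,
                           n_iterations=n_iterations, seed=seed)
    b = result.best_position
    params = AdaBoostParams(int(b[0]), float(b[1]), int(b[2]), float(b[3]))
    return params, 1.0 - result.best_fitness


def train_family(
    features: np.ndarray, labels: np.ndarray, params: AdaBoostParams
) -> SammeAdaBoost:
    """Fit the boosted ensemble of one family with tuned hyperparameters."""
    return params.build().fit(np.asarray(features, dtype=np.float32),
                              np.asarray(labels))


def predict_family(
    model: SammeAdaBoost, features: np.ndarray, family: str
) -> FamilyPrediction:
    return FamilyPrediction(family=family, classes=model.classes_,
                            proba=model.predict_proba(features))


def fuse_predictions(
    family_preds: Sequence[FamilyPrediction], normalize: bool = False
) -> FusionResult:
    """Adaptive weighted fusion of per-family probability vectors.

    For each sample i and family k the weight is n_i^c / N_k with n_i^c the
    number of families predicting the same class as family k. Weights are
    used unnormalised by default; ``normalize`` divides by their sum, which
    rescales the fused vector without moving the argmax.
    """
    if not family_preds:
        raise ValueError("need at least one family prediction")
    classes = family_preds[0].classes
    n = family_preds[0].proba.shape[0]
    for fp in family_preds:
        if fp.proba.shape != (n, len(classes)) or not np.array_equal(
                fp.classes, classes):
            raise ValueError("family predictions must cover identical "
                             "samples and classes")
    n_k = len(family_preds)
    pred = np.stack([fp.predicted for fp in family_preds], axis=1)  # (n, K)
    # n_i^c per family: how many families agree with this family's class
    agree = (pred[:, :, None] == pred[:, None, :]).sum(axis=2)
    weights = agree / n_k
    if normalize:
        weights = weights / weights.sum(axis=1, keepdims=True)
    proba = np.einsum("ik,ikc->ic", weights,
                      np.stack([fp.proba for fp in family_preds], axis=1))
    return FusionResult(classes=classes, weights=weights, proba=proba,
                        predicted=np.argmax(proba, axis=1))


def _ovr_counts(y_true: np.ndarray, y_pred: np.ndarray, cls: int
                ) -> tuple[int, int, int, int]:
    tp = int(np.sum((y_pred == cls) & (y_true == cls)))
    fp = int(np.sum((y_pred == cls) & (y_true != cls)))
    fn = int(np.sum((y_pred != cls) & (y_true == cls)))
    tn = int(np.sum((y_pred != cls) & (y_true != cls)))
    return tp, fp, tn, fn


def compute_metrics(
    y_true: np.ndarray,
    fused: FusionResult,
    per_fold: pd.DataFrame | None = None,
) -> MetricsReport:
    """Accuracy, macro sensitivity/specificity, and (one-vs-one) AUC.

    ``y_true`` holds class codes aligned with ``fused.classes``. With two
    classes the positive class is the last one in ``fused.classes`` (PD
    when labels are HC/PD); with three or more, sensitivity and
    specificity are macro-averaged over one-vs-rest classes and the AUC is
    the macro one-vs-one average.
    """
    y_true = np.asarray(y_true)
    y_pred = fused.predicted
    n_classes = len(fused.classes)
    acc = float(np.mean(y_pred == y_true))
    rows = []
    for c in range(n_classes):
        if not np.any(y_true == c):
            warnings.warn(f"class {fused.classes[c]!r} absent from y_true; "
                          "skipping its sensitivity")
            continue
        tp, fp, tn, fn = _ovr_counts(y_true, y_pred, c)
        sen = tp / (tp + fn)
        spe = tn / (tn + fp) if tn + fp else float("nan")
        rows.append({"class": fused.classes[c], "TP": tp, "FP": fp,
                     "TN": tn, "FN": fn, "sensitivity": sen,
                     "specificity": spe})
    per_class = pd.DataFrame(rows)
    if n_classes == 2:
        sen = float(per_class.iloc[-1]["sensitivity"])
        spe = float(per_class.iloc[-1]["specificity"])
        scores = fused.proba / fused.proba.sum(axis=1, keepdims=True)
        auc = float(roc_auc_score(y_true, scores[:, 1]))
    else:
        sen = float(per_class["sensitivity"].mean())
        spe = float(per_class["specificity"].mean())
        scores = fused.proba / fused.proba.sum(axis=1, keepdims=True)
        auc = float(roc_auc_score(y_true, scores, multi_class="ovo",
                                  average="macro", labels=np.arange(n_classes)))
    confusion = np.zeros((n_classes, n_classes), dtype=int)
    for yt, yp in zip(y_true, y_pred):
        confusion[yt, yp] += 1
    return MetricsReport(accuracy=acc, sensitivity=sen, specificity=spe,
                         auc=auc, per_class=per_class, confusion=confusion,
                         per_fold=per_fold)


@dataclasses.dataclass(frozen=True)
class PipelineConfig:
    """Everything the cross-validated pipeline needs, seeded from one root."""

    n_outer_folds: int = 5
    n_inner_folds: int = 3
    top_k: int = 30
    rf_trees: int = 500
    n_coatis: int = 50
    n_iterations: int = 10
    normalize_fusion: bool = False
    seed: int = 0


@dataclasses.dataclass
class CvArtifacts:
    """Per-fold bookkeeping of the cross-validated run."""

    selected: dict[tuple[int, str], list[str]]
    params: dict[tuple[int, str], AdaBoostParams]
    inner_accuracy: dict[tuple[int, str], float]
    fold_rows: dict[int, pd.Index]


def run_cv(
    table: FeatureTable,
    labels: pd.Series | np.ndarray | None = None,
    config: PipelineConfig = PipelineConfig(),
) -> tuple[MetricsReport, CvArtifacts]:
    """Stratified outer CV of the full per-family pipeline.

    Within each training fold and per family: random-forest top-k feature
    selection, eCOA hyperparameter tuning, AdaBoost training; the test-fold
    family probabilities are fused and predictions pooled over folds before
    the metrics are computed.
    """
    y_raw = np.asarray(table.labels if labels is None else labels)
    if any(v is None for v in y_raw):
        raise ValueError("every recording needs a class label")
    classes, y = np.unique(y_raw, return_inverse=True)
    counts = np.bincount(y)
    if counts.min() < config.n_outer_folds:
        raise ValueError("need at least n_outer_folds samples per class")
    families = table.family_tags
    skf = StratifiedKFold(config.n_outer_folds, shuffle=True,
                          random_state=config.seed)
    n = len(y)
    fused_proba = np.zeros((n, len(classes)))
    fused_pred = np.full(n, -1)
    fused_weights = np.zeros((n, len(families)))
    art = CvArtifacts({}, {}, {}, {})
    fold_metrics = []
    for fold, (tr, te) in enumerate(skf.split(table.data, y)):
        tr_index = table.data.index[tr]
        family_preds = []
        for fi, family in enumerate(families):
            sel = rf_select(table, y_raw, family, k=config.top_k,
                            seed=config.seed + fold,
                            n_trees=config.rf_trees, train_index=tr_index)
            X = sel.transform(table).to_numpy()
            params, inner_acc = tune_adaboost(
                X[tr], y[tr], n_coatis=config.n_coatis,
                n_iterations=config.n_iterations,
                inner_folds=config.n_inner_folds,
                seed=config.seed + 1000 * fold + fi,
            )
            model = train_family(X[tr], y[tr], params)
            family_preds.append(predict_family(model, X[te], family))
            key = (fold, family)
            art.selected[key] = sel.features
            art.params[key] = params
            art.inner_accuracy[key] = inner_acc
        fusion = fuse_predictions(family_preds,
                                  normalize=config.normalize_fusion)
        fused_proba[te] = fusion.proba
        fused_pred[te] = fusion.predicted
        fused_weights[te] = fusion.weights
        art.fold_rows[fold] = table.data.index[te]
        fold_metrics.append({
            "fold": fold,
            "accuracy": float(np.mean(fusion.predicted == y[te])),
            "n_test": len(te),
        })
    pooled = FusionResult(classes=classes, weights=fused_weights,
                          proba=fused_proba, predicted=fused_pred)
    report = compute_metrics(y, pooled, per_fold=pd.DataFrame(fold_metrics))
    return report, art
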