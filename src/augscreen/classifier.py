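"""Boosted-tree activity classifier: splitting, grid-searched CV training,
probability prediction and ROC/accuracy evaluation.

The learner is an XGBoost gradient-boosted decision-tree ensemble trained on
the concatenated MACCS | ECFP | descriptor feature matrix.  Hyperparameters
are chosen by grid search with stratified k-fold cross-validation scored by
recall (the screening priority is not missing true activators); ties are
broken by higher CV accuracy, then by smaller ensemble.  Label convention:
1 = activator, 0 = inactive/decoy.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.model_selection import ParameterGrid, StratifiedKFold, cross_validate, train_test_split
from sklearn.preprocessing import StandardScaler
from xgboost import XGBClassifier

from .augmentation import LabeledDataset
from .chem_core import FeatureMatrix, Molecule, build_feature_matrix, featurize

DEFAULT_GRID: dict[str, list] = {
    "n_estimators": [100, 300, 600],
    "max_depth": [3, 5, 7],
    "learning_rate": [0.05, 0.1, 0.3],
    "subsample": [0.8, 1.0],
}

# compact grid for routine benchmarking; same search semantics
SMALL_GRID: dict[str, list] = {
    "n_estimators": [100, 300],
    "max_depth": [3, 5],
    "learning_rate": [0.1],
    "subsample": [1.0],
}


class UnfittedClassifierError(RuntimeError):
    pass


@dataclass
class SplitConfig:
    train_fraction: float = 0.75
    stratified: bool = True
    random_state: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.train_fraction < 1):
            raise ValueError("train_fraction must lie in (0, 1)")


def stratified_split(ds: LabeledDataset, cfg: SplitConfig | None = None) -> tuple[LabeledDataset, LabeledDataset]:
    """Split a labeled dataset into disjoint, exhaustive train/test subsets.

    With ``stratified=True`` per-class proportions are preserved within
    rounding.  Sizes follow scikit-learn's convention: the test set gets
    ``ceil(n * (1 - train_fraction))`` rows.
    """
    cfg = cfg or SplitConfig()
    classes = np.unique(ds.labels)
    if len(classes) < 2:
        raise ValueError("stratified split requires both classes present")
    idx = np.arange(len(ds))
    train_idx, test_idx = train_test_split(
        idx,
        train_size=cfg.train_fraction,
        stratify=ds.labels if cfg.stratified else None,
        random_state=cfg.random_state,
        shuffle=True,
    )
    return ds.subset(sorted(train_idx)), ds.subset(sorted(test_idx))


@dataclass
class TrainedClassifier:
    """A fitted ensemble plus the scaler and search record needed to reuse it."""

    model: XGBClassifier
    scaler: StandardScaler
    ecfp_nbits: int
    best_params: dict
    grid: dict
    cv_results: list[dict]  # one record per grid point: params, mean/sd recall, mean accuracy
    fold_recall: list[float]  # per-fold recall of the winning grid point
    cv_accuracy_mean: float
    cv_accuracy_sd: float
    scoring: str = "recall"
    random_state: int = 0

    def save(self, path: str | Path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @staticmethod
    def load(path: str | Path) -> "TrainedClassifier":
        with open(path, "rb") as fh:
            obj = pickle.load(fh)
        if not isinstance(obj, TrainedClassifier):
            raise TypeError(f"{path} does not contain a TrainedClassifier")
        return obj


def _make_model(params: dict, random_state: int) -> XGBClassifier:
    return XGBClassifier(
        tree_method="hist",
        random_state=random_state,
        n_jobs=1,
        eval_metric="logloss",
        **params,
    )


def train(
    train_ds: LabeledDataset,
    grid: dict[str, list] | None = None,
    cv_folds: int = 10,
    random_state: int = 0,
    ecfp_nbits: int = 2048,
) -> TrainedClassifier:
    """Grid-search + k-fold CV training of the boosted-tree classifier.

    The best grid point maximizes mean CV recall; ties are broken by higher
    mean CV accuracy, then by smaller ``n_estimators``.  The returned object
    carries per-fold recall of the winner and the mean/SD of its CV accuracy.
    """
    grid = grid if grid is not None else DEFAULT_GRID
    if not grid:
        raise ValueError("empty hyperparameter grid")
    points = list(ParameterGrid(grid))
    if not points:
        raise ValueError("empty hyperparameter grid")
    counts = np.bincount(train_ds.labels, minlength=2)
    if counts.min() < cv_folds:
        raise ValueError(f"need >= {cv_folds} rows per class for {cv_folds}-fold CV (have {counts.tolist()})")

    fm = build_feature_matrix(train_ds.molecules, scaler=None, ecfp_nbits=ecfp_nbits)
    X, y = fm.X, train_ds.labels
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=random_state)

    records = []
    for params in points:
        model = _make_model(params, random_state)
        cv = cross_validate(model, X, y, cv=skf, scoring=("recall", "accuracy"), n_jobs=1)
        rec, acc = cv["test_recall"], cv["test_accuracy"]
        records.append(
            {
                "params": params,
                "mean_recall": float(rec.mean()),
                "sd_recall": float(rec.std()),
                "fold_recall": rec.tolist(),
                "mean_accuracy": float(acc.mean()),
                "sd_accuracy": float(acc.std()),
            }
        )

    def sort_key(r: dict):
        return (-r["mean_recall"], -r["mean_accuracy"], r["params"].get("n_estimators", 0))

    best = min(records, key=sort_key)
    final = _make_model(best["params"], random_state)
    final.fit(X, y)
    return TrainedClassifier(
        model=final,
        scaler=fm.scaler,
        ecfp_nbits=ecfp_nbits,
        best_params=best["params"],
        grid=grid,
        cv_results=records,
        fold_recall=best["fold_recall"],
        cv_accuracy_mean=best["mean_accuracy"],
        cv_accuracy_sd=best["sd_accuracy"],
        random_state=random_state,
    )


def predict_probability(clf: TrainedClassifier, mols: Sequence[Molecule]) -> list[tuple[str, float]]:
    """Class-1 (activator) probability per molecule, order-preserving."""
    if clf is None or getattr(clf, "model", None) is None:
        raise UnfittedClassifierError("classifier is not fitted")
    if len(mols) == 0:
        return []
    raw = featurize(mols, ecfp_nbits=clf.ecfp_nbits)
    X = clf.scaler.transform(raw)
    p = clf.model.predict_proba(X)[:, 1]
    return [(m.id, float(pi)) for m, pi in zip(mols, p)]


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

@dataclass
class EvaluationReport:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    accuracy: float
    tn: int
    fp: int
    fn: int
    tp: int
    threshold: float = 0.5
    cv_accuracy_mean: float | None = None
    cv_accuracy_sd: float | None = None

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "accuracy": self.accuracy,
            "tn": self.tn,
            "fp": self.fp,
            "fn": self.fn,
            "tp": self.tp,
            "threshold": self.threshold,
            "cv_accuracy_mean": self.cv_accuracy_mean,
            "cv_accuracy_sd": self.cv_accuracy_sd,
        }


def confusion_accuracy(tn: int, fn: int, fp: int, tp: int) -> float:
    """Accuracy (TP+TN)/(TP+TN+FP+FN) from confusion counts."""
    total = tn + fn + fp + tp
    if total == 0:
        raise ValueError("empty confusion table")
    return (tp + tn) / total


def roc_points(labels: np.ndarray, scores: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """ROC curve (FPR, TPR, thresholds) over all score thresholds."""
    from sklearn.metrics import roc_curve

    fpr, tpr, thr = roc_curve(labels, scores)
    return fpr, tpr, thr


def roc_auc(labels: np.ndarray, scores: np.ndarray) -> float:
    """Area under the ROC curve by trapezoidal integration."""
    fpr, tpr, _ = roc_points(np.asarray(labels), np.asarray(scores))
    return float(np.trapezoid(tpr, fpr))


def evaluate(clf: TrainedClassifier, test_ds: LabeledDataset, threshold: float = 0.5) -> EvaluationReport:
    """Confusion counts at ``threshold``, accuracy, and trapezoidal ROC AUC."""
    labels = test_ds.labels
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC undefined: test set contains a single class")
    scores = np.array([p for _, p in predict_probability(clf, test_ds.molecules)])
    pred = (scores >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (labels == 1)))
    tn = int(np.sum((pred == 0) & (labels == 0)))
    fp = int(np.sum((pred == 1) & (labels == 0)))
    fn = int(np.sum((pred == 0) & (labels == 1)))
    fpr, tpr, thr = roc_points(labels, scores)
    return EvaluationReport(
        fpr=fpr,
        tpr=tpr,
        thresholds=thr,
        auc=float(np.trapezoid(tpr, fpr)),
        accuracy=confusion_accuracy(tn, fn, fp, tp),
        tn=tn,
        fp=fp,
        fn=fn,
        tp=tp,
        threshold=threshold,
        cv_accuracy_mean=clf.cv_accuracy_mean,
        cv_accuracy_sd=clf.cv_accuracy_sd,
    )
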