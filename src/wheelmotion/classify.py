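"""Model selection, evaluation and feature importance for propulsion type.

The benchmark mirrors a standard tabular-classification protocol: a
stratified 80/20 split (strata = target x diagnosis), model selection among
five classifier families (logistic regression, SVM, random forest, Gaussian
naive Bayes, gradient-boosted trees) by mean F1 over stratified 10-fold
cross-validation on the training set, refit of the winner on the full
training set, and held-out evaluation.  The whole procedure is repeated
over independent random splits (default 25) and metrics averaged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from xgboost import XGBClassifier

from .features import FeatureMatrix

MODEL_FAMILIES = ("logistic_regression", "svm", "random_forest", "naive_bayes", "xgboost")

__all__ = [
    "MODEL_FAMILIES",
    "ConfusionCounts",
    "EvaluationReport",
    "ImportanceTable",
    "stratified_split",
    "make_classifier",
    "select_model",
    "evaluate_metrics",
    "confusion_from_predictions",
    "run_benchmark",
    "feature_importance",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion counts with active (=1) as the positive class."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class SplitResult:
    family: str
    cv_f1: float
    counts: ConfusionCounts
    accuracy: float
    precision: float
    recall: float
    f1: float


@dataclass
class EvaluationReport:
    """Per-split and averaged test-set metrics for one model variant."""

    variant: str
    n_splits: int
    splits: list[SplitResult]
    mean_accuracy: float
    mean_precision: float
    mean_recall: float
    mean_f1: float
    retained_columns: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "variant": self.variant,
            "n_splits": self.n_splits,
            "mean_accuracy": self.mean_accuracy,
            "mean_precision": self.mean_precision,
            "mean_recall": self.mean_recall,
            "mean_f1": self.mean_f1,
            "splits": [
                {
                    "family": s.family,
                    "cv_f1": s.cv_f1,
                    "accuracy": s.accuracy,
                    "precision": s.precision,
                    "recall": s.recall,
                    "f1": s.f1,
                    "confusion": {
                        "tp": s.counts.tp,
                        "tn": s.counts.tn,
                        "fp": s.counts.fp,
                        "fn": s.counts.fn,
                    },
                }
                for s in self.splits
            ],
            "retained_columns": list(self.retained_columns),
        }


@dataclass
class ImportanceTable:
    """Normalized gain importances (sum 1), with the sign of corr(x, y)."""

    rows: list[tuple[str, float, str]]  # (predictor, score, "+"/"-")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=["predictor", "importance", "correlation_sign"])


def stratified_split(
    fm: FeatureMatrix, test_fraction: float = 0.2, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Deterministic stratified split on (label, diagnosis) strata.

    Each stratum contributes round(n * test_fraction) rows (at least 1) to
    the test set.  Raises if any stratum has fewer than 2 rows.
    """
    rng = np.random.default_rng(seed)
    df = fm.data
    test_idx: list[np.ndarray] = []
    for (label, diag), grp in df.groupby(["y", "diagnosis"], sort=True):
        n = len(grp)
        if n < 2:
            raise ValueError(f"stratum (y={label}, diagnosis={diag}) has {n} row(s); need >= 2")
        n_test = max(1, int(round(n * test_fraction)))
        chosen = rng.choice(grp.index.to_numpy(), size=n_test, replace=False)
        test_idx.append(np.sort(chosen))
    test_index = np.concatenate(test_idx)
    test = df.loc[np.sort(test_index)]
    train = df.drop(index=test_index)
    return train, test


def make_classifier(family: str, seed: int = 0):
    """Instantiate one of the five classifier families at library defaults."""
    if family == "logistic_regression":
        return Pipeline(
            [("scale", StandardScaler()), ("clf", LogisticRegression(max_iter=2000))]
        )
    if family == "svm":
        return Pipeline([("scale", StandardScaler()), ("clf", SVC(random_state=seed))])
    if family == "random_forest":
        return RandomForestClassifier(random_state=seed, n_jobs=1)
    if family == "naive_bayes":
        return GaussianNB()
    if family == "xgboost":
        return XGBClassifier(random_state=seed, n_jobs=1, verbosity=0)
    raise ValueError(f"unknown model family {family!r}")


def _f1_binary(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    counts = confusion_from_predictions(y_true, y_pred)
    return evaluate_metrics(counts)[3]


def select_model(
    train: pd.DataFrame,
    columns: list[str],
    seed: int = 0,
    n_folds: int = 10,
) -> tuple[object, str, float]:
    """Pick the best family by mean F1 over stratified k-fold CV; refit on all.

    Returns ``(fitted_model, family_name, cv_f1)``.  Ties break toward the
    earlier family in :data:`MODEL_FAMILIES` for determinism.
    """
    X = train[columns].to_numpy(dtype=float)
    y = train["y"].to_numpy(dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training data contains a single class")
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = list(cv.split(X, y))
    best_family, best_score = None, -np.inf
    for family in MODEL_FAMILIES:
        scores = []
        for tr, va in folds:
            model = make_classifier(family, seed=seed)
            model.fit(X[tr], y[tr])
            scores.append(_f1_binary(y[va], model.predict(X[va])))
        score = float(np.mean(scores))
        if score > best_score:
            best_family, best_score = family, score
    final = make_classifier(best_family, seed=seed)
    final.fit(X, y)
    return final, best_family, best_score


def confusion_from_predictions(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    return ConfusionCounts(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


def evaluate_metrics(counts: ConfusionCounts) -> tuple[float, float, float, float]:
    """(accuracy, precision, recall, F1); zero-denominator ratios are 0."""
    if counts.total == 0:
        raise ValueError("cannot evaluate metrics on zero counts")
    accuracy = (counts.tp + counts.tn) / counts.total
    precision = counts.tp / (counts.tp + counts.fp) if counts.tp + counts.fp else 0.0
    recall = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else 0.0
    f1 = (
        2.0 * precision * recall / (precision + recall) if precision + recall else 0.0
    )
    return accuracy, precision, recall, f1


def run_benchmark(
    fm: FeatureMatrix,
    columns: list[str] | None = None,
    n_splits: int = 25,
    seed: int = 0,
    test_fraction: float = 0.2,
    n_folds: int = 10,
) -> EvaluationReport:
    """Repeated split -> select -> evaluate; averaged metrics across splits.

    ``columns`` defaults to the correlation-pruned predictor set computed on
    the full matrix before splitting.
    """
    from .features import prune_correlated

    if columns is None:
        columns = prune_correlated(fm)
    split_seeds = np.random.SeedSequence(seed).generate_state(n_splits) % (2**31)
    results = []
    for s in split_seeds:
        train, test = stratified_split(fm, test_fraction=test_fraction, seed=int(s))
        model, family, cv_f1 = select_model(train, columns, seed=int(s), n_folds=n_folds)
        y_pred = model.predict(test[columns].to_numpy(dtype=float))
        counts = confusion_from_predictions(test["y"].to_numpy(dtype=int), y_pred)
        acc, prec, rec, f1 = evaluate_metrics(counts)
        results.append(SplitResult(family, cv_f1, counts, acc, prec, rec, f1))
    return EvaluationReport(
        variant=fm.variant,
        n_splits=n_splits,
        splits=results,
        mean_accuracy=float(np.mean([r.accuracy for r in results])),
        mean_precision=float(np.mean([r.precision for r in results])),
        mean_recall=float(np.mean([r.recall for r in results])),
        mean_f1=float(np.mean([r.f1 for r in results])),
        retained_columns=list(columns),
    )


def feature_importance(
    fm: FeatureMatrix, columns: list[str] | None = None, seed: int = 0
) -> ImportanceTable:
    """Gain-based importances of a boosted-tree model fit on all the data.

    Scores are normalized to sum to 1 and each predictor is annotated with
    the sign of its Pearson correlation with the target.
    """
    from .features import prune_correlated

    if columns is None:
        columns = prune_correlated(fm)
    X = fm.data[columns].to_numpy(dtype=float)
    y = fm.y
    if len(np.unique(y)) < 2:
        raise ValueError("feature importance requires both classes")
    model = XGBClassifier(random_state=seed, n_jobs=1, verbosity=0)
    model.fit(X, y)
    booster = model.get_booster()
    gains = booster.get_score(importance_type="gain")
    raw = np.array([gains.get(f"f{i}", 0.0) for i in range(len(columns))], dtype=float)
    total = raw.sum()
    scores = raw / total if total > 0 else np.full(len(columns), 1.0 / len(columns))
    rows = []
    for i, col in enumerate(columns):
        x = X[:, i]
        sign = "+" if np.corrcoef(x, y)[0, 1] >= 0 else "-"
        rows.append((col, float(scores[i]), sign))
    rows.sort(key=lambda r: r[1], reverse=True)
    return ImportanceTable(rows=rows)
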