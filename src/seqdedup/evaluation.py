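"""Experimental protocols: cross-validation, learning curves, ablation,
error profiling, binary-vs-multiclass comparison, and generalisation.

All protocols consume the feature table (one row per pair, the 22 named
feature columns plus ``label``/``subtype``) and report pooled-fold (micro)
metrics: per-class precision/recall, one-vs-rest AUROC per class, overall
accuracy, and a single confusion matrix.  Cross-validation is stratified
with a fixed seed; every report echoes the configuration that produced it
and a short config hash for replay.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix, precision_score, recall_score, roc_auc_score
from sklearn.model_selection import KFold, StratifiedKFold

from seqdedup.features import NUMERIC_FEATURES
from seqdedup.labeling import SUBTYPES
from seqdedup.models import FEATURE_SETS, config_hash, encode, predict, train

__all__ = [
    "EvaluationReport",
    "LearningCurvePoint",
    "multiclass_labels",
    "evaluate_predictions",
    "cross_validate",
    "learning_curve",
    "ablate",
    "error_profile",
    "relative_type_accuracy",
    "cross_dataset",
    "cross_dataset_sweep",
]

_CURVE_METRICS = ("accuracy", "precision_DU", "recall_DU", "precision_DI", "recall_DI")


@dataclass
class EvaluationReport:
    """Pooled metrics for one experiment."""

    accuracy: float
    precision: dict[str, float]
    recall: dict[str, float]
    auroc: dict[str, float]
    confusion: pd.DataFrame
    n_per_class: dict[str, int]
    metadata: dict = field(default_factory=dict)

    @property
    def classes(self) -> tuple[str, ...]:
        return tuple(self.confusion.index)

    @property
    def avg_precision(self) -> float:
        """Macro average over classes (the ablation summary statistic)."""
        return float(np.mean(list(self.precision.values())))

    @property
    def avg_recall(self) -> float:
        return float(np.mean(list(self.recall.values())))

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "auroc": self.auroc,
            "confusion": self.confusion.to_dict(),
            "n_per_class": self.n_per_class,
            "metadata": self.metadata,
        }


@dataclass
class LearningCurvePoint:
    """Metrics at one training-set fraction, over repeated subsamples."""

    sample_fraction: float
    repeats: pd.DataFrame  # one row per repeat, columns _CURVE_METRICS
    mean: dict[str, float]
    std: dict[str, float]


def multiclass_labels(df: pd.DataFrame) -> np.ndarray:
    """Collapse label/subtype columns to one multiclass target:
    ES/EF/NS for duplicates, DI for distinct pairs."""
    labels = df["label"].to_numpy(dtype=object).copy()
    dup = labels == "DU"
    subtype = df["subtype"].fillna("").to_numpy(dtype=object)
    if np.any(dup & (subtype == "")):
        raise ValueError("duplicate pairs need a subtype for multiclass mode")
    labels[dup] = subtype[dup]
    return labels.astype(str)


def _labels_for_mode(df: pd.DataFrame, mode: str) -> np.ndarray:
    if mode == "binary":
        return df["label"].to_numpy(dtype=str)
    if mode == "multiclass":
        return multiclass_labels(df)
    raise ValueError(f"mode must be binary or multiclass, got {mode!r}")


def evaluate_predictions(
    y_true: np.ndarray,
    y_pred: np.ndarray,
    scores: Optional[pd.DataFrame] = None,
    metadata: Optional[dict] = None,
) -> EvaluationReport:
    """Compute pooled per-class precision/recall/AUROC, accuracy, confusion."""
    y_true = np.asarray(y_true, dtype=str)
    y_pred = np.asarray(y_pred, dtype=str)
    classes = sorted(set(y_true) | set(y_pred))
    cm = confusion_matrix(y_true, y_pred, labels=classes)
    precision = dict(
        zip(classes, precision_score(y_true, y_pred, labels=classes, average=None, zero_division=0))
    )
    recall = dict(
        zip(classes, recall_score(y_true, y_pred, labels=classes, average=None, zero_division=0))
    )
    auroc: dict[str, float] = {}
    for cls in classes:
        indicator = (y_true == cls).astype(int)
        if scores is None or cls not in scores.columns or len(set(indicator)) < 2:
            auroc[cls] = float("nan")
        else:
            auroc[cls] = float(roc_auc_score(indicator, scores[cls].to_numpy()))
    return EvaluationReport(
        accuracy=float((y_true == y_pred).mean()),
        precision={k: float(v) for k, v in precision.items()},
        recall={k: float(v) for k, v in recall.items()},
        auroc=auroc,
        confusion=pd.DataFrame(cm, index=classes, columns=classes),
        n_per_class={cls: int((y_true == cls).sum()) for cls in classes},
        metadata=metadata or {},
    )


def _fold_splitter(labels: np.ndarray, k: int, seed: int):
    """Stratified folds; non-stratified fallback when a class has < k members."""
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < k:
        warnings.warn(
            f"smallest class has {counts.min()} members (< {k} folds); "
            "falling back to non-stratified folds",
            stacklevel=3,
        )
        return KFold(n_splits=k, shuffle=True, random_state=seed)
    return StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)


def _cv_predictions(
    df: pd.DataFrame,
    labels: np.ndarray,
    algorithm: str,
    mode: str,
    feature_set: str,
    k: int,
    seed: int,
) -> tuple[np.ndarray, pd.DataFrame, list[np.ndarray]]:
    """Pooled out-of-fold predictions and scores (rows in original order)."""
    if len(df) < k:
        raise ValueError(f"need at least k={k} pairs, got {len(df)}")
    if len(np.unique(labels)) < 2:
        raise ValueError("cross-validation requires at least two classes")
    classes = sorted(np.unique(labels))
    y_pred = np.empty(len(df), dtype=object)
    scores = pd.DataFrame(0.0, index=range(len(df)), columns=classes)
    splitter = _fold_splitter(labels, k, seed)
    fold_assignment = []
    for train_idx, test_idx in splitter.split(df, labels):
        fold_assignment.append(test_idx)
        mat_train = encode(df.iloc[train_idx], feature_set, labels[train_idx])
        mat_test = encode(df.iloc[test_idx], feature_set)
        model = train(mat_train, algorithm=algorithm, mode=mode, seed=seed)
        pred, fold_scores = predict(model, mat_test)
        y_pred[test_idx] = pred
        for cls in fold_scores.columns:
            scores.loc[test_idx, cls] = fold_scores[cls].to_numpy()
    return y_pred.astype(str), scores, fold_assignment


def cross_validate(
    df: pd.DataFrame,
    algorithm: str = "decision_tree",
    mode: str = "binary",
    feature_set: str = "All",
    k: int = 10,
    seed: int = 0,
) -> EvaluationReport:
    """Stratified k-fold cross-validation with pooled-fold metrics."""
    labels = _labels_for_mode(df, mode)
    y_pred, scores, folds = _cv_predictions(
        df, labels, algorithm, mode, feature_set, k, seed
    )
    config = {
        "protocol": "cross_validate",
        "algorithm": algorithm,
        "mode": mode,
        "feature_set": feature_set,
        "folds": k,
        "seed": seed,
        "n": len(df),
    }
    report = evaluate_predictions(labels, y_pred, scores, metadata=config)
    report.metadata["config_hash"] = config_hash(config)
    report.metadata["fold_sizes"] = [len(f) for f in folds]
    return report


def _geometric_fractions(start: float, growth_factor: float) -> list[float]:
    if growth_factor <= 1:
        raise ValueError("growth_factor must exceed 1")
    fractions = []
    f = start
    while f < 1.0:
        fractions.append(f)
        f *= growth_factor
    fractions.append(1.0)
    return fractions


def _binary_point_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> dict[str, float]:
    out = {"accuracy": float((y_true == y_pred).mean())}
    for cls in ("DU", "DI"):
        out[f"precision_{cls}"] = float(
            precision_score(y_true, y_pred, labels=[cls], average=None, zero_division=0)[0]
        )
        out[f"recall_{cls}"] = float(
            recall_score(y_true, y_pred, labels=[cls], average=None, zero_division=0)[0]
        )
    return out


def learning_curve(
    df: pd.DataFrame,
    algorithm: str = "decision_tree",
    feature_set: str = "All",
    growth_factor: float = 1.05,
    repeats: int = 20,
    seed: int = 0,
    k: int = 10,
    start_fraction: float = 0.01,
    max_resample: int = 10,
) -> list[LearningCurvePoint]:
    """Binary-classification learning curve under k-fold cross-validation.

    For each fold, the training split is randomly subsampled at fractions
    growing geometrically from ``start_fraction`` to exactly 1.0, the model
    is trained on the subsample and tested on the untouched fold, and five
    metrics are recorded (accuracy, precision/recall for DU and DI).  Each
    fraction is measured ``repeats`` times with distinct derived seeds.
    """
    labels = _labels_for_mode(df, "binary")
    fractions = _geometric_fractions(start_fraction, growth_factor)
    splitter = _fold_splitter(labels, k, seed)
    folds = list(splitter.split(df, labels))
    points: list[LearningCurvePoint] = []
    ss = np.random.SeedSequence(seed)
    repeat_seeds = [int(s) for s in ss.generate_state(repeats) % (2**31 - 1)]
    for fraction in fractions:
        rows = []
        for rep, rep_seed in enumerate(repeat_seeds):
            rng = np.random.default_rng(rep_seed + int(fraction * 1e6))
            y_pred = np.empty(len(df), dtype=object)
            covered = np.zeros(len(df), dtype=bool)
            for train_idx, test_idx in folds:
                n_sample = max(2, int(round(fraction * len(train_idx))))
                sample = None
                for _ in range(max_resample):
                    cand = rng.choice(train_idx, size=min(n_sample, len(train_idx)), replace=False)
                    if len(np.unique(labels[cand])) >= 2:
                        sample = cand
                        break
                if sample is None:
                    warnings.warn(
                        f"fraction {fraction:.4f}: could not draw two classes; fold skipped",
                        stacklevel=2,
                    )
                    continue
                mat_train = encode(df.iloc[sample], feature_set, labels[sample])
                model = train(mat_train, algorithm=algorithm, mode="binary", seed=rep_seed)
                pred, _ = predict(model, encode(df.iloc[test_idx], feature_set))
                y_pred[test_idx] = pred
                covered[test_idx] = True
            if covered.any():
                rows.append(_binary_point_metrics(labels[covered], y_pred[covered].astype(str)))
        repeats_df = pd.DataFrame(rows, columns=list(_CURVE_METRICS))
        points.append(
            LearningCurvePoint(
                sample_fraction=fraction,
                repeats=repeats_df,
                mean={m: float(repeats_df[m].mean()) for m in _CURVE_METRICS},
                std={m: float(repeats_df[m].std(ddof=1)) for m in _CURVE_METRICS},
            )
        )
    return points


def ablate(
    df: pd.DataFrame,
    algorithm: str = "decision_tree",
    mode: str = "binary",
    k: int = 10,
    seed: int = 0,
) -> dict[str, EvaluationReport]:
    """Cross-validate every named feature set with shared fold assignment."""
    return {
        name: cross_validate(df, algorithm=algorithm, mode=mode, feature_set=name, k=k, seed=seed)
        for name in FEATURE_SETS
    }


def error_profile(
    truth: Sequence[str],
    predictions: Sequence[str],
    features: pd.DataFrame,
) -> pd.DataFrame:
    """Mean numeric-feature values over binary error pairs.

    FP = distinct pair predicted duplicate; FN = duplicate predicted
    distinct.  For each numeric feature the mean is taken over error pairs
    where the feature is present — pairs missing a feature are excluded
    from that feature's mean, not zero-filled.  The first row carries the
    instance counts.
    """
    truth = np.asarray(truth, dtype=str)
    predictions = np.asarray(predictions, dtype=str)
    masks = {
        "FP": (truth == "DI") & (predictions == "DU"),
        "FN": (truth == "DU") & (predictions == "DI"),
    }
    table = pd.DataFrame(index=["#Instances", *NUMERIC_FEATURES], columns=["FP", "FN"], dtype=float)
    for kind, mask in masks.items():
        table.loc["#Instances", kind] = float(mask.sum())
        subset = features.loc[mask, list(NUMERIC_FEATURES)]
        for feat in NUMERIC_FEATURES:
            values = pd.to_numeric(subset[feat], errors="coerce").dropna()
            table.loc[feat, kind] = float(values.mean()) if len(values) else float("nan")
    return table


def relative_type_accuracy(
    binary_preds: Sequence[str],
    multi_preds: Sequence[str],
    truth_binary: Sequence[str],
    truth_subtypes: Sequence[str],
) -> pd.DataFrame:
    """Per-subtype relative accuracy of binary vs multiclass models.

    A binary model is credited on a duplicate whenever it predicts DU; a
    multiclass model whenever it predicts any duplicate subtype (subtype
    confusion among ES/EF/NS still identifies a duplicate).  DI rows are
    credited only on an exact DI prediction.
    """
    binary_preds = np.asarray(binary_preds, dtype=str)
    multi_preds = np.asarray(multi_preds, dtype=str)
    truth_binary = np.asarray(truth_binary, dtype=str)
    truth_subtypes = np.asarray(truth_subtypes, dtype=str)
    if not (len(binary_preds) == len(multi_preds) == len(truth_binary)):
        raise ValueError("prediction and truth arrays must share length")
    rows = {}
    for subtype in SUBTYPES:
        mask = (truth_binary == "DU") & (truth_subtypes == subtype)
        if mask.sum() == 0:
            rows[subtype] = {"binary": float("nan"), "multiclass": float("nan"), "n": 0}
            continue
        rows[subtype] = {
            "binary": float((binary_preds[mask] == "DU").mean()),
            "multiclass": float(np.isin(multi_preds[mask], SUBTYPES).mean()),
            "n": int(mask.sum()),
        }
    di_mask = truth_binary == "DI"
    rows["DI"] = {
        "binary": float((binary_preds[di_mask] == "DI").mean()) if di_mask.any() else float("nan"),
        "multiclass": float((multi_preds[di_mask] == "DI").mean()) if di_mask.any() else float("nan"),
        "n": int(di_mask.sum()),
    }
    return pd.DataFrame(rows).T[["binary", "multiclass", "n"]]


def cross_dataset(
    train_df: pd.DataFrame,
    test_df: pd.DataFrame,
    algorithm: str = "decision_tree",
    mode: str = "binary",
    feature_set: str = "All",
    seed: int = 0,
) -> EvaluationReport:
    """Train on one full dataset, evaluate on another (generalisation)."""
    if train_df is test_df:
        raise ValueError("train and test datasets must be disjoint")
    y_train = _labels_for_mode(train_df, mode)
    y_test = _labels_for_mode(test_df, mode)
    model = train(encode(train_df, feature_set, y_train), algorithm=algorithm, mode=mode, seed=seed)
    y_pred, scores = predict(model, encode(test_df, feature_set))
    config = {
        "protocol": "cross_dataset",
        "algorithm": algorithm,
        "mode": mode,
        "feature_set": feature_set,
        "seed": seed,
        "n_train": len(train_df),
        "n_test": len(test_df),
    }
    report = evaluate_predictions(y_test, y_pred, scores, metadata=config)
    report.metadata["config_hash"] = config_hash(config)
    return report


def cross_dataset_sweep(
    datasets: dict[str, pd.DataFrame],
    algorithm: str = "decision_tree",
    mode: str = "binary",
    feature_set: str = "All",
    seed: int = 0,
) -> dict[tuple[str, str], EvaluationReport]:
    """All ordered train/test dataset pairs: n datasets -> n*(n-1) reports."""
    reports = {}
    for name_train, df_train in datasets.items():
        for name_test, df_test in datasets.items():
            if name_train == name_test:
                continue
            report = cross_dataset(
                df_train, df_test, algorithm=algorithm, mode=mode,
                feature_set=feature_set, seed=seed,
            )
            report.metadata["train_dataset"] = name_train
            report.metadata["test_dataset"] = name_test
            reports[(name_train, name_test)] = report
    return reports
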