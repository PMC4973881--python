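"""Feature encoding and the three classifiers (Naive Bayes, tree, SVM).

The named feature sets mirror the ablation design: metadata only, bare
sequence similarity, sequence plus alignment quality, plus coding-region
features, plus metadata, or everything.

Encoding turns the 22-feature schema into a dense numeric matrix: Yes/No
flags become 0/1 indicators, the three-valued Submitter feature is one-hot
encoded, and missing numerics are imputed (similarities to 0, E-values to
the report cutoff) — the ``Has_*``/``*_HITS`` indicators retain the
missingness signal the categorical features encode, and SVMs cannot consume
missing values.  SVM inputs are min-max scaled to [0, 1] with parameters
fitted on training data only; multi-class SVM uses the one-vs-one scheme.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import joblib
import numpy as np
import pandas as pd
from sklearn.naive_bayes import GaussianNB
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import MinMaxScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from seqdedup.features import FEATURE_NAMES, NUMERIC_FEATURES, PairFeatures

__all__ = [
    "FEATURE_SETS",
    "ALGORITHMS",
    "EncodedMatrix",
    "TrainedModel",
    "encode",
    "train",
    "predict",
    "save_model",
    "load_model",
    "config_hash",
]

_META = ("Description", "Has_Literature", "Literature", "Submitter")
_SEQ = ("Length", "Identity")
_SQ = _SEQ + ("Has_HITS", "AP", "Expect_Value", "Over_Threshold")
_CDS_TRS = (
    "Has_CDS", "CDS_HITS", "CDS_Identity", "CDS_AP", "CDS_Expect", "CDS_Threshold",
    "Has_TRS", "TRS_HITS", "TRS_Identity", "TRS_AP", "TRS_Expect", "TRS_Threshold",
)

FEATURE_SETS: dict[str, tuple[str, ...]] = {
    "Meta": _META,
    "Seq": _SEQ,
    "SQ": _SQ,
    "SQC": _SQ + _CDS_TRS,
    "SQM": _SQ + _META,
    "All": FEATURE_NAMES,
}

ALGORITHMS = ("naive_bayes", "decision_tree", "svm")

#: Imputation value for missing E-values (the alignment report cutoff).
EVALUE_IMPUTE = 10.0

_EXPECT_COLUMNS = {"Expect_Value", "CDS_Expect", "TRS_Expect"}
_SUBMITTER_LEVELS = ("SAME", "DIFFERENT", "NA")


def config_hash(config: dict) -> str:
    """Short deterministic hash of a run configuration, for provenance."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha1(blob).hexdigest()[:12]


@dataclass(frozen=True)
class EncodedMatrix:
    """Dense numeric design matrix for one named feature set."""

    X: np.ndarray
    column_names: tuple[str, ...]
    labels: Optional[np.ndarray]
    feature_set: str

    @property
    def n_rows(self) -> int:
        return self.X.shape[0]


def _as_frame(
    features: Union[pd.DataFrame, Sequence[PairFeatures]]
) -> pd.DataFrame:
    if isinstance(features, pd.DataFrame):
        return features
    return pd.DataFrame([f.to_dict() for f in features])


def encode(
    features: Union[pd.DataFrame, Sequence[PairFeatures]],
    feature_set: str = "All",
    labels: Optional[Sequence[str]] = None,
) -> EncodedMatrix:
    """Encode pair features into a dense matrix for a named feature set."""
    if feature_set not in FEATURE_SETS:
        raise ValueError(
            f"unknown feature set {feature_set!r}; choose from {sorted(FEATURE_SETS)}"
        )
    df = _as_frame(features)
    columns: list[str] = []
    data: list[np.ndarray] = []
    for name in FEATURE_SETS[feature_set]:
        col = df[name]
        if name == "Submitter":
            for level in _SUBMITTER_LEVELS:
                columns.append(f"Submitter={level}")
                data.append((col == level).to_numpy(dtype=float))
        elif name in NUMERIC_FEATURES:
            values = pd.to_numeric(col, errors="coerce").to_numpy(dtype=float)
            fill = EVALUE_IMPUTE if name in _EXPECT_COLUMNS else 0.0
            values = np.where(np.isnan(values), fill, values)
            columns.append(name)
            data.append(values)
        else:  # Yes/No indicator
            columns.append(name)
            data.append((col == "Yes").to_numpy(dtype=float))
    X = np.column_stack(data) if data else np.empty((len(df), 0))
    label_arr = np.asarray(labels) if labels is not None else None
    if label_arr is not None and len(label_arr) != X.shape[0]:
        raise ValueError("labels length does not match feature rows")
    return EncodedMatrix(
        X=X, column_names=tuple(columns), labels=label_arr, feature_set=feature_set
    )


@dataclass
class TrainedModel:
    """A fitted classifier plus everything needed to reapply it."""

    algorithm: str
    mode: str
    feature_set: str
    estimator: object
    column_names: tuple[str, ...]
    classes: tuple[str, ...]
    seed: int

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"TrainedModel({self.algorithm}, {self.mode}, {self.feature_set}, "
            f"classes={self.classes}, seed={self.seed})"
        )


def _make_estimator(algorithm: str, seed: int):
    if algorithm == "naive_bayes":
        return GaussianNB()
    if algorithm == "decision_tree":
        return DecisionTreeClassifier(random_state=seed)
    if algorithm == "svm":
        # clip=True: test-time values outside the training range are clipped
        # to the [0, 1] scale fitted on training data only
        return Pipeline(
            [
                ("scale", MinMaxScaler(feature_range=(0.0, 1.0), clip=True)),
                ("svc", SVC(kernel="rbf", probability=True, random_state=seed)),
            ]
        )
    raise ValueError(f"unknown algorithm {algorithm!r}; choose from {ALGORITHMS}")


def train(
    matrix: EncodedMatrix,
    algorithm: str = "decision_tree",
    mode: str = "binary",
    seed: int = 0,
) -> TrainedModel:
    """Fit one of the three classifiers on an encoded matrix."""
    if matrix.labels is None:
        raise ValueError("training requires labels")
    if mode not in ("binary", "multiclass"):
        raise ValueError(f"mode must be binary or multiclass, got {mode!r}")
    classes = np.unique(matrix.labels)
    if len(classes) < 2:
        raise ValueError("training requires at least two label classes")
    est = _make_estimator(algorithm, seed)
    est.fit(matrix.X, matrix.labels)
    return TrainedModel(
        algorithm=algorithm,
        mode=mode,
        feature_set=matrix.feature_set,
        estimator=est,
        column_names=matrix.column_names,
        classes=tuple(str(c) for c in np.asarray(est.classes_)),
        seed=seed,
    )


def predict(
    model: TrainedModel, matrix: EncodedMatrix
) -> tuple[np.ndarray, pd.DataFrame]:
    """Hard labels plus per-class probability scores (usable for AUROC)."""
    if matrix.column_names != model.column_names:
        raise ValueError(
            f"column mismatch: model trained on {model.column_names}, "
            f"got {matrix.column_names}"
        )
    labels = model.estimator.predict(matrix.X)
    proba = model.estimator.predict_proba(matrix.X)
    scores = pd.DataFrame(proba, columns=list(model.estimator.classes_))
    return np.asarray(labels), scores


def save_model(model: TrainedModel, path: Union[str, Path]) -> None:
    """Persist a trained model (joblib with a format-version tag)."""
    joblib.dump({"format": 1, "model": model}, path)


def load_model(path: Union[str, Path]) -> TrainedModel:
    payload = joblib.load(path)
    if not isinstance(payload, dict) or payload.get("format") != 1:
        raise ValueError(f"{path}: not a seqdedup model file")
    return payload["model"]
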