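"""Evaluation protocols against hand-computed oracles and design contracts."""

import itertools

import numpy as np
import pandas as pd
import pytest

from seqdedup.evaluation import (
    cross_dataset,
    cross_dataset_sweep,
    cross_validate,
    error_profile,
    evaluate_predictions,
    learning_curve,
    multiclass_labels,
    relative_type_accuracy,
    ablate,
)


# --- metric oracle on a fixed 10-pair fixture ------------------------------

FIXTURE_TRUTH = ["DU", "DU", "DU", "DU", "DU", "DI", "DI", "DI", "DI", "DI"]
FIXTURE_PRED = ["DU", "DU", "DU", "DI", "DI", "DI", "DI", "DI", "DU", "DI"]
FIXTURE_SCORES_DU = [0.9, 0.8, 0.7, 0.4, 0.45, 0.2, 0.1, 0.3, 0.6, 0.05]


def oracle_metrics():
    """Exhaustive hand computation of precision/recall/accuracy/AUROC."""
    tp = sum(t == "DU" and p == "DU" for t, p in zip(FIXTURE_TRUTH, FIXTURE_PRED))
    fp = sum(t == "DI" and p == "DU" for t, p in zip(FIXTURE_TRUTH, FIXTURE_PRED))
    fn = sum(t == "DU" and p == "DI" for t, p in zip(FIXTURE_TRUTH, FIXTURE_PRED))
    tn = sum(t == "DI" and p == "DI" for t, p in zip(FIXTURE_TRUTH, FIXTURE_PRED))
    # AUROC by pairwise enumeration over all (positive, negative) pairs
    pos = [s for t, s in zip(FIXTURE_TRUTH, FIXTURE_SCORES_DU) if t == "DU"]
    neg = [s for t, s in zip(FIXTURE_TRUTH, FIXTURE_SCORES_DU) if t == "DI"]
    wins = sum(
        1.0 if p > q else 0.5 if p == q else 0.0
        for p, q in itertools.product(pos, neg)
    )
    return {
        "precision_DU": tp / (tp + fp),
        "recall_DU": tp / (tp + fn),
        "precision_DI": tn / (tn + fn),
        "recall_DI": tn / (tn + fp),
        "accuracy": (tp + tn) / 10,
        "auroc_DU": wins / (len(pos) * len(neg)),
    }


def test_metrics_match_hand_computation_exactly():
    scores = pd.DataFrame({
        "DU": FIXTURE_SCORES_DU,
        "DI": [1 - s for s in FIXTURE_SCORES_DU],
    })
    report = evaluate_predictions(FIXTURE_TRUTH, FIXTURE_PRED, scores)
    expected = oracle_metrics()
    assert report.precision["DU"] == pytest.approx(expected["precision_DU"])
    assert report.recall["DU"] == pytest.approx(expected["recall_DU"])
    assert report.precision["DI"] == pytest.approx(expected["precision_DI"])
    assert report.recall["DI"] == pytest.approx(expected["recall_DI"])
    assert report.accuracy == pytest.approx(expected["accuracy"])
    assert report.auroc["DU"] == pytest.approx(expected["auroc_DU"])


def test_auroc_extremes():
    truth = ["DU"] * 5 + ["DI"] * 5
    perfect = pd.DataFrame({"DU": [1.0] * 5 + [0.0] * 5})
    inverted = pd.DataFrame({"DU": [0.0] * 5 + [1.0] * 5})
    assert evaluate_predictions(truth, truth, perfect).auroc["DU"] == 1.0
    assert evaluate_predictions(truth, truth, inverted).auroc["DU"] == 0.0


def test_confusion_marginals_equal_class_counts():
    report = evaluate_predictions(FIXTURE_TRUTH, FIXTURE_PRED)
    assert report.confusion.sum(axis=1).to_dict() == {"DI": 5, "DU": 5}
    assert report.confusion.to_numpy().sum() == 10
    assert report.accuracy == np.trace(report.confusion.to_numpy()) / 10


# --- cross-validation ------------------------------------------------------

def test_separable_corpus_cross_validates_cleanly(separable_features):
    report = cross_validate(separable_features, "decision_tree", "binary", "All",
                            k=10, seed=5)
    assert report.accuracy >= 0.99
    assert sum(report.metadata["fold_sizes"]) == len(separable_features)


def test_permuted_labels_score_at_chance(separable_features):
    df = separable_features.copy()
    df["label"] = np.random.default_rng(0).permutation(df["label"].to_numpy())
    report = cross_validate(df, "decision_tree", "binary", "All", k=10, seed=5)
    assert report.accuracy == pytest.approx(0.5, abs=0.07)


def test_multiclass_cv_and_report_carry_config(small_features):
    with pytest.warns(UserWarning, match="non-stratified"):
        # 8 NS pairs < 10 folds triggers the fallback
        report = cross_validate(small_features, "decision_tree", "multiclass",
                                "All", k=10, seed=2)
    assert set(report.classes) <= {"ES", "EF", "NS", "DI"}
    assert report.metadata["config_hash"]
    assert report.metadata["seed"] == 2


def test_cv_requires_enough_rows(small_features):
    with pytest.raises(ValueError, match="at least k"):
        cross_validate(small_features.head(5), k=10)


# --- learning curve --------------------------------------------------------

def test_learning_curve_protocol(separable_features):
    points = learning_curve(
        separable_features, growth_factor=4.0, repeats=3, seed=0, k=5
    )
    fractions = [p.sample_fraction for p in points]
    assert fractions[0] == pytest.approx(0.01)
    assert fractions[-1] == 1.0
    assert all(f1 < f2 for f1, f2 in zip(fractions, fractions[1:]))
    # geometric growth until the cap
    for f1, f2 in zip(fractions[:-2], fractions[1:-1]):
        assert f2 == pytest.approx(f1 * 4.0)
    for point in points:
        assert len(point.repeats) == 3
        assert set(point.mean) == {
            "accuracy", "precision_DU", "recall_DU", "precision_DI", "recall_DI"
        }
    assert points[-1].mean["accuracy"] >= points[0].mean["accuracy"] - 0.01


def test_learning_curve_rejects_bad_growth(separable_features):
    with pytest.raises(ValueError, match="growth_factor"):
        learning_curve(separable_features, growth_factor=1.0)


# --- ablation --------------------------------------------------------------

def test_ablation_covers_all_feature_sets(separable_features):
    reports = ablate(separable_features, "decision_tree", k=5, seed=9)
    assert set(reports) == {"Meta", "Seq", "SQ", "SQC", "SQM", "All"}
    fold_sizes = {name: tuple(r.metadata["fold_sizes"]) for name, r in reports.items()}
    assert len(set(fold_sizes.values())) == 1  # shared fold design
    assert reports["Seq"].metadata["feature_set"] == "Seq"
    for report in reports.values():
        assert 0.0 <= report.avg_precision <= 1.0


# --- error profiling -------------------------------------------------------

def test_error_profile_means_and_exclusions():
    truth = ["DI", "DI", "DI", "DU", "DU"]
    preds = ["DU", "DU", "DI", "DI", "DU"]
    features = pd.DataFrame({
        "Description": [0.1, 0.3, 0.9, 0.5, 0.2],
        "Literature": [np.nan] * 5,
        "Length": [1.0] * 5,
        "Identity": [0.9, 1.0, 0.5, np.nan, 0.8],
        "AP": [0.2, 0.4, 0.1, 0.3, 0.9],
        "Expect_Value": [0.01] * 5,
        "CDS_Identity": [np.nan] * 5, "CDS_AP": [np.nan] * 5,
        "CDS_Expect": [np.nan] * 5, "TRS_Identity": [np.nan] * 5,
        "TRS_AP": [np.nan] * 5, "TRS_Expect": [np.nan] * 5,
    })
    table = error_profile(truth, preds, features)
    assert table.loc["#Instances", "FP"] == 2
    assert table.loc["#Instances", "FN"] == 1
    assert table.loc["Identity", "FP"] == pytest.approx(0.95)
    # the FN pair's Identity is missing -> excluded, mean undefined
    assert np.isnan(table.loc["Identity", "FN"])
    assert np.isnan(table.loc["Literature", "FP"])


def test_error_profile_with_no_errors():
    truth = preds = ["DU", "DI"]
    features = pd.DataFrame(
        {c: [0.5, 0.5] for c in [
            "Description", "Literature", "Length", "Identity", "AP",
            "Expect_Value", "CDS_Identity", "CDS_AP", "CDS_Expect",
            "TRS_Identity", "TRS_AP", "TRS_Expect"]}
    )
    table = error_profile(truth, preds, features)
    assert table.loc["#Instances"].tolist() == [0.0, 0.0]
    assert table.drop("#Instances").isna().all().all()


# --- binary vs multiclass relative accuracy --------------------------------

def test_relative_type_accuracy_credits_subtype_confusion():
    truth_binary = ["DU", "DU", "DU", "DI", "DI"]
    truth_subtype = ["EF", "ES", "NS", "", ""]
    binary_preds = ["DU", "DI", "DU", "DI", "DU"]
    multi_preds = ["ES", "EF", "DI", "DI", "NS"]
    table = relative_type_accuracy(binary_preds, multi_preds, truth_binary, truth_subtype)
    assert table.loc["EF", "binary"] == 1.0
    assert table.loc["EF", "multiclass"] == 1.0  # EF predicted ES still counts
    assert table.loc["ES", "binary"] == 0.0
    assert table.loc["ES", "multiclass"] == 1.0
    assert table.loc["NS", "multiclass"] == 0.0  # NS predicted DI is wrong
    assert table.loc["DI", "binary"] == 0.5
    assert table.loc["DI", "multiclass"] == 0.5  # DI predicted NS is wrong
    assert table["n"].tolist() == [1, 1, 1, 2]


# --- generalisation --------------------------------------------------------

def test_cross_dataset_rejects_identity(separable_features):
    with pytest.raises(ValueError, match="disjoint"):
        cross_dataset(separable_features, separable_features)


def test_cross_dataset_sweep_counts_and_transfer(separable_features):
    from seqdedup.features import compute_feature_table
    from seqdedup.synth import generate_separable_set

    datasets = {
        "a": separable_features,
        "b": compute_feature_table(generate_separable_set(120, seed=21)),
        "c": compute_feature_table(generate_separable_set(120, seed=22)),
    }
    reports = cross_dataset_sweep(datasets, "decision_tree", "binary", "All", seed=0)
    assert len(reports) == 6
    assert set(reports) == {(a, b) for a in "abc" for b in "abc" if a != b}
    # identical generating process: transfer stays accurate
    for report in reports.values():
        assert report.accuracy >= 0.95


def test_multiclass_labels_requires_subtypes():
    df = pd.DataFrame({"label": ["DU", "DI"], "subtype": ["", ""]})
    with pytest.raises(ValueError, match="subtype"):
        multiclass_labels(df)
    df2 = pd.DataFrame({"label": ["DU", "DI"], "subtype": ["ES", ""]})
    assert multiclass_labels(df2).tolist() == ["ES", "DI"]
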