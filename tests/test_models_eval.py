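"""Splitting, ROC/AUC, metric tallies, importance, and the benchmark suite."""

import numpy as np
import pandas as pd
import pytest

from vardyn.models_eval import (
    ModelSpec,
    SuiteConfig,
    concordance_table,
    default_model_specs,
    dt_feature_importance,
    fit_predict,
    metrics_report,
    roc_auc_ovr,
    run_benchmark_suite,
    stratified_folds,
    train_test_split,
)
from vardyn.synthdata import FeatureTableDesign, make_feature_table
from vardyn.trajfeatures import FEATURE_NAMES


# ------------------------------------------------------------------- splitting


def test_stratified_folds_balanced_and_reproducible():
    labels = np.repeat([0, 1, 3], 97)
    folds = stratified_folds(labels, 10, seed=0)
    all_test = np.concatenate([te for _, te in folds])
    assert len(all_test) == len(labels)
    assert len(np.unique(all_test)) == len(labels)  # disjoint cover
    for train, test in folds:
        assert np.intersect1d(train, test).size == 0
        for c in (0, 1, 3):
            assert 9 <= (labels[test] == c).sum() <= 10
    again = stratified_folds(labels, 10, seed=0)
    for (a, b), (c, d) in zip(folds, again):
        assert np.array_equal(a, c) and np.array_equal(b, d)
    with pytest.raises(ValueError):
        stratified_folds([0, 0, 0, 1], k=2)


def test_train_test_split_sizes_and_determinism():
    table = pd.DataFrame({"x": np.arange(291.0), "label": np.repeat([0, 1, 3], 97)})
    train, test = train_test_split(table)
    assert len(test) == 59 and len(train) == 232  # ceil(0.2 * 291)
    assert set(train.index).isdisjoint(test.index)
    assert set(train.index) | set(test.index) == set(table.index)
    train2, test2 = train_test_split(table)
    pd.testing.assert_frame_equal(test, test2)
    tiny = pd.DataFrame({"x": [1.0, 2, 3, 4], "label": [0, 0, 0, 1]})
    with pytest.warns(UserWarning):
        train_test_split(tiny, test_fraction=0.5, seed=0)


# ------------------------------------------------------------------------ ROC


def test_auc_toy_score_vectors():
    labels = np.array([1, 1, 0, 0])
    assert roc_auc_ovr(np.array([0.9, 0.8, 0.2, 0.1]), labels, 1)[2] == 1.0
    assert roc_auc_ovr(np.array([0.1, 0.2, 0.8, 0.9]), labels, 1)[2] == 0.0
    # 3 of 4 discordant-free pairs -> 0.75
    mixed = roc_auc_ovr(np.array([0.9, 0.8, 0.7, 0.6]), np.array([1, 0, 1, 0]), 1)
    assert mixed[2] == pytest.approx(0.75)
    with pytest.raises(ValueError):
        roc_auc_ovr(np.array([0.1, 0.2]), np.array([1, 1]), 1)


def test_auc_matches_sklearn_and_monotone_invariance():
    from sklearn.metrics import roc_auc_score

    rng = np.random.default_rng(0)
    labels = rng.integers(0, 2, size=200)
    scores = rng.uniform(size=200) + 0.3 * labels
    mine = roc_auc_ovr(scores, labels, 1)[2]
    assert mine == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)
    transformed = np.exp(3.0 * scores) - 1.0  # strictly monotone transform
    assert roc_auc_ovr(transformed, labels, 1)[2] == pytest.approx(mine, abs=1e-12)


def test_auc_handles_ties_by_grouping():
    scores = np.array([0.5, 0.5, 0.5, 0.5])
    labels = np.array([1, 1, 0, 0])
    assert roc_auc_ovr(scores, labels, 1)[2] == pytest.approx(0.5)


# -------------------------------------------------------------------- metrics


def test_metrics_hand_tally():
    labels = [0, 0, 1, 1, 3, 3]
    preds = [0, 1, 1, 1, 3, 0]
    m = metrics_report(preds, labels)
    expected_cm = pd.DataFrame(
        [[1, 1, 0], [0, 2, 0], [1, 0, 1]], index=[0, 1, 3], columns=[0, 1, 3]
    )
    pd.testing.assert_frame_equal(m["confusion"], expected_cm)
    assert m["accuracy"] == pytest.approx(4 / 6)
    assert m["per_class"][0]["f1"] == pytest.approx(0.5)
    assert m["per_class"][1]["f1"] == pytest.approx(0.8)
    assert m["per_class"][3]["f1"] == pytest.approx(2 / 3)
    assert m["macro_f1"] == pytest.approx((0.5 + 0.8 + 2 / 3) / 3)
    assert m["micro_f1"] == pytest.approx(m["accuracy"])  # multiclass identity


def test_metrics_perfect_and_zero_prediction_guard():
    m = metrics_report([0, 1, 3], [0, 1, 3])
    assert m["accuracy"] == 1.0 and m["macro_f1"] == 1.0
    with pytest.warns(UserWarning, match="zero predicted"):
        m = metrics_report([0, 0, 0], [0, 1, 1])
    assert m["per_class"][1]["precision"] == 0.0
    with pytest.raises(ValueError):
        metrics_report([0], [0, 1])


def test_confusion_row_sums_equal_true_counts():
    rng = np.random.default_rng(1)
    labels = rng.choice([0, 1, 3], size=120)
    preds = rng.choice([0, 1, 3], size=120)
    m = metrics_report(preds, labels)
    for c in (0, 1, 3):
        assert m["confusion"].loc[c].sum() == (labels == c).sum()
    assert np.trace(m["confusion"].to_numpy()) / 120 == pytest.approx(m["accuracy"])


# ----------------------------------------------------------------- estimators


@pytest.mark.parametrize("spec", default_model_specs(), ids=lambda s: s.algorithm)
def test_separable_blobs_fit_perfectly(spec):
    rng = np.random.default_rng(2)
    x0 = rng.normal(loc=0.0, scale=0.3, size=(30, 2))
    x1 = rng.normal(loc=5.0, scale=0.3, size=(30, 2))
    x = np.vstack([x0, x1])
    y = np.array([0] * 30 + [1] * 30)
    classes, scores, hard = fit_predict(spec, x, y, x, seed=0)
    assert np.allclose(scores.sum(axis=1), 1.0, atol=1e-6)
    assert (hard == y).mean() == 1.0


def test_fit_predict_contracts():
    x = np.random.default_rng(3).normal(size=(20, 2))
    with pytest.raises(ValueError):
        fit_predict(ModelSpec("knn"), x, np.zeros(20), x)
    with pytest.raises(ValueError):
        ModelSpec("adaboost")


def test_tree_and_knn_invariant_to_row_permutation():
    rng = np.random.default_rng(4)
    x = rng.normal(size=(60, 3))
    y = (x[:, 0] + 0.1 * rng.normal(size=60) > 0).astype(int)
    xe = rng.normal(size=(20, 3))
    perm = rng.permutation(60)
    for alg in ("decision_tree", "knn"):
        spec = ModelSpec(alg) if alg != "decision_tree" else ModelSpec(alg, {"max_depth": 5})
        _, _, ref = fit_predict(spec, x, y, xe, seed=7)
        _, _, shuffled = fit_predict(spec, x[perm], y[perm], xe, seed=7)
        assert np.array_equal(ref, shuffled)


# ----------------------------------------------------------------- importance


def test_single_informative_feature_dominates():
    rng = np.random.default_rng(5)
    n = 100
    informative = np.r_[rng.uniform(0, 1, 50), rng.uniform(2, 3, 50)]
    features = pd.DataFrame(
        {
            "signal": informative,
            "noise1": rng.normal(size=n),
            "noise2": rng.normal(size=n),
        }
    )
    labels = np.array([0] * 50 + [1] * 50)
    imp = dt_feature_importance(features, labels, n_folds=10, seed=0)
    assert imp.sum() == pytest.approx(1.0)
    assert (imp >= 0).all()
    assert imp["signal"] == pytest.approx(1.0, abs=1e-9)


def test_importance_ranking_matches_reference_tree():
    from sklearn.tree import DecisionTreeClassifier

    rng = np.random.default_rng(6)
    n = 200
    f1 = np.r_[rng.normal(0, 1, 100), rng.normal(3, 1, 100)]
    f2 = np.r_[rng.normal(0, 1, 100), rng.normal(1.0, 1, 100)]
    features = pd.DataFrame({"f1": f1, "f2": f2, "noise": rng.normal(size=n)})
    labels = np.array([0] * 100 + [1] * 100)
    imp = dt_feature_importance(features, labels, n_folds=10, seed=0)
    ref = DecisionTreeClassifier(max_depth=5, min_samples_split=20, random_state=0)
    ref.fit(features, labels)
    ref_rank = list(features.columns[np.argsort(-ref.feature_importances_)])
    assert list(imp.sort_values(ascending=False).index) == ref_rank


# -------------------------------------------------------------- benchmark suite


@pytest.fixture(scope="module")
def small_table():
    return make_feature_table(
        FeatureTableDesign(n_benign=40, n_damaging=60, n_ambiguous=12, n_unknown=30, seed=3)
    )


def test_suite_leakage_safe_protocol(small_table):
    specs = [ModelSpec("random_forest", {"n_estimators": 100, "max_depth": 7})]
    reports, _ = run_benchmark_suite(
        small_table, list(FEATURE_NAMES), specs, config=SuiteConfig(seed=3)
    )
    report = reports["random_forest"]
    assert report.confusion.to_numpy().sum() == 23  # ceil(0.2 * 112) test rows
    assert report.roc[0][2] > 0.9  # strong separation, benign vs rest
    assert report.importances is not None
    assert report.importances.sum() == pytest.approx(1.0)


def test_suite_paper_compat_protocol_and_concordance(small_table):
    specs = [ModelSpec("decision_tree", {"max_depth": 5, "min_samples_split": 20})]
    rng = np.random.default_rng(7)
    unknown_ids = small_table.loc[small_table["label"] == 2, "variant"]
    external = pd.DataFrame(
        {"toolA": rng.uniform(size=len(unknown_ids)), "toolB": rng.uniform(size=len(unknown_ids))},
        index=unknown_ids,
    )
    reports, concordance = run_benchmark_suite(
        small_table,
        list(FEATURE_NAMES),
        specs,
        external_scores=external,
        config=SuiteConfig(protocol="paper_compat", seed=3),
    )
    assert reports["decision_tree"].confusion.to_numpy().sum() == 36  # ceil(0.2*180)
    assert concordance is not None
    # partition: matched + unmatched = total per (model, class)
    assert (concordance["matched"] + concordance["unmatched"]).equals(
        concordance["total"]
    )


def test_concordance_requires_external_columns():
    preds = pd.DataFrame(
        {"variant": ["v1"], "model": ["knn"], "predicted_class": [0]}
    )
    with pytest.raises(ValueError):
        concordance_table(preds, pd.DataFrame())
    with pytest.raises(ValueError):
        concordance_table(
            preds,
            pd.DataFrame({"toolA": [0.3]}, index=["v1"]),
            thresholds={"toolA": None},
        )
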