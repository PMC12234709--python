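"""Multiclass classifier training and the full evaluation surface.

Eight classifier configurations (random forest, deep net, semi-supervised
label spreading, decision tree, gradient boosting, RBF-kernel SVM, k-nearest
neighbours, logistic regression) are trained on the balanced feature table
and evaluated with one-vs-rest ROC/AUC, confusion matrices, accuracy, the F1
family, and Gini feature importance from a depth-limited decision tree.

Folds, splits, ROC sweeps, metric tallies and importance averaging are
implemented here from their definitions; scikit-learn backs only the
classifier cores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import ceil

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.semi_supervised import LabelSpreading
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .balance import smote_balance

ALGORITHMS = (
    "random_forest",
    "deep_net",
    "semi_supervised_spreading",
    "decision_tree",
    "gradient_boosting",
    "svm_rbf",
    "knn",
    "logistic",
)


@dataclass(frozen=True)
class ModelSpec:
    """A classifier configuration: algorithm name plus hyperparameters."""

    algorithm: str
    hyperparameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unsupported algorithm {self.algorithm!r}")


def default_model_specs() -> list[ModelSpec]:
    """The eight classifier presets used throughout the pipeline."""
    return [
        ModelSpec("random_forest", {"n_estimators": 100, "max_depth": 7}),
        ModelSpec("deep_net", {"hidden_layer_sizes": (64, 64, 64), "max_iter": 400}),
        ModelSpec(
            "semi_supervised_spreading",
            {"kernel": "rbf", "alpha": 0.2, "gamma": 20.0},
        ),
        ModelSpec("decision_tree", {"max_depth": 5, "min_samples_split": 20}),
        ModelSpec(
            "gradient_boosting",
            {"learning_rate": 0.05, "n_estimators": 200, "max_depth": 4},
        ),
        ModelSpec("svm_rbf", {"gamma": 20.0, "C": 1.0}),
        ModelSpec("knn", {"n_neighbors": 4}),
        ModelSpec("logistic", {"C": 1.0}),
    ]


def build_estimator(spec: ModelSpec, seed: int | None = None):
    hp = dict(spec.hyperparameters)
    alg = spec.algorithm
    if alg == "random_forest":
        return RandomForestClassifier(random_state=seed, **hp)
    if alg == "deep_net":
        hp.setdefault("hidden_layer_sizes", (64, 64, 64))
        hp.setdefault("max_iter", 400)
        return MLPClassifier(solver="adam", random_state=seed, **hp)
    if alg == "semi_supervised_spreading":
        hp.setdefault("kernel", "rbf")
        hp.setdefault("alpha", 0.2)
        hp.setdefault("gamma", 20.0)
        return LabelSpreading(**hp)
    if alg == "decision_tree":
        return DecisionTreeClassifier(random_state=seed, **hp)
    if alg == "gradient_boosting":
        return GradientBoostingClassifier(random_state=seed, **hp)
    if alg == "svm_rbf":
        hp.setdefault("gamma", 20.0)
        return SVC(kernel="rbf", probability=True, random_state=seed, **hp)
    if alg == "knn":
        return KNeighborsClassifier(**hp)
    if alg == "logistic":
        hp.setdefault("max_iter", 2000)
        return LogisticRegression(**hp)
    raise ValueError(f"unsupported algorithm {alg!r}")


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------


def stratified_folds(
    labels, k: int, seed: int | None = None
) -> list[tuple[np.ndarray, np.ndarray]]:
    """k disjoint stratified test folds covering all samples.

    Per-class counts in each fold are within +-1 of proportional. Errors when
    k exceeds the smallest class count.
    """
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if k > counts.min():
        raise ValueError(
            f"k={k} exceeds the smallest class count ({counts.min()})"
        )
    rng = np.random.default_rng(seed)
    fold_members: list[list[int]] = [[] for _ in range(k)]
    for c in classes:
        idx = np.flatnonzero(labels == c)
        rng.shuffle(idx)
        for pos, i in enumerate(idx):
            fold_members[pos % k].append(int(i))
    all_idx = np.arange(len(labels))
    folds = []
    for members in fold_members:
        test = np.sort(np.array(members, dtype=int))
        train = np.setdiff1d(all_idx, test)
        folds.append((train, test))
    return folds


def train_test_split(
    table: pd.DataFrame,
    test_fraction: float = 0.2,
    seed: int | None = 42,
    stratify: str = "label",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stratified train/test split (default 80:20, seed 42).

    Total test size is ``ceil(test_fraction * n)``; per-class quotas are
    allocated proportionally with largest-remainder rounding.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must be in (0, 1)")
    n = len(table)
    labels = table[stratify].to_numpy()
    classes, counts = np.unique(labels, return_counts=True)
    n_test = ceil(test_fraction * n)
    raw = n_test * counts / n
    quota = np.floor(raw).astype(int)
    remainder = raw - quota
    for i in np.argsort(-remainder)[: n_test - quota.sum()]:
        quota[i] += 1
    rng = np.random.default_rng(seed)
    test_idx: list[int] = []
    for c, q in zip(classes, quota):
        idx = np.flatnonzero(labels == c)
        rng.shuffle(idx)
        test_idx.extend(idx[:q].tolist())
        if q == 0 or q == len(idx):
            warnings.warn(
                f"class {c} absent from one side of the split", stacklevel=2
            )
    test_idx = np.sort(np.array(test_idx, dtype=int))
    train_idx = np.setdiff1d(np.arange(n), test_idx)
    return table.iloc[train_idx], table.iloc[test_idx]


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


def fit_predict(
    spec: ModelSpec,
    train_features: np.ndarray,
    train_labels: np.ndarray,
    eval_features: np.ndarray,
    unlabeled_features: np.ndarray | None = None,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Train one spec and score evaluation rows.

    Returns (classes, score matrix with rows summing to 1, hard labels).
    Semi-supervised spreading additionally consumes the unlabeled block
    (class-2 rows) with labels masked to -1.
    """
    train_features = np.asarray(train_features, float)
    train_labels = np.asarray(train_labels)
    if len(np.unique(train_labels)) < 2:
        raise ValueError("training labels are a single class")
    est = build_estimator(spec, seed)
    if spec.algorithm == "semi_supervised_spreading":
        if unlabeled_features is not None and len(unlabeled_features):
            x = np.vstack([train_features, np.asarray(unlabeled_features, float)])
            y = np.concatenate(
                [train_labels, -np.ones(len(unlabeled_features), dtype=int)]
            )
        else:
            x, y = train_features, train_labels
        est.fit(x, y)
    else:
        est.fit(train_features, train_labels)
    scores = est.predict_proba(np.asarray(eval_features, float))
    scores = np.clip(scores, 0.0, None)
    row_sums = scores.sum(axis=1, keepdims=True)
    row_sums[row_sums == 0] = 1.0
    scores = scores / row_sums
    classes = np.asarray(est.classes_)
    hard = classes[np.argmax(scores, axis=1)]
    return classes, scores, hard


def cross_validated_scores(
    features: np.ndarray,
    labels: np.ndarray,
    spec: ModelSpec,
    n_folds: int = 10,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Out-of-fold score matrix pooled over stratified folds.

    Every row is scored exactly once, by the model trained on the other
    folds. Returns (classes, scores) with scores aligned to the input rows.
    """
    features = np.asarray(features, float)
    labels = np.asarray(labels)
    folds = stratified_folds(labels, n_folds, seed)
    classes = np.unique(labels)
    scores = np.full((len(labels), len(classes)), np.nan)
    for train_idx, test_idx in folds:
        fold_classes, fold_scores, _ = fit_predict(
            spec, features[train_idx], labels[train_idx], features[test_idx], seed=seed
        )
        col = {c: i for i, c in enumerate(fold_classes)}
        for j, c in enumerate(classes):
            scores[test_idx, j] = fold_scores[:, col[c]]
    return classes, scores


# ---------------------------------------------------------------------------
# evaluation machinery
# ---------------------------------------------------------------------------


def roc_auc_ovr(
    scores: np.ndarray, labels: np.ndarray, positive_class
) -> tuple[np.ndarray, np.ndarray, float]:
    """One-vs-rest ROC by threshold sweep; trapezoidal AUC.

    ``scores`` are the positive-class scores per sample; tied scores are
    grouped into a single step.
    """
    scores = np.asarray(scores, float)
    y = (np.asarray(labels) == positive_class).astype(int)
    n_pos = y.sum()
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: labels contain a single class")
    order = np.argsort(-scores, kind="mergesort")
    s = scores[order]
    y = y[order]
    # group ties: step only where the score changes
    distinct = np.r_[np.flatnonzero(np.diff(s)), len(s) - 1]
    tp = np.cumsum(y)[distinct]
    fp = (distinct + 1) - tp
    tpr = np.r_[0.0, tp / n_pos]
    fpr = np.r_[0.0, fp / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, auc


def metrics_report(predictions, labels, classes=None) -> dict:
    """Confusion matrix, accuracy, per-class P/R/F1, macro-F1, micro-F1.

    Macro-F1 is the unweighted mean of per-class F1; micro-F1 comes from the
    pooled counts (and equals accuracy for single-label multiclass).
    """
    predictions = np.asarray(predictions)
    labels = np.asarray(labels)
    if len(predictions) != len(labels):
        raise ValueError("prediction and label vectors differ in length")
    if classes is None:
        classes = np.unique(np.concatenate([labels, predictions]))
    classes = list(classes)
    k = len(classes)
    index = {c: i for i, c in enumerate(classes)}
    cm = np.zeros((k, k), dtype=int)
    for t, p in zip(labels, predictions):
        cm[index[t], index[p]] += 1
    total = cm.sum()
    accuracy = float(np.trace(cm) / total) if total else float("nan")
    per_class = {}
    f1s = []
    for c in classes:
        i = index[c]
        tp = cm[i, i]
        fp = cm[:, i].sum() - tp
        fn = cm[i, :].sum() - tp
        if tp + fp == 0:
            warnings.warn(f"class {c} has zero predicted positives", stacklevel=2)
            precision = 0.0
        else:
            precision = tp / (tp + fp)
        recall = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
        per_class[c] = {"precision": precision, "recall": recall, "f1": f1}
        f1s.append(f1)
    tp_all = np.trace(cm)
    micro_p = tp_all / total if total else 0.0
    micro_f1 = micro_p  # pooled FP == pooled FN in single-label multiclass
    return {
        "classes": classes,
        "confusion": pd.DataFrame(cm, index=classes, columns=classes),
        "accuracy": accuracy,
        "per_class": per_class,
        "macro_f1": float(np.mean(f1s)),
        "micro_f1": float(micro_f1),
    }


def dt_feature_importance(
    features: pd.DataFrame,
    labels,
    n_folds: int = 10,
    seed: int | None = None,
    max_depth: int = 5,
    min_samples_split: int = 20,
) -> pd.Series:
    """Gini importance from a depth-limited decision tree, averaged over
    stratified folds and normalized to sum to 1."""
    labels = np.asarray(labels)
    folds = stratified_folds(labels, n_folds, seed)
    x = features.to_numpy(float)
    acc = np.zeros(features.shape[1])
    for train_idx, _ in folds:
        tree = DecisionTreeClassifier(
            max_depth=max_depth,
            min_samples_split=min_samples_split,
            random_state=seed,
        )
        tree.fit(x[train_idx], labels[train_idx])
        acc += tree.feature_importances_
    acc /= len(folds)
    if acc.sum() > 0:
        acc /= acc.sum()
    return pd.Series(acc, index=features.columns)


# ---------------------------------------------------------------------------
# benchmark suite
# ---------------------------------------------------------------------------


@dataclass
class EvaluationReport:
    model: str
    roc: dict  # class -> (fpr, tpr, auc)
    macro_auc: float
    confusion: pd.DataFrame
    accuracy: float
    per_class: dict
    macro_f1: float
    micro_f1: float
    importances: pd.Series | None = None

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "auc_per_class": {str(c): v[2] for c, v in self.roc.items()},
            "macro_auc": self.macro_auc,
            "accuracy": self.accuracy,
            "per_class": {
                str(c): v for c, v in self.per_class.items()
            },
            "macro_f1": self.macro_f1,
            "micro_f1": self.micro_f1,
            "confusion": self.confusion.to_dict(),
            "importances": (
                None if self.importances is None else self.importances.to_dict()
            ),
        }


@dataclass
class SuiteConfig:
    """Protocol settings for the benchmark run."""

    protocol: str = "leakage_safe"  # or "paper_compat" (balance before split)
    test_fraction: float = 0.2
    split_seed: int = 42
    seed: int = 0
    smote_k: int = 5
    external_thresholds: dict = field(default_factory=dict)
    default_threshold: float = 0.5


def evaluate_model(
    spec: ModelSpec,
    train: pd.DataFrame,
    test: pd.DataFrame,
    feature_cols: list[str],
    unlabeled: pd.DataFrame | None = None,
    seed: int | None = None,
) -> EvaluationReport:
    """Fit one spec on train, evaluate on test; full report."""
    xu = (
        unlabeled[feature_cols].to_numpy(float)
        if unlabeled is not None and len(unlabeled)
        else None
    )
    classes, scores, hard = fit_predict(
        spec,
        train[feature_cols].to_numpy(float),
        train["label"].to_numpy(),
        test[feature_cols].to_numpy(float),
        unlabeled_features=xu,
        seed=seed,
    )
    y_test = test["label"].to_numpy()
    roc = {}
    aucs = []
    for i, c in enumerate(classes):
        if (y_test == c).any() and (y_test != c).any():
            fpr, tpr, auc = roc_auc_ovr(scores[:, i], y_test, c)
            roc[int(c)] = (fpr, tpr, auc)
            aucs.append(auc)
    metrics = metrics_report(hard, y_test, classes=list(classes))
    importances = None
    if spec.algorithm in ("random_forest", "decision_tree", "gradient_boosting"):
        est = build_estimator(spec, seed)
        est.fit(train[feature_cols].to_numpy(float), train["label"].to_numpy())
        imp = est.feature_importances_
        if imp.sum() > 0:
            imp = imp / imp.sum()
        importances = pd.Series(imp, index=feature_cols)
    return EvaluationReport(
        model=spec.algorithm,
        roc=roc,
        macro_auc=float(np.mean(aucs)) if aucs else float("nan"),
        confusion=metrics["confusion"],
        accuracy=metrics["accuracy"],
        per_class=metrics["per_class"],
        macro_f1=metrics["macro_f1"],
        micro_f1=metrics["micro_f1"],
        importances=importances,
    )


def concordance_table(
    predictions: pd.DataFrame,
    external_scores: pd.DataFrame,
    thresholds: dict | None = None,
    default_threshold: float = 0.5,
) -> pd.DataFrame:
    """Match/no-match tally of model calls on unknown variants vs benchmarks.

    ``predictions`` has columns (variant, model, predicted_class);
    ``external_scores`` is indexed by variant with one column per external
    tool, binarized at its threshold (score >= threshold -> damaging).
    A benign/damaging call matches when at least one tool agrees.
    """
    thresholds = thresholds or {}
    if external_scores.empty or not len(external_scores.columns):
        raise ValueError("external score columns required for concordance")
    calls = {}
    for tool in external_scores.columns:
        thr = thresholds.get(tool, default_threshold)
        if thr is None:
            raise ValueError(f"missing threshold for external tool {tool!r}")
        calls[tool] = (external_scores[tool] >= thr).map({True: 1, False: 0})
    call_df = pd.DataFrame(calls)
    rows = []
    for model, block in predictions.groupby("model"):
        for cls, name in ((0, "benign"), (1, "damaging")):
            sub = block[block["predicted_class"] == cls]
            matched = 0
            for _, r in sub.iterrows():
                v = r["variant"]
                if v in call_df.index and (call_df.loc[v] == cls).any():
                    matched += 1
            rows.append(
                {
                    "model": model,
                    "predicted_class": name,
                    "total": len(sub),
                    "matched": matched,
                    "unmatched": len(sub) - matched,
                }
            )
    return pd.DataFrame(rows)


def run_benchmark_suite(
    feature_table: pd.DataFrame,
    feature_cols: list[str],
    model_specs: list[ModelSpec] | None = None,
    external_scores: pd.DataFrame | None = None,
    config: SuiteConfig | None = None,
) -> tuple[dict[str, EvaluationReport], pd.DataFrame | None]:
    """Train and evaluate every spec under the configured protocol.

    ``feature_table`` holds labeled rows (labels 0/1/3) and optionally
    unknown rows (label 2), which feed the semi-supervised unlabeled block
    and the concordance analysis. Under the default leakage-safe protocol,
    SMOTE runs inside the training portion only; ``paper_compat`` balances
    first and splits afterwards.
    """
    config = config or SuiteConfig()
    model_specs = model_specs or default_model_specs()
    labeled = feature_table[feature_table["label"].isin((0, 1, 3))].reset_index(
        drop=True
    )
    unknown = feature_table[feature_table["label"] == 2].reset_index(drop=True)

    if config.protocol == "paper_compat":
        balanced = smote_balance(labeled, config.smote_k, config.seed)
        train, test = train_test_split(
            balanced, config.test_fraction, config.split_seed
        )
    elif config.protocol == "leakage_safe":
        train_raw, test = train_test_split(
            labeled, config.test_fraction, config.split_seed
        )
        train = smote_balance(
            train_raw.reset_index(drop=True), config.smote_k, config.seed
        )
    else:
        raise ValueError(f"unknown protocol {config.protocol!r}")

    reports: dict[str, EvaluationReport] = {}
    pred_rows = []
    for spec in model_specs:
        reports[spec.algorithm] = evaluate_model(
            spec, train, test, feature_cols, unlabeled=unknown, seed=config.seed
        )
        if len(unknown):
            xu = unknown[feature_cols].to_numpy(float)
            _, _, hard = fit_predict(
                spec,
                train[feature_cols].to_numpy(float),
                train["label"].to_numpy(),
                xu,
                unlabeled_features=xu
                if spec.algorithm == "semi_supervised_spreading"
                else None,
                seed=config.seed,
            )
            for v, p in zip(unknown.get("variant", unknown.index), hard):
                pred_rows.append(
                    {"variant": v, "model": spec.algorithm, "predicted_class": int(p)}
                )

    concordance = None
    if external_scores is not None and pred_rows:
        concordance = concordance_table(
            pd.DataFrame(pred_rows),
            external_scores,
            config.external_thresholds,
            config.default_threshold,
        )
    return reports, concordance
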