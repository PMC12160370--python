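"""Multiclass constitution classifiers and the evaluation metric suite.

Eight benchmark algorithms (decision tree, random forest, KNN, multinomial
logistic, elastic-net logistic, MLP, LightGBM, XGBoost) plus the fusion MLP
are trained on traditional, deep, or fused feature tables behind a uniform
probability interface.

Evaluation extends the binary confusion-count formulas to five classes
one-vs-rest: each class contributes a :class:`ConfusionCounts` from which
accuracy, precision (= PPV), sensitivity (= recall), specificity, F1, NPV,
MCC and Cohen's kappa are computed, and the macro value is the unweighted
mean over classes (NaN-producing zero denominators are excluded with a
warning).  AUC is the one-vs-rest area under the ROC curve, macro-averaged.
Cross-validation is stratified; the fold-AUC summary reports the mean and
the standard error (sample standard deviation of the fold AUCs over sqrt(k)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import KFold, StratifiedKFold, train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "ALGORITHMS",
    "ConfusionCounts",
    "MetricRecord",
    "FusionMLPSpec",
    "CVReport",
    "split_train_test",
    "train_model",
    "binary_metrics",
    "metrics",
    "auc_ovr",
    "aggregate_fold_aucs",
    "cross_validate",
    "fuse_features",
    "rank_importance",
]

ALGORITHMS = (
    "decision_tree",
    "random_forest",
    "knn",
    "multinomial_logistic",
    "elastic_net_logistic",
    "mlp",
    "gbdt_light",
    "gbdt_xgb",
)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.n < 1:
            raise ValueError("total count must be >= 1")

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricRecord:
    accuracy: float
    precision: float
    sensitivity: float
    specificity: float
    f1: float
    auc: float
    mcc: float
    kap: float
    npv: float

    @property
    def ppv(self) -> float:  # precision printed under its synonym
        return self.precision

    @property
    def recall(self) -> float:
        return self.sensitivity

    def as_dict(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy, "precision": self.precision,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "f1": self.f1, "auc": self.auc, "mcc": self.mcc, "kap": self.kap,
            "npv": self.npv,
        }


@dataclass
class FusionMLPSpec:
    n_inputs: int = 37
    hidden_sizes: tuple[int, ...] = (8, 8)
    n_outputs: int = 5
    activation: str = "relu"
    epochs: int = 200
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self):
        if self.n_inputs < 1 or self.n_outputs < 2:
            raise ValueError("need n_inputs >= 1 and n_outputs >= 2")

    def parameter_count(self) -> int:
        sizes = (self.n_inputs, *self.hidden_sizes, self.n_outputs)
        return sum(a * b + b for a, b in zip(sizes[:-1], sizes[1:]))


@dataclass
class CVReport:
    fold_metrics: list[MetricRecord]
    fold_assignments: list[np.ndarray]
    mean_auc: float
    se_auc: float


# --------------------------------------------------------------------------
# splitting / training
# --------------------------------------------------------------------------


def split_train_test(X, y, ratio: float = 0.2, stratify: bool = True, seed: int = 0):
    """Stratified train/test index split; ``ratio`` is the held-out share."""
    if not 0.0 < ratio < 1.0:
        raise ValueError("ratio must be in (0, 1)")
    y = np.asarray(y)
    idx = np.arange(len(y))
    train, test = train_test_split(
        idx, test_size=ratio, random_state=seed, stratify=y if stratify else None
    )
    return np.sort(train), np.sort(test)


class _XGBWrapper:
    """Maps arbitrary labels to 0..k-1 for xgboost and back for predictions."""

    def __init__(self, model, classes):
        self._model = model
        self.classes_ = classes

    def predict_proba(self, X):
        return self._model.predict_proba(np.asarray(X))

    def predict(self, X):
        return self.classes_[self._model.predict(np.asarray(X)).astype(int)]


def train_model(algorithm: str, X, y, params: dict | None = None, seed: int = 0):
    """Fit one of the benchmark classifiers; returns a probability model."""
    params = dict(params or {})
    Xa = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    if not np.isfinite(Xa).all():
        raise ValueError("non-finite values in X")
    if len(np.unique(y)) < 2:
        raise ValueError("y must contain at least 2 classes")
    if algorithm == "decision_tree":
        model = DecisionTreeClassifier(random_state=seed, **params)
    elif algorithm == "random_forest":
        params.setdefault("n_estimators", 200)
        model = RandomForestClassifier(random_state=seed, **params)
    elif algorithm == "knn":
        params.setdefault("n_neighbors", 5)
        model = KNeighborsClassifier(**params)
    elif algorithm == "multinomial_logistic":
        params.setdefault("max_iter", 2000)
        model = LogisticRegression(random_state=seed, **params)
    elif algorithm == "elastic_net_logistic":
        params.setdefault("l1_ratio", 0.5)
        params.setdefault("max_iter", 3000)
        model = LogisticRegression(
            penalty="elasticnet", solver="saga", random_state=seed, **params
        )
    elif algorithm == "mlp":
        spec = params.pop("spec", None)
        if spec is not None:
            params.setdefault("hidden_layer_sizes", spec.hidden_sizes)
            params.setdefault("max_iter", spec.epochs)
            params.setdefault("learning_rate_init", spec.learning_rate)
            params.setdefault("activation", spec.activation)
            seed = spec.seed
        params.setdefault("hidden_layer_sizes", (8, 8))
        params.setdefault("max_iter", 500)
        model = MLPClassifier(random_state=seed, **params)
    elif algorithm == "gbdt_light":
        from lightgbm import LGBMClassifier

        params.setdefault("n_estimators", 100)
        params.setdefault("verbose", -1)
        params.setdefault("min_child_samples", 5)  # desk-scale datasets
        model = LGBMClassifier(random_state=seed, **params)
    elif algorithm == "gbdt_xgb":
        from xgboost import XGBClassifier

        params.setdefault("n_estimators", 100)
        classes = np.unique(y)
        codes = np.searchsorted(classes, y)
        model = XGBClassifier(random_state=seed, **params)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(Xa, codes)
        return _XGBWrapper(model, classes)
    else:
        raise ValueError(f"unknown algorithm {algorithm!r}; choose from {ALGORITHMS}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # MLP convergence chatter at small max_iter
        model.fit(Xa, y)
    return model


# --------------------------------------------------------------------------
# metrics
# --------------------------------------------------------------------------


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        warnings.warn(f"{what} undefined (zero denominator); reporting NaN")
        return float("nan")
    return num / den


def binary_metrics(counts: ConfusionCounts, auc: float = float("nan")) -> MetricRecord:
    """The confusion-count formula suite for one (binary) class."""
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    n = counts.n
    accuracy = (tp + tn) / n
    precision = _safe_div(tp, tp + fp, "precision")
    sensitivity = _safe_div(tp, tp + fn, "sensitivity")
    specificity = _safe_div(tn, tn + fp, "specificity")
    f1 = (
        _safe_div(2 * precision * sensitivity, precision + sensitivity, "f1")
        if np.isfinite(precision) and np.isfinite(sensitivity)
        else float("nan")
    )
    mcc_den = np.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = _safe_div(tp * tn - fp * fn, mcc_den, "mcc")
    pe = ((tp + fp) * (tp + fn) + (tn + fp) * (tn + fn)) / n**2
    kap = _safe_div(accuracy - pe, 1.0 - pe, "kappa")
    npv = _safe_div(tn, tn + fn, "npv")
    return MetricRecord(accuracy, precision, sensitivity, specificity, f1, auc, mcc, kap, npv)


def auc_ovr(y_bin: np.ndarray, scores: np.ndarray) -> float:
    """Trapezoidal ROC area for one class (rank formulation, tie-corrected)."""
    y_bin = np.asarray(y_bin, dtype=bool)
    n_pos = int(y_bin.sum())
    n_neg = len(y_bin) - n_pos
    if n_pos == 0 or n_neg == 0:
        warnings.warn("AUC undefined for a single-class fold; reporting NaN")
        return float("nan")
    ranks = pd.Series(scores).rank(method="average").to_numpy()
    return float((ranks[y_bin].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def metrics(y_true, y_pred, y_scores=None, classes=None) -> tuple[dict, MetricRecord]:
    """Per-class one-vs-rest records plus the macro-averaged record.

    ``y_scores`` (N x K class probabilities, column order = ``classes``) is
    required for AUC; without it AUC is NaN.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred lengths differ")
    if classes is None:
        classes = np.unique(np.concatenate([y_true, y_pred]))
    per_class: dict = {}
    for k, cls in enumerate(classes):
        t = y_true == cls
        p = y_pred == cls
        counts = ConfusionCounts(
            tp=int(np.sum(p & t)), tn=int(np.sum(~p & ~t)),
            fp=int(np.sum(p & ~t)), fn=int(np.sum(~p & t)),
        )
        auc = float("nan")
        if y_scores is not None:
            auc = auc_ovr(t, np.asarray(y_scores)[:, k])
        per_class[cls] = binary_metrics(counts, auc)
    fields = list(MetricRecord.__dataclass_fields__)
    macro_vals = {}
    for f in fields:
        vals = np.array([getattr(r, f) for r in per_class.values()], dtype=float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            macro_vals[f] = float(np.nanmean(vals)) if not np.isnan(vals).all() else float("nan")
    return per_class, MetricRecord(**macro_vals)


def aggregate_fold_aucs(fold_aucs) -> tuple[float, float]:
    """Mean and standard error (sd / sqrt(k)) of per-fold AUCs."""
    a = np.asarray(fold_aucs, dtype=float)
    mean = float(a.mean())
    se = float(a.std(ddof=1) / np.sqrt(len(a))) if len(a) > 1 else 0.0
    return mean, se


def cross_validate(
    algorithm: str, X, y, k: int = 5, seed: int = 0, params: dict | None = None,
    balance=None,
) -> CVReport:
    """Stratified k-fold cross-validation with the full metric suite.

    ``balance`` (optional) is applied to the *training* portion of each fold
    only — e.g. ``lambda X, y: smote(X, y, cfg)``.
    """
    y = np.asarray(y)
    Xa = np.asarray(X, dtype=np.float64)
    if k < 2 or len(y) < k:
        raise ValueError("need k >= 2 and at least k samples")
    classes, class_counts = np.unique(y, return_counts=True)
    if k > class_counts.min():
        warnings.warn(
            f"k={k} exceeds the smallest class ({class_counts.min()}); "
            "falling back to unstratified folds"
        )
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    else:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_metrics: list[MetricRecord] = []
    assignments: list[np.ndarray] = []
    for fold, (tr, te) in enumerate(splitter.split(Xa, y)):
        Xtr, ytr = Xa[tr], y[tr]
        if balance is not None:
            Xtr, ytr = balance(Xtr, ytr)
        model = train_model(algorithm, Xtr, ytr, params, seed=seed + fold)
        proba = model.predict_proba(Xa[te])
        # align probability columns with the global class order
        proba_full = np.zeros((len(te), len(classes)))
        for j, cls in enumerate(model.classes_):
            proba_full[:, list(classes).index(cls)] = proba[:, j]
        pred = classes[proba_full.argmax(axis=1)]
        if not set(y[te]) >= set(classes):
            warnings.warn(f"fold {fold} is missing some classes; their AUC is NaN")
        _, macro = metrics(y[te], pred, proba_full, classes)
        fold_metrics.append(macro)
        assignments.append(te)
    mean_auc, se_auc = aggregate_fold_aucs([m.auc for m in fold_metrics])
    return CVReport(fold_metrics, assignments, mean_auc, se_auc)


# --------------------------------------------------------------------------
# fusion
# --------------------------------------------------------------------------


def fuse_features(
    traditional: pd.DataFrame,
    deep: pd.DataFrame,
    selected_traditional: list[str],
    selected_deep: list[str],
    demographics: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Column-wise fusion: selected traditional + demographics + selected deep.

    All inputs must share sample ids; duplicated feature names across the
    sources are rejected.
    """
    if set(traditional.index) != set(deep.index):
        raise ValueError("traditional and deep tables have different sample ids")
    parts = [traditional.loc[:, selected_traditional]]
    if demographics is not None:
        if set(demographics.index) != set(traditional.index):
            raise ValueError("demographics table has different sample ids")
        parts.append(demographics.loc[traditional.index])
    parts.append(deep.loc[traditional.index, selected_deep])
    fused = pd.concat(parts, axis=1)
    dup = fused.columns[fused.columns.duplicated()].tolist()
    if dup:
        raise ValueError(f"duplicated feature names across sources: {dup}")
    return fused


def rank_importance(
    fused: pd.DataFrame, labels, n_trees: int = 500, max_depth: int = 15, seed: int = 0
) -> list[tuple[str, float]]:
    """Random-forest Gini importance ranking of the fused features."""
    rf = RandomForestClassifier(
        n_estimators=n_trees, max_depth=max_depth, random_state=seed
    )
    rf.fit(fused.to_numpy(dtype=np.float64), np.asarray(labels))
    imp = rf.feature_importances_
    total = imp.sum()
    if total > 0:
        imp = imp / total
    order = np.argsort(-imp)
    return [(fused.columns[j], float(imp[j])) for j in order]
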