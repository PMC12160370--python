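"""Feature screening and class balancing.

Screening combines two selectors and keeps their intersection for stability:

* **LASSO** — one-vs-rest per class, the regularization strength chosen by
  10-fold cross-validation minimizing mean squared error; the selected set is
  the union over classes of features with a nonzero coefficient at the chosen
  penalty.
* **Random forest** — 500 trees of depth <= 15, Gini splitting; importance is
  the mean decrease in Gini impurity, and features above the mean importance
  are kept.  An out-of-bag error curve (overall and per class) is recorded as
  the forest grows.

Class imbalance is addressed by SMOTE: minority classes are oversampled to
the majority count with synthetic rows interpolated between a minority sample
and one of its k nearest same-class neighbours.  Originals are preserved
verbatim; apply it to training folds only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LassoCV
from sklearn.model_selection import KFold
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "SelectionConfig",
    "SelectionResult",
    "lasso_select",
    "rf_select",
    "intersect",
    "smote",
    "screen_features",
]


@dataclass
class SelectionConfig:
    lasso_cv_folds: int = 10
    lambda_grid: tuple[float, ...] | None = None  # None = automatic path
    rf_n_trees: int = 500
    rf_max_depth: int = 15
    rf_oob_curve_points: int = 5
    smote_k: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.lasso_cv_folds < 2:
            raise ValueError("lasso_cv_folds must be >= 2")
        if self.rf_n_trees < 1:
            raise ValueError("rf_n_trees must be >= 1")
        if self.lambda_grid is not None and any(l <= 0 for l in self.lambda_grid):
            raise ValueError("lambda values must be > 0")


@dataclass
class SelectionResult:
    lasso_set: list[str]
    rf_ranking: list[tuple[str, float]]
    rf_set: list[str]
    intersection: list[str]
    oob_curve: dict[str, list[float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "lasso_set": self.lasso_set,
            "rf_ranking": [[n, float(v)] for n, v in self.rf_ranking],
            "rf_set": self.rf_set,
            "intersection": self.intersection,
        }


def _feature_names(X, names) -> list[str]:
    if names is not None:
        return list(names)
    if hasattr(X, "columns"):
        return list(X.columns)
    return [f"f{i}" for i in range(np.asarray(X).shape[1])]


def lasso_select(X, y, config: SelectionConfig | None = None, feature_names=None) -> list[str]:
    """One-vs-rest cross-validated LASSO; union of nonzero supports."""
    config = config or SelectionConfig()
    names = _feature_names(X, feature_names)
    Xa = np.asarray(X, dtype=np.float64)
    ya = np.asarray(y)
    if Xa.shape[0] < config.lasso_cv_folds:
        raise ValueError("need at least as many samples as CV folds")
    selected: set[str] = set()
    for ci, cls in enumerate(np.unique(ya)):
        yb = (ya == cls).astype(np.float64)
        cv = KFold(config.lasso_cv_folds, shuffle=True, random_state=config.seed + ci)
        alphas = 100 if config.lambda_grid is None else list(config.lambda_grid)
        model = LassoCV(alphas=alphas, cv=cv, random_state=config.seed, max_iter=5000)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # convergence chatter on tiny folds
            model.fit(Xa, yb)
        selected.update(names[j] for j in np.flatnonzero(model.coef_ != 0.0))
    if not selected:
        warnings.warn("LASSO selected no features (all coefficients shrunk to zero)")
    return sorted(selected)


def rf_select(
    X, y, config: SelectionConfig | None = None, feature_names=None
) -> tuple[list[tuple[str, float]], list[str], dict[str, list[float]]]:
    """Gini-importance ranking, above-mean cutoff, and OOB error curve."""
    config = config or SelectionConfig()
    names = _feature_names(X, feature_names)
    Xa = np.asarray(X, dtype=np.float64)
    ya = np.asarray(y)
    if Xa.shape[0] < 10:
        raise ValueError("need at least 10 samples for the forest")
    classes = np.unique(ya)
    # grow the forest in steps to record the OOB error trajectory
    steps = np.unique(
        np.linspace(
            max(10, config.rf_n_trees // config.rf_oob_curve_points),
            config.rf_n_trees,
            config.rf_oob_curve_points,
            dtype=int,
        )
    )
    rf = RandomForestClassifier(
        n_estimators=1,
        max_depth=config.rf_max_depth,
        criterion="gini",
        oob_score=True,
        warm_start=True,
        bootstrap=True,
        random_state=config.seed,
    )
    curve: dict[str, list[float]] = {"n_trees": [], "oob": []}
    for c in classes:
        curve[f"oob_{c}"] = []
    for n_est in steps:
        rf.set_params(n_estimators=int(n_est))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # few-tree OOB coverage warnings
            rf.fit(Xa, ya)
        dec = rf.oob_decision_function_
        have = ~np.isnan(dec).any(axis=1)
        pred = np.full(len(ya), -1, dtype=object)
        pred[have] = classes[dec[have].argmax(axis=1)]
        curve["n_trees"].append(int(n_est))
        curve["oob"].append(float(np.mean(pred[have] != ya[have])) if have.any() else 1.0)
        for c in classes:
            sel = have & (ya == c)
            curve[f"oob_{c}"].append(
                float(np.mean(pred[sel] != ya[sel])) if sel.any() else 1.0
            )
    imp = rf.feature_importances_
    total = imp.sum()
    imp = imp / total if total > 0 else imp
    order = np.argsort(-imp)
    ranking = [(names[j], float(imp[j])) for j in order]
    cutoff = imp.mean()
    rf_set = sorted(names[j] for j in range(len(names)) if imp[j] > cutoff)
    return ranking, rf_set, curve


def intersect(result_a, result_b) -> list[str]:
    """Exact set intersection, deterministically ordered by name."""
    return sorted(set(result_a) & set(result_b))


def screen_features(X, y, config: SelectionConfig | None = None, feature_names=None) -> SelectionResult:
    """LASSO set, RF ranking, and their intersection in one pass."""
    config = config or SelectionConfig()
    names = _feature_names(X, feature_names)
    lasso = lasso_select(X, y, config, names)
    ranking, rf_set, curve = rf_select(X, y, config, names)
    return SelectionResult(
        lasso_set=lasso,
        rf_ranking=ranking,
        rf_set=rf_set,
        intersection=intersect(lasso, rf_set),
        oob_curve=curve,
    )


def make_screening_benchmark(
    seed: int,
    n: int = 300,
    p: int = 60,
    k: int = 5,
    n_classes: int = 5,
    shift: float = 2.0,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Planted-feature benchmark table for screening tests.

    The first ``k`` features carry class-conditional mean shifts (each with
    its own standardized offset pattern across classes, amplitude ``shift``
    in units of the noise standard deviation); the rest are pure noise.
    Returns (X, y, names of the planted features).
    """
    r = np.random.default_rng(seed)
    y = r.integers(0, n_classes, n)
    X = r.normal(size=(n, p))
    pattern = r.normal(0.0, 1.0, (n_classes, k))
    pattern = (pattern - pattern.mean(axis=0)) / pattern.std(axis=0)
    X[:, :k] += shift * pattern[y]
    return X, y, [f"f{i}" for i in range(k)]


def smote(X, y, config: SelectionConfig | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Oversample every minority class to the majority count.

    Synthetic rows are convex combinations x_i + u * (x_nn - x_i) with
    u ~ U(0, 1), where x_nn is one of the k nearest same-class neighbours of
    x_i.  Original rows are returned first, unchanged.  When a class has
    fewer than k+1 members, k falls back to (class size - 1) with a warning;
    a singleton class cannot be oversampled and is an error.
    """
    config = config or SelectionConfig()
    Xa = np.asarray(X, dtype=np.float64)
    ya = np.asarray(y)
    rng = np.random.default_rng(config.seed)
    classes, counts = np.unique(ya, return_counts=True)
    target = counts.max()
    new_X, new_y = [Xa], [ya]
    for cls, count in zip(classes, counts):
        deficit = int(target - count)
        if deficit == 0:
            continue
        if count < 2:
            raise ValueError(f"class {cls!r} has a single sample; SMOTE impossible")
        k = config.smote_k
        if count < k + 1:
            k = int(count - 1)
            warnings.warn(f"class {cls!r} has {count} samples; reducing k to {k}")
        Xc = Xa[ya == cls]
        nn = NearestNeighbors(n_neighbors=k + 1).fit(Xc)
        _, idx = nn.kneighbors(Xc)  # column 0 is the point itself
        base = rng.integers(0, len(Xc), size=deficit)
        pick = rng.integers(1, k + 1, size=deficit)
        gap = rng.random(deficit)
        neigh = idx[base, pick]
        synth = Xc[base] + gap[:, None] * (Xc[neigh] - Xc[base])
        new_X.append(synth)
        new_y.append(np.full(deficit, cls, dtype=ya.dtype))
    return np.concatenate(new_X, axis=0), np.concatenate(new_y, axis=0)
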