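"""Random forest with deep decision trees (RFDDT), built from scratch.

Each of ``n_trees`` trees is grown on a bootstrap sample of the training
set.  At every node the best Gini-impurity split is chosen among
``ceil(sqrt(p))`` randomly selected features, with candidate thresholds at
the midpoints between sorted unique feature values.  Trees are "deep": by
default there is no depth cap and ``min_samples_leaf = 1``, so each tree
grows to purity.  Prediction is a majority vote across trees; ties break to
the lexicographically smallest class label.

Also provides one-vs-rest confusion counting, the percentage metrics

    accuracy    = (TP + TN) / (TP + TN + FP + FN) * 100
    sensitivity = TP / (TP + FN) * 100
    specificity = TN / (TN + FP) * 100

and a cross-validated multi-classifier benchmark harness into which any
estimator with a ``fit``/``predict`` contract can be plugged.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .errors import (
    EmptyDatasetError,
    ShapeError,
    StratificationError,
)

__all__ = [
    "Dataset",
    "RfddtParams",
    "ForestModel",
    "RfddtClassifier",
    "ConfusionMatrix",
    "fit_rfddt",
    "predict",
    "confusion",
    "metrics",
    "Metrics",
    "benchmark",
    "bootstrap_indices",
]


@dataclass
class Dataset:
    """Feature matrix plus class labels."""

    X: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        self.y = np.asarray(self.y)
        if self.X.ndim != 2:
            raise ShapeError("X must be 2-D (n_samples, n_features)")
        if self.y.shape != (self.X.shape[0],):
            raise ShapeError("y length must match X rows")
        if self.X.shape[0] == 0:
            raise EmptyDatasetError("dataset has no samples")
        if not np.all(np.isfinite(self.X)):
            raise ShapeError("X contains non-finite entries")


@dataclass(frozen=True)
class RfddtParams:
    """Forest hyperparameters; max_depth=None means unbounded ("deep")."""

    n_trees: int = 100
    max_depth: Optional[int] = None
    min_samples_leaf: int = 1
    features_per_split: Optional[int] = None  # default ceil(sqrt(p))


@dataclass
class _Tree:
    """Flat-array binary tree: leaf nodes have feature == -1."""

    feature: np.ndarray      # int, -1 at leaves
    threshold: np.ndarray    # float
    left: np.ndarray         # int child index
    right: np.ndarray
    counts: np.ndarray       # (n_nodes, n_classes) class counts at the node
    bootstrap_seed: int
    feature_subsets: List[np.ndarray] = field(default_factory=list)

    def apply(self, X: np.ndarray) -> np.ndarray:
        """Leaf index for each row of X."""
        out = np.zeros(X.shape[0], dtype=np.int64)
        for i in range(X.shape[0]):
            node = 0
            while self.feature[node] >= 0:
                if X[i, self.feature[node]] <= self.threshold[node]:
                    node = self.left[node]
                else:
                    node = self.right[node]
            out[i] = node
        return out


def _gini_best_split(Xf: np.ndarray, y_codes: np.ndarray, n_classes: int
                     ) -> Tuple[float, float]:
    """Best (impurity_decrease_proxy, threshold) for one feature, or (-inf, nan).

    Returns the negative weighted child Gini (higher is better) so callers
    can compare across features.
    """
    order = np.argsort(Xf, kind="mergesort")
    xs = Xf[order]
    ys = y_codes[order]
    n = xs.size
    onehot = np.zeros((n, n_classes))
    onehot[np.arange(n), ys] = 1.0
    cum = np.cumsum(onehot, axis=0)
    total = cum[-1]
    boundaries = np.nonzero(np.diff(xs) > 0)[0]  # split after index b
    if boundaries.size == 0:
        return -math.inf, math.nan
    nl = (boundaries + 1).astype(np.float64)
    nr = n - nl
    left_counts = cum[boundaries]
    right_counts = total[None, :] - left_counts
    gl = 1.0 - np.sum((left_counts / nl[:, None]) ** 2, axis=1)
    gr = 1.0 - np.sum((right_counts / nr[:, None]) ** 2, axis=1)
    weighted = (nl * gl + nr * gr) / n
    k = int(np.argmin(weighted))
    thr = 0.5 * (xs[boundaries[k]] + xs[boundaries[k] + 1])
    return -float(weighted[k]), float(thr)


def _grow_tree(X: np.ndarray, y_codes: np.ndarray, n_classes: int,
               params: RfddtParams, rng: np.random.Generator,
               bootstrap_seed: int) -> _Tree:
    p = X.shape[1]
    mtry = params.features_per_split or int(math.ceil(math.sqrt(p)))
    mtry = min(mtry, p)

    feature: List[int] = []
    threshold: List[float] = []
    left: List[int] = []
    right: List[int] = []
    counts: List[np.ndarray] = []
    subsets: List[np.ndarray] = []

    def new_node() -> int:
        feature.append(-1)
        threshold.append(math.nan)
        left.append(-1)
        right.append(-1)
        counts.append(np.zeros(n_classes))
        return len(feature) - 1

    root = new_node()
    stack = [(root, np.arange(X.shape[0]), 0)]
    while stack:
        node, idx, depth = stack.pop()
        cnt = np.bincount(y_codes[idx], minlength=n_classes).astype(np.float64)
        counts[node] = cnt
        pure = np.count_nonzero(cnt) <= 1
        depth_cap = params.max_depth is not None and depth >= params.max_depth
        if pure or depth_cap or idx.size < 2 * params.min_samples_leaf:
            continue
        feats = rng.choice(p, size=mtry, replace=False)
        subsets.append(np.sort(feats))
        best = (-math.inf, math.nan, -1)
        for f in feats:
            score, thr = _gini_best_split(X[idx, f], y_codes[idx], n_classes)
            if score > best[0]:
                best = (score, thr, int(f))
        if best[2] < 0:
            continue  # no valid split (all candidate features constant)
        _, thr, f = best
        mask = X[idx, f] <= thr
        li, ri = idx[mask], idx[~mask]
        if li.size < params.min_samples_leaf or ri.size < params.min_samples_leaf:
            continue
        feature[node] = f
        threshold[node] = thr
        lnode, rnode = new_node(), new_node()
        left[node], right[node] = lnode, rnode
        stack.append((rnode, ri, depth + 1))
        stack.append((lnode, li, depth + 1))
    return _Tree(
        feature=np.asarray(feature, dtype=np.int64),
        threshold=np.asarray(threshold, dtype=np.float64),
        left=np.asarray(left, dtype=np.int64),
        right=np.asarray(right, dtype=np.int64),
        counts=np.asarray(counts, dtype=np.float64),
        bootstrap_seed=bootstrap_seed,
        feature_subsets=subsets,
    )


def bootstrap_indices(n: int, seed: int) -> np.ndarray:
    """The bootstrap sample (size n, with replacement) a tree seed produces."""
    return np.random.default_rng(seed).integers(0, n, size=n)


@dataclass
class ForestModel:
    """A trained RFDDT ensemble."""

    trees: List[_Tree]
    classes: np.ndarray
    n_features: int
    params: RfddtParams
    seed: int

    @property
    def n_trees(self) -> int:
        return len(self.trees)

    def to_json(self) -> str:
        def tree_dict(t: _Tree) -> dict:
            return {
                "feature": t.feature.tolist(),
                "threshold": [None if math.isnan(v) else v for v in t.threshold],
                "left": t.left.tolist(),
                "right": t.right.tolist(),
                "counts": t.counts.tolist(),
                "bootstrap_seed": t.bootstrap_seed,
            }
        return json.dumps({
            "format": "ecgkit-forest",
            "version": 1,
            "classes": [str(c) for c in self.classes],
            "n_features": self.n_features,
            "seed": self.seed,
            "params": {"n_trees": self.params.n_trees,
                       "max_depth": self.params.max_depth,
                       "min_samples_leaf": self.params.min_samples_leaf,
                       "features_per_split": self.params.features_per_split},
            "trees": [tree_dict(t) for t in self.trees],
        })

    @classmethod
    def from_json(cls, text: str) -> "ForestModel":
        obj = json.loads(text)
        if obj.get("format") != "ecgkit-forest":
            raise ShapeError("not an ecgkit forest model file")
        params = RfddtParams(**obj["params"])
        trees = [
            _Tree(
                feature=np.asarray(t["feature"], dtype=np.int64),
                threshold=np.asarray([math.nan if v is None else v
                                      for v in t["threshold"]], dtype=np.float64),
                left=np.asarray(t["left"], dtype=np.int64),
                right=np.asarray(t["right"], dtype=np.int64),
                counts=np.asarray(t["counts"], dtype=np.float64),
                bootstrap_seed=int(t["bootstrap_seed"]),
            )
            for t in obj["trees"]
        ]
        return cls(trees=trees, classes=np.asarray(obj["classes"]),
                   n_features=int(obj["n_features"]), params=params,
                   seed=int(obj["seed"]))


def fit_rfddt(data: Dataset, params: Optional[RfddtParams] = None,
              seed: int = 0) -> ForestModel:
    """Train an RFDDT forest; deterministic for a fixed seed.

    Single-class data yields a degenerate constant predictor with a warning.
    """
    params = params or RfddtParams()
    classes, y_codes = np.unique(data.y, return_counts=False), None
    classes = np.sort(classes)
    y_codes = np.searchsorted(classes, data.y)
    n, p = data.X.shape
    if classes.size < 2:
        warnings.warn("training data has a single class; returning a constant predictor")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(params.n_trees)
    trees: List[_Tree] = []
    for child in children:
        rng = np.random.default_rng(child)
        boot_seed = int(rng.integers(0, 2**31 - 1))
        idx = bootstrap_indices(n, boot_seed)
        tree = _grow_tree(data.X[idx], y_codes[idx], classes.size, params, rng,
                          bootstrap_seed=boot_seed)
        trees.append(tree)
    return ForestModel(trees=trees, classes=classes, n_features=p,
                       params=params, seed=seed)


def predict(model: ForestModel, X: np.ndarray) -> np.ndarray:
    """Majority vote over trees; ties go to the lexicographically smallest label."""
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] != model.n_features:
        raise ShapeError(
            f"X must have {model.n_features} features, got shape {X.shape}")
    votes = np.zeros((X.shape[0], model.classes.size))
    for tree in model.trees:
        leaves = tree.apply(X)
        cls = np.argmax(tree.counts[leaves], axis=1)
        votes[np.arange(X.shape[0]), cls] += 1.0
    # argmax on the sorted class axis returns the first (lexicographically
    # smallest) label among tied vote counts
    return model.classes[np.argmax(votes, axis=1)]


class RfddtClassifier:
    """sklearn-style wrapper so the forest plugs into the benchmark harness."""

    def __init__(self, params: Optional[RfddtParams] = None, seed: int = 0):
        self.params = params or RfddtParams()
        self.seed = seed
        self.model_: Optional[ForestModel] = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "RfddtClassifier":
        self.model_ = fit_rfddt(Dataset(X, y), self.params, self.seed)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self.model_ is None:
            raise ShapeError("classifier is not fitted")
        return predict(self.model_, X)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionMatrix:
    """One-vs-rest counts for a designated positive class."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion(y_true: Sequence, y_pred: Sequence, positive_class) -> ConfusionMatrix:
    """One-vs-rest confusion counts for ``positive_class``."""
    yt = np.asarray(y_true)
    yp = np.asarray(y_pred)
    if yt.shape != yp.shape:
        raise ShapeError("y_true and y_pred must have equal length")
    pos_t = yt == positive_class
    pos_p = yp == positive_class
    return ConfusionMatrix(
        tp=int(np.count_nonzero(pos_t & pos_p)),
        fp=int(np.count_nonzero(~pos_t & pos_p)),
        fn=int(np.count_nonzero(pos_t & ~pos_p)),
        tn=int(np.count_nonzero(~pos_t & ~pos_p)),
    )


@dataclass(frozen=True)
class Metrics:
    """Accuracy / sensitivity / specificity, in percent; NaN where undefined."""

    accuracy: float
    sensitivity: float
    specificity: float

    def as_tuple(self) -> Tuple[float, float, float]:
        return (self.accuracy, self.sensitivity, self.specificity)


def metrics(cm: ConfusionMatrix) -> Metrics:
    """Percentage metrics from a confusion matrix.

    Undefined ratios (zero denominator) are reported as NaN; an all-zero
    matrix is rejected.
    """
    if cm.n == 0:
        raise EmptyDatasetError("confusion matrix has no counts")
    acc = (cm.tp + cm.tn) / cm.n * 100.0
    sen = cm.tp / (cm.tp + cm.fn) * 100.0 if (cm.tp + cm.fn) else math.nan
    spe = cm.tn / (cm.tn + cm.fp) * 100.0 if (cm.tn + cm.fp) else math.nan
    return Metrics(accuracy=acc, sensitivity=sen, specificity=spe)


def macro_metrics(y_true: Sequence, y_pred: Sequence) -> Metrics:
    """One-vs-rest metrics per class, macro-averaged (NaN-safe)."""
    classes = np.unique(np.asarray(y_true))
    per = [metrics(confusion(y_true, y_pred, c)) for c in classes]
    def _avg(vals):
        vals = [v for v in vals if not math.isnan(v)]
        return float(np.mean(vals)) if vals else math.nan
    return Metrics(
        accuracy=_avg([m.accuracy for m in per]),
        sensitivity=_avg([m.sensitivity for m in per]),
        specificity=_avg([m.specificity for m in per]),
    )


# ---------------------------------------------------------------------------
# Benchmark harness
# ---------------------------------------------------------------------------

def default_classifier_set(seed: int = 0) -> Dict[str, object]:
    """The comparison suite: RFDDT plus standard sklearn baselines."""
    from sklearn.ensemble import (AdaBoostClassifier, BaggingClassifier,
                                  GradientBoostingClassifier)
    from sklearn.linear_model import LogisticRegression
    from sklearn.neighbors import KNeighborsClassifier
    from sklearn.svm import SVC

    return {
        "RFDDT": RfddtClassifier(seed=seed),
        "SVM": SVC(random_state=seed),
        "KNN": KNeighborsClassifier(),
        "AdaBoost": AdaBoostClassifier(random_state=seed),
        "Gradient": GradientBoostingClassifier(random_state=seed),
        "Logistic": LogisticRegression(max_iter=2000, random_state=seed),
        "Bagging": BaggingClassifier(random_state=seed),
    }


def benchmark(classifier_set: Dict[str, object], data: Dataset,
              cv_folds: int = 5, seed: int = 0):
    """Stratified k-fold cross-validated comparison grid.

    Predictions are pooled across folds per classifier and scored with
    macro-averaged one-vs-rest accuracy/sensitivity/specificity (percent).
    Returns a pandas DataFrame with one row per classifier.
    """
    import pandas as pd
    from sklearn.model_selection import StratifiedKFold

    if not classifier_set:
        raise EmptyDatasetError("classifier_set is empty")
    if cv_folds < 2:
        raise StratificationError("need at least 2 folds")
    _, counts = np.unique(data.y, return_counts=True)
    if cv_folds > int(counts.min()):
        raise StratificationError(
            f"{cv_folds} folds exceed the smallest class size {int(counts.min())}")
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    rows = {}
    for name, clf in classifier_set.items():
        y_pred = np.empty(data.y.shape, dtype=data.y.dtype)
        for train, test in skf.split(data.X, data.y):
            import copy
            c = copy.deepcopy(clf)
            c.fit(data.X[train], data.y[train])
            y_pred[test] = c.predict(data.X[test])
        m = macro_metrics(data.y, y_pred)
        rows[name] = {"accuracy": m.accuracy, "sensitivity": m.sensitivity,
                      "specificity": m.specificity}
    return pd.DataFrame.from_dict(rows, orient="index",
                                  columns=["accuracy", "sensitivity", "specificity"])
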