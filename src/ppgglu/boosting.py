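"""From-scratch regression models mapping PPG features to blood glucose.

The centrepiece is a squared-loss gradient-boosted decision-tree regressor
(GBDT): an initial constant prediction (the training mean) plus N shallow
CART trees, each fit to the residuals of the model so far and added with a
learning rate.  Per-round residual vectors are retained for diagnostics.
The baselines (linear, ridge, k-nearest-neighbours, a single tree, bagged
trees and a random forest) are implemented here as well, so model
comparisons never depend on an external learning library.

Determinism: all split searches use midpoint thresholds between consecutive
sorted unique values, the best split maximises variance reduction, and ties
are broken by lowest feature index then lowest threshold.  Stochastic models
(bagging, random forest) are seeded.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "RegressionTree",
    "GradientBoostedRegressor",
    "LinearRegressor",
    "RidgeRegressor",
    "KNNRegressor",
    "BaggedTrees",
    "fit_tree",
    "fit_gbdt",
    "predict",
    "fit_baseline",
    "make_model",
    "benchmark_models",
    "calibrate_personal",
    "save_model",
    "load_model",
    "BASELINE_NAMES",
    "UNIMPLEMENTED_MODELS",
]

#: Model names from the published comparison that this package does not
#: implement (no architecture or kernel details are available for them).
UNIMPLEMENTED_MODELS = ("cnn", "svm", "adaboost", "extra_trees")

#: Physiological clipping range for glucose predictions, mmol/L.
GLUCOSE_CLIP_RANGE = (2.0, 30.0)


def _check_xy(X, y) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2:
        raise ValidationError(f"X must be 2-D, got shape {X.shape}")
    if len(X) != len(y):
        raise ValidationError(f"X and y length mismatch: {len(X)} vs {len(y)}")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValidationError("X and y must be finite")
    return X, y


# ---------------------------------------------------------------------------
# CART regression tree
# ---------------------------------------------------------------------------


def _best_split(
    X: np.ndarray, y: np.ndarray, feature_indices: np.ndarray, min_samples_leaf: int
) -> tuple[int, float] | None:
    """Greedy variance-reduction split over (feature, midpoint) candidates.

    Returns (feature, threshold) maximising the decrease in summed squared
    error, ties broken by lowest feature index then lowest threshold, or
    None when no admissible split exists.
    """
    n = len(y)
    best: tuple[float, int, float] | None = None  # (reduction, feature, threshold)
    sse_parent = float(np.sum(y * y) - (np.sum(y) ** 2) / n)
    # reductions closer than this are treated as exact ties, so the
    # documented tie-break (lowest feature, then lowest threshold) is not
    # upset by floating-point jitter
    tie_tol = 1e-10 * max(1.0, abs(sse_parent))
    for f in feature_indices:
        xs = X[:, f]
        order = np.argsort(xs, kind="stable")
        xs_s, ys = xs[order], y[order]
        cum = np.cumsum(ys)
        cum2 = np.cumsum(ys * ys)
        total, total2 = cum[-1], cum2[-1]
        # candidate split after position i (left = [0..i])
        sizes_l = np.arange(1, n)
        valid = (xs_s[:-1] < xs_s[1:]) & (sizes_l >= min_samples_leaf)
        valid &= (n - sizes_l) >= min_samples_leaf
        idx = np.nonzero(valid)[0]
        if len(idx) == 0:
            continue
        nl = sizes_l[idx].astype(float)
        nr = n - nl
        sse_l = cum2[idx] - cum[idx] ** 2 / nl
        sse_r = (total2 - cum2[idx]) - (total - cum[idx]) ** 2 / nr
        reductions = sse_parent - (sse_l + sse_r)
        # first candidate within tolerance of the max = lowest threshold
        k = int(np.argmax(reductions >= np.max(reductions) - tie_tol))
        red = float(reductions[k])
        thr = float(0.5 * (xs_s[idx[k]] + xs_s[idx[k] + 1]))
        if best is None or red > best[0] + tie_tol:
            best = (red, int(f), thr)
    if best is None:
        return None
    return best[1], best[2]


@dataclass
class _Node:
    feature: int = -1
    threshold: float = 0.0
    left: "_Node | None" = None
    right: "_Node | None" = None
    value: float = 0.0

    @property
    def is_leaf(self) -> bool:
        return self.left is None

    def to_dict(self) -> dict:
        if self.is_leaf:
            return {"value": self.value}
        return {
            "feature": self.feature,
            "threshold": self.threshold,
            "left": self.left.to_dict(),
            "right": self.right.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "_Node":
        if "value" in d:
            return cls(value=float(d["value"]))
        return cls(
            feature=int(d["feature"]),
            threshold=float(d["threshold"]),
            left=cls.from_dict(d["left"]),
            right=cls.from_dict(d["right"]),
        )


class RegressionTree:
    """CART regression tree with greedy variance-reduction splits.

    ``max_depth=None`` grows until leaves are pure or smaller than
    ``2 * min_samples_leaf``.  ``max_features`` subsamples candidate features
    per node ('sqrt' or an int; used by the random forest)."""

    def __init__(
        self,
        max_depth: int | None = 3,
        min_samples_leaf: int = 2,
        max_features: int | str | None = None,
        rng: np.random.Generator | None = None,
    ) -> None:
        if max_depth is not None and max_depth < 0:
            raise ValidationError(f"max_depth must be >= 0, got {max_depth}")
        if min_samples_leaf < 1:
            raise ValidationError(f"min_samples_leaf must be >= 1, got {min_samples_leaf}")
        self.max_depth = max_depth
        self.min_samples_leaf = min_samples_leaf
        self.max_features = max_features
        self.rng = rng
        self.root_: _Node | None = None
        self.n_features_: int | None = None

    def _candidate_features(self, d: int) -> np.ndarray:
        if self.max_features is None:
            return np.arange(d)
        if self.max_features == "sqrt":
            k = max(1, int(np.sqrt(d)))
        else:
            k = min(int(self.max_features), d)
        if self.rng is None or k >= d:
            return np.arange(d)
        return np.sort(self.rng.choice(d, size=k, replace=False))

    def _build(self, X: np.ndarray, y: np.ndarray, depth: int) -> _Node:
        node = _Node(value=float(np.mean(y)))
        if self.max_depth is not None and depth >= self.max_depth:
            return node
        if len(y) < 2 * self.min_samples_leaf or np.ptp(y) == 0:
            return node
        split = _best_split(X, y, self._candidate_features(X.shape[1]), self.min_samples_leaf)
        if split is None:
            return node
        f, thr = split
        mask = X[:, f] <= thr
        if mask.all() or not mask.any():
            # degenerate split from float midpoint rounding between two
            # adjacent representable values
            return node
        node.feature, node.threshold = f, thr
        node.left = self._build(X[mask], y[mask], depth + 1)
        node.right = self._build(X[~mask], y[~mask], depth + 1)
        return node

    def fit(self, X, y) -> "RegressionTree":
        X, y = _check_xy(X, y)
        if len(y) == 0:
            raise ValidationError("cannot fit a tree on zero samples")
        self.n_features_ = X.shape[1]
        self.root_ = self._build(X, y, depth=0)
        return self

    def predict(self, X) -> np.ndarray:
        if self.root_ is None:
            raise ValidationError("tree is not fitted")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_:
            raise ValidationError(
                f"expected {self.n_features_} features, got shape {X.shape}"
            )
        out = np.empty(len(X))
        for i, row in enumerate(X):
            node = self.root_
            while not node.is_leaf:
                node = node.left if row[node.feature] <= node.threshold else node.right
            out[i] = node.value
        return out

    def to_dict(self) -> dict:
        return {
            "kind": "regression_tree",
            "max_depth": self.max_depth,
            "min_samples_leaf": self.min_samples_leaf,
            "n_features": self.n_features_,
            "root": self.root_.to_dict() if self.root_ else None,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RegressionTree":
        tree = cls(max_depth=d["max_depth"], min_samples_leaf=d["min_samples_leaf"])
        tree.n_features_ = d["n_features"]
        tree.root_ = _Node.from_dict(d["root"]) if d["root"] else None
        return tree


# ---------------------------------------------------------------------------
# Gradient boosting
# ---------------------------------------------------------------------------


class GradientBoostedRegressor:
    """Residual-boosting tree ensemble for squared loss.

    prediction(x) = F0 + learning_rate * sum_k T_k(x), with F0 the training
    mean and each T_k a CART tree fit to the residuals r_k = y - F_{k-1}(X).
    ``residual_log_`` keeps r_1..r_N; ``train_mse_`` the per-round training
    MSE, which is non-increasing for learning rates in (0, 1].
    """

    def __init__(
        self,
        n_rounds: int = 200,
        learning_rate: float = 0.1,
        max_depth: int | None = 3,
        min_samples_leaf: int = 2,
        clip_predictions: bool = False,
    ) -> None:
        if not isinstance(n_rounds, (int, np.integer)) or n_rounds < 0:
            raise ValidationError(f"n_rounds must be an integer >= 0, got {n_rounds}")
        if not 0 < learning_rate <= 1:
            raise ValidationError(f"learning_rate must be in (0, 1], got {learning_rate}")
        self.n_rounds = int(n_rounds)
        self.learning_rate = learning_rate
        self.max_depth = max_depth
        self.min_samples_leaf = min_samples_leaf
        self.clip_predictions = clip_predictions
        self.f0_: float | None = None
        self.trees_: list[RegressionTree] = []
        self.residual_log_: list[np.ndarray] = []
        self.train_mse_: list[float] = []
        self.n_features_: int | None = None

    def fit(self, X, y) -> "GradientBoostedRegressor":
        X, y = _check_xy(X, y)
        if len(y) == 0:
            raise ValidationError("cannot fit on zero samples")
        self.n_features_ = X.shape[1]
        self.f0_ = float(np.mean(y))
        self.trees_, self.residual_log_, self.train_mse_ = [], [], []
        current = np.full(len(y), self.f0_)
        for _ in range(self.n_rounds):
            residual = y - current
            self.residual_log_.append(residual.copy())
            tree = RegressionTree(self.max_depth, self.min_samples_leaf)
            tree.fit(X, residual)
            current = current + self.learning_rate * tree.predict(X)
            self.trees_.append(tree)
            self.train_mse_.append(float(np.mean((y - current) ** 2)))
        return self

    def predict(self, X) -> np.ndarray:
        if self.f0_ is None:
            raise ValidationError("model is not fitted")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_:
            raise ValidationError(
                f"expected {self.n_features_} features, got shape {X.shape}"
            )
        out = np.full(len(X), self.f0_)
        for tree in self.trees_:
            out = out + self.learning_rate * tree.predict(X)
        if self.clip_predictions:
            out = np.clip(out, *GLUCOSE_CLIP_RANGE)
        return out

    def to_dict(self) -> dict:
        return {
            "kind": "gbdt",
            "f0": self.f0_,
            "learning_rate": self.learning_rate,
            "n_rounds": self.n_rounds,
            "max_depth": self.max_depth,
            "min_samples_leaf": self.min_samples_leaf,
            "clip_predictions": self.clip_predictions,
            "n_features": self.n_features_,
            "trees": [t.to_dict() for t in self.trees_],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GradientBoostedRegressor":
        model = cls(
            n_rounds=d["n_rounds"],
            learning_rate=d["learning_rate"],
            max_depth=d["max_depth"],
            min_samples_leaf=d["min_samples_leaf"],
            clip_predictions=d.get("clip_predictions", False),
        )
        model.f0_ = d["f0"]
        model.n_features_ = d["n_features"]
        model.trees_ = [RegressionTree.from_dict(t) for t in d["trees"]]
        return model


# ---------------------------------------------------------------------------
# Baselines
# ---------------------------------------------------------------------------


class LinearRegressor:
    """Ordinary least squares via the normal equations (lstsq)."""

    def __init__(self) -> None:
        self.coef_: np.ndarray | None = None
        self.intercept_: float | None = None

    def fit(self, X, y) -> "LinearRegressor":
        X, y = _check_xy(X, y)
        A = np.column_stack([np.ones(len(X)), X])
        beta, *_ = np.linalg.lstsq(A, y, rcond=None)
        self.intercept_ = float(beta[0])
        self.coef_ = beta[1:]
        return self

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return self.intercept_ + X @ self.coef_


class RidgeRegressor:
    """L2-penalised least squares; the intercept is not penalised."""

    def __init__(self, alpha: float = 1.0) -> None:
        if alpha < 0:
            raise ValidationError(f"alpha must be >= 0, got {alpha}")
        self.alpha = alpha
        self.coef_: np.ndarray | None = None
        self.intercept_: float | None = None

    def fit(self, X, y) -> "RidgeRegressor":
        X, y = _check_xy(X, y)
        A = np.column_stack([np.ones(len(X)), X])
        penalty = self.alpha * np.eye(A.shape[1])
        penalty[0, 0] = 0.0
        beta = np.linalg.solve(A.T @ A + penalty, A.T @ y)
        self.intercept_ = float(beta[0])
        self.coef_ = beta[1:]
        return self

    predict = LinearRegressor.predict


class KNNRegressor:
    """Mean of the k nearest training responses by Euclidean distance.

    Distance ties are broken by training-row order (stable sort)."""

    def __init__(self, k: int = 5) -> None:
        if k < 1:
            raise ValidationError(f"k must be >= 1, got {k}")
        self.k = k
        self.X_: np.ndarray | None = None
        self.y_: np.ndarray | None = None

    def fit(self, X, y) -> "KNNRegressor":
        self.X_, self.y_ = _check_xy(X, y)
        if self.k > len(self.y_):
            raise ValidationError(f"k={self.k} exceeds n={len(self.y_)}")
        return self

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        out = np.empty(len(X))
        for i, row in enumerate(X):
            d2 = np.sum((self.X_ - row) ** 2, axis=1)
            nearest = np.argsort(d2, kind="stable")[: self.k]
            out[i] = float(np.mean(self.y_[nearest]))
        return out


class BaggedTrees:
    """Trees on bootstrap resamples; the random forest additionally samples
    sqrt(d) candidate features per split."""

    def __init__(
        self,
        n_estimators: int = 100,
        max_depth: int | None = None,
        min_samples_leaf: int = 2,
        max_features: int | str | None = None,
        seed: int | None = None,
    ) -> None:
        if n_estimators < 1:
            raise ValidationError(f"n_estimators must be >= 1, got {n_estimators}")
        self.n_estimators = n_estimators
        self.max_depth = max_depth
        self.min_samples_leaf = min_samples_leaf
        self.max_features = max_features
        self.seed = seed
        self.trees_: list[RegressionTree] = []
        self.n_features_: int | None = None

    def fit(self, X, y) -> "BaggedTrees":
        X, y = _check_xy(X, y)
        rng = np.random.default_rng(self.seed)
        n = len(y)
        self.n_features_ = X.shape[1]
        self.trees_ = []
        for _ in range(self.n_estimators):
            idx = rng.integers(0, n, size=n)
            tree = RegressionTree(
                self.max_depth, self.min_samples_leaf, self.max_features, rng=rng
            )
            tree.fit(X[idx], y[idx])
            self.trees_.append(tree)
        return self

    def predict(self, X) -> np.ndarray:
        if not self.trees_:
            raise ValidationError("model is not fitted")
        return np.mean([t.predict(X) for t in self.trees_], axis=0)


# ---------------------------------------------------------------------------
# Functional surface
# ---------------------------------------------------------------------------


def fit_tree(X, y, max_depth: int | None = 3, min_samples_leaf: int = 2) -> RegressionTree:
    return RegressionTree(max_depth=max_depth, min_samples_leaf=min_samples_leaf).fit(X, y)


def fit_gbdt(
    X,
    y,
    n_rounds: int = 200,
    learning_rate: float = 0.1,
    max_depth: int | None = 3,
    min_samples_leaf: int = 2,
) -> GradientBoostedRegressor:
    return GradientBoostedRegressor(
        n_rounds=n_rounds,
        learning_rate=learning_rate,
        max_depth=max_depth,
        min_samples_leaf=min_samples_leaf,
    ).fit(X, y)


def predict(model, X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if len(X) == 0:
        return np.empty(0)
    return model.predict(X)


BASELINE_NAMES = ("linear", "ridge", "knn", "dtr", "rfr", "bagging")


def fit_baseline(name: str, X, y, seed: int | None = None, **params):
    """Fit one of the named baseline models (seeded where stochastic)."""
    model = make_model(name, seed=seed, **params)
    return model.fit(X, y)


def make_model(name: str, seed: int | None = None, **params):
    """Factory for all implemented models ('gbdt' plus the baselines)."""
    builders = {
        "gbdt": lambda: GradientBoostedRegressor(**params),
        "linear": lambda: LinearRegressor(**params),
        "ridge": lambda: RidgeRegressor(**params),
        "knn": lambda: KNNRegressor(**params),
        "dtr": lambda: RegressionTree(**{"max_depth": None, **params}),
        "rfr": lambda: BaggedTrees(**{"max_features": "sqrt", "seed": seed, **params}),
        "bagging": lambda: BaggedTrees(**{"seed": seed, **params}),
    }
    if name not in builders:
        raise ValidationError(
            f"unknown model {name!r}; options: " + ", ".join(sorted(builders))
        )
    return builders[name]()


def benchmark_models(
    X,
    y,
    test_fraction: float = 0.25,
    seed: int | None = None,
    models: Sequence[str] = ("gbdt",) + BASELINE_NAMES,
    model_params: dict[str, dict] | None = None,
) -> pd.DataFrame:
    """Held-out metric table (MSE, RMSE, MAE, MARD, R2) per model.

    One random train/test split (seeded); one row per implemented model.
    Models from the published comparison without enough detail to implement
    (see :data:`UNIMPLEMENTED_MODELS`) are simply not rows in this table.
    """
    from .evaluation import compute_metrics

    X, y = _check_xy(X, y)
    if len(y) < 20:
        raise ValidationError(f"need >= 20 rows to benchmark, got {len(y)}")
    rng = np.random.default_rng(seed)
    n_test = max(1, int(round(test_fraction * len(y))))
    perm = rng.permutation(len(y))
    test_idx, train_idx = perm[:n_test], perm[n_test:]
    model_params = model_params or {}
    rows = {}
    for name in models:
        model = make_model(name, seed=seed, **model_params.get(name, {}))
        model.fit(X[train_idx], y[train_idx])
        report = compute_metrics(y[test_idx], model.predict(X[test_idx]))
        rows[name] = {
            "MSE": report.mse,
            "RMSE": report.rmse,
            "MAE": report.mae,
            "MARD": report.mard,
            "R2": report.r2,
        }
    return pd.DataFrame.from_dict(rows, orient="index")


# ---------------------------------------------------------------------------
# Personal calibration
# ---------------------------------------------------------------------------


class AffineCalibratedModel:
    """Population model with an affine output correction y ~ a * y' + b."""

    def __init__(self, base, scale: float, offset: float) -> None:
        self.base = base
        self.scale = scale
        self.offset = offset

    def predict(self, X) -> np.ndarray:
        return self.scale * self.base.predict(X) + self.offset


class BoostCalibratedModel:
    """Population GBDT plus extra boosting rounds fit on one person's data."""

    def __init__(self, base, extra_trees: list[RegressionTree], learning_rate: float) -> None:
        self.base = base
        self.extra_trees = extra_trees
        self.learning_rate = learning_rate

    def predict(self, X) -> np.ndarray:
        out = self.base.predict(X)
        for tree in self.extra_trees:
            out = out + self.learning_rate * tree.predict(X)
        return out


def calibrate_personal(
    model,
    X_personal,
    y_personal,
    strategy: str = "boost",
    n_rounds: int = 25,
    learning_rate: float | None = None,
    max_depth: int = 1,
):
    """Personalise a population model from k initial (PPG, glucose) pairs.

    ``strategy='boost'`` freezes the population trees and fits additional
    boosting rounds on the person's residuals; ``strategy='affine'`` fits an
    output correction ``a * y' + b`` (with k = 1 the slope is fixed at 1 and
    only the offset is fit).
    """
    X_personal, y_personal = _check_xy(X_personal, y_personal)
    k = len(y_personal)
    if k == 0:
        raise ValidationError("personal calibration needs at least 1 measurement")
    base_pred = model.predict(X_personal)
    if strategy == "affine":
        if k == 1 or np.ptp(base_pred) == 0:
            return AffineCalibratedModel(model, 1.0, float(np.mean(y_personal - base_pred)))
        A = np.column_stack([np.ones(k), base_pred])
        beta, *_ = np.linalg.lstsq(A, y_personal, rcond=None)
        return AffineCalibratedModel(model, float(beta[1]), float(beta[0]))
    if strategy == "boost":
        lr = learning_rate
        if lr is None:
            lr = getattr(model, "learning_rate", 0.1)
        current = base_pred.copy()
        extra = []
        for _ in range(n_rounds):
            tree = RegressionTree(max_depth=max_depth, min_samples_leaf=1)
            tree.fit(X_personal, y_personal - current)
            current = current + lr * tree.predict(X_personal)
            extra.append(tree)
        return BoostCalibratedModel(model, extra, lr)
    raise ValidationError(f"unknown calibration strategy {strategy!r} (boost | affine)")


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

_FORMAT_VERSION = 1


def save_model(model, path: str | Path, feature_names: Sequence[str] | None = None,
               seed: int | None = None) -> None:
    """Serialize a tree or GBDT model to JSON with metadata."""
    if not hasattr(model, "to_dict"):
        raise ValidationError(f"model of type {type(model).__name__} is not serializable")
    payload = {
        "format_version": _FORMAT_VERSION,
        "feature_names": list(feature_names) if feature_names else None,
        "seed": seed,
        "model": model.to_dict(),
    }
    Path(path).write_text(json.dumps(payload, sort_keys=True, indent=1))


def load_model(path: str | Path):
    payload = json.loads(Path(path).read_text())
    d = payload["model"]
    if d["kind"] == "gbdt":
        return GradientBoostedRegressor.from_dict(d)
    if d["kind"] == "regression_tree":
        return RegressionTree.from_dict(d)
    raise ValidationError(f"unknown serialized model kind {d.get('kind')!r}")
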