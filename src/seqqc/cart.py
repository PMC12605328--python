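"""Depth-limited CART with Gini-Simpson impurity, written from scratch.

A small classification tree used to predict acquisition-sequence
stability class (good/poor) from session-level image-quality metrics.
The growth procedure is deliberately conservative and fully specified so
every trained tree is auditable:

* impurity: Gini-Simpson index ``1 - sum_c p_c^2`` — the probability of
  mislabeling a randomly drawn case when labels are assigned at random
  according to the node's class distribution;
* split candidates: midpoints between consecutive sorted unique values of
  each feature; a case goes left when ``x <= threshold``;
* a split must improve the impurity (parent Gini minus the size-weighted
  child Gini) by at least ``min_improvement`` (default 0.02), the parent
  must hold at least ``min_parent`` cases (default 20) and each child at
  least ``min_child`` (default 3); the maximum depth is 2;
* ties in improvement are broken by feature order (column order of the
  training table) and then by the lower threshold; a leaf with a tied
  class vote is labeled "poor" (in a QC context, flagging is the safe
  default).

The reference tree published for T1-weighted sequence QC — narrow
left-right field of view (FOVx <= 150 mm) is poor; otherwise low
contrast-to-noise ratio (CNR <= 3.147) is poor; otherwise good — is
available via :func:`published_tree`.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from .evaluation import ConfusionTable, metrics as confusion_metrics

__all__ = [
    "GOOD",
    "POOR",
    "Split",
    "CartNode",
    "gini",
    "best_split",
    "grow",
    "published_tree",
    "cross_validate",
    "stratified_kfold_indices",
    "CartClassifier",
]

GOOD, POOR = "good", "poor"


def gini(labels: Sequence) -> float:
    """Gini-Simpson impurity ``1 - sum_c p_c^2`` of a label multiset."""
    y = np.asarray(labels)
    if y.size == 0:
        raise ValueError("Gini impurity undefined for an empty node")
    _, counts = np.unique(y, return_counts=True)
    p = counts / y.size
    return float(1.0 - np.sum(p**2))


@dataclass(frozen=True)
class Split:
    feature: str
    threshold: float
    improvement: float


def best_split(
    X: pd.DataFrame,
    y: Sequence,
    *,
    min_parent: int = 20,
    min_child: int = 3,
    min_improvement: float = 0.02,
) -> Split | None:
    """Exhaustive best binary split of a node, or ``None``.

    Scans every feature (in column order) and every midpoint between
    consecutive sorted unique values; keeps the split with the largest
    improvement ``gini(parent) - weighted gini(children)``, first
    encountered on ties.  Returns ``None`` when the parent is too small,
    no candidate satisfies ``min_child``, or the best improvement falls
    short of ``min_improvement``.
    """
    y = np.asarray(y)
    n = y.size
    if n < min_parent:
        return None
    parent = gini(y)
    best: Split | None = None
    for feature in X.columns:
        x = X[feature].to_numpy(dtype=float)
        uniq = np.unique(x)
        for lo, hi in zip(uniq[:-1], uniq[1:]):
            thr = 0.5 * (lo + hi)
            left = x <= thr
            nl = int(left.sum())
            nr = n - nl
            if nl < min_child or nr < min_child:
                continue
            child = (nl * gini(y[left]) + nr * gini(y[~left])) / n
            imp = parent - child
            if best is None or imp > best.improvement:
                best = Split(str(feature), float(thr), float(imp))
    if best is None or best.improvement < min_improvement:
        return None
    return best


@dataclass
class CartNode:
    """One node of the tree; a leaf iff it has no children."""

    prediction: str
    counts: dict[str, int] | None
    impurity: float | None
    feature: str | None = None
    threshold: float | None = None
    improvement: float | None = None
    left: "CartNode | None" = None
    right: "CartNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.left is None

    def depth(self) -> int:
        if self.is_leaf:
            return 0
        return 1 + max(self.left.depth(), self.right.depth())

    def to_dict(self) -> dict:
        d: dict = {
            "prediction": self.prediction,
            "counts": self.counts,
            "impurity": self.impurity,
        }
        if not self.is_leaf:
            d.update(
                feature=self.feature,
                threshold=self.threshold,
                improvement=self.improvement,
                left=self.left.to_dict(),
                right=self.right.to_dict(),
            )
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CartNode":
        node = cls(
            prediction=d["prediction"],
            counts=d.get("counts"),
            impurity=d.get("impurity"),
            feature=d.get("feature"),
            threshold=d.get("threshold"),
            improvement=d.get("improvement"),
        )
        if "left" in d:
            node.left = cls.from_dict(d["left"])
            node.right = cls.from_dict(d["right"])
        return node


def _majority(y: np.ndarray) -> str:
    classes, counts = np.unique(y, return_counts=True)
    top = counts.max()
    tied = [str(c) for c, k in zip(classes, counts) if k == top]
    if len(tied) > 1:
        # QC bias: on a tied vote, flag the node as poor when possible
        return POOR if POOR in tied else sorted(tied)[-1]
    return tied[0]


class CartClassifier(ClassifierMixin, BaseEstimator):
    """Depth-limited CART for good/poor sequence classification.

    Parameters mirror the conservative growth rules documented in the
    module docstring.  ``X`` may be a DataFrame (column order fixes the
    tie-break order) or an array combined with ``feature_names``.

    Attributes after :meth:`fit`: ``tree_`` (root :class:`CartNode`),
    ``classes_``, ``feature_names_in_``, ``n_features_in_``,
    ``split_improvements_``.
    """

    def __init__(
        self,
        min_improvement: float = 0.02,
        min_parent: int = 20,
        min_child: int = 3,
        max_depth: int = 2,
        feature_names: Sequence[str] | None = None,
    ) -> None:
        self.min_improvement = min_improvement
        self.min_parent = min_parent
        self.min_child = min_child
        self.max_depth = max_depth
        self.feature_names = feature_names

    # -- fitting ---------------------------------------------------------
    def _as_frame(self, X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            return X
        X = np.asarray(X, dtype=float)
        names = (
            list(self.feature_names)
            if self.feature_names is not None
            else [f"x{i}" for i in range(X.shape[1])]
        )
        return pd.DataFrame(X, columns=names)

    def fit(self, X, y) -> "CartClassifier":
        if self.min_child > self.min_parent:
            raise ValueError("min_child must be <= min_parent")
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")
        Xf = self._as_frame(X)
        y = np.asarray(y)
        if len(Xf) != y.size:
            raise ValueError("X and y length mismatch")
        if Xf.isna().any().any():
            raise ValueError("X must not contain missing values")
        self.classes_ = np.unique(y)
        self.feature_names_in_ = np.asarray(Xf.columns, dtype=object)
        self.n_features_in_ = Xf.shape[1]
        self.split_improvements_: list[float] = []
        self.tree_ = self._grow(Xf, y, depth=0)
        return self

    def _grow(self, X: pd.DataFrame, y: np.ndarray, depth: int) -> CartNode:
        classes, counts = np.unique(y, return_counts=True)
        node = CartNode(
            prediction=_majority(y),
            counts={str(c): int(k) for c, k in zip(classes, counts)},
            impurity=gini(y),
        )
        if depth >= self.max_depth:
            return node
        split = best_split(
            X,
            y,
            min_parent=self.min_parent,
            min_child=self.min_child,
            min_improvement=self.min_improvement,
        )
        if split is None:
            return node
        mask = X[split.feature].to_numpy(float) <= split.threshold
        node.feature = split.feature
        node.threshold = split.threshold
        node.improvement = split.improvement
        self.split_improvements_.append(split.improvement)
        node.left = self._grow(X[mask], y[mask], depth + 1)
        node.right = self._grow(X[~mask], y[~mask], depth + 1)
        return node

    # -- prediction ------------------------------------------------------
    def _predict_row(self, row: pd.Series) -> str:
        node = self.tree_
        while not node.is_leaf:
            if node.feature not in row.index:
                raise ValueError(f"missing feature {node.feature!r} for prediction")
            val = row[node.feature]
            if pd.isna(val):
                raise ValueError(f"missing value for feature {node.feature!r}")
            node = node.left if float(val) <= node.threshold else node.right
        return node.prediction

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "tree_"):
            raise ValueError("CartClassifier is not fitted")
        Xf = X if isinstance(X, pd.DataFrame) else self._as_frame(X)
        return np.asarray([self._predict_row(row) for _, row in Xf.iterrows()], dtype=object)

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "hyperparams": {
                "min_improvement": self.min_improvement,
                "min_parent": self.min_parent,
                "min_child": self.min_child,
                "max_depth": self.max_depth,
            },
            "feature_names": list(map(str, self.feature_names_in_)),
            "tree": self.tree_.to_dict(),
        }

    def to_json(self, path=None) -> str:
        s = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s

    @classmethod
    def from_dict(cls, d: dict) -> "CartClassifier":
        est = cls(**d.get("hyperparams", {}))
        est.tree_ = CartNode.from_dict(d["tree"])
        est.feature_names_in_ = np.asarray(d.get("feature_names", []), dtype=object)
        est.n_features_in_ = len(est.feature_names_in_)
        est.classes_ = np.asarray(sorted({GOOD, POOR}))
        est.split_improvements_ = []
        return est

    @classmethod
    def from_json(cls, source: str) -> "CartClassifier":
        try:
            d = json.loads(source)
        except json.JSONDecodeError:
            with open(source) as fh:
                d = json.load(fh)
        return cls.from_dict(d)

    # -- the published reference tree -----------------------------------
    @classmethod
    def published(
        cls, *, fovx_cutoff: float = 150.0, cnr_cutoff: float = 3.147
    ) -> "CartClassifier":
        """The fixed reference tree for T1w sequence QC.

        ``FOVx <= 150 mm -> poor``; otherwise ``CNR <= 3.147 -> poor``;
        otherwise good.  Values exactly at a cutoff fall on the risk side
        (poor); the boundary orientation is configurable through the
        cutoffs only, not the inequality.
        """
        est = cls()
        cnr_node = CartNode(
            prediction=GOOD,
            counts=None,
            impurity=None,
            feature="cnr",
            threshold=float(cnr_cutoff),
            left=CartNode(prediction=POOR, counts=None, impurity=None),
            right=CartNode(prediction=GOOD, counts=None, impurity=None),
        )
        est.tree_ = CartNode(
            prediction=GOOD,
            counts=None,
            impurity=None,
            feature="fovx_mm",
            threshold=float(fovx_cutoff),
            left=CartNode(prediction=POOR, counts=None, impurity=None),
            right=cnr_node,
        )
        est.feature_names_in_ = np.asarray(["fovx_mm", "fovy_mm", "cnr", "fwhm_mm"], dtype=object)
        est.n_features_in_ = 4
        est.classes_ = np.asarray([GOOD, POOR])
        est.split_improvements_ = []
        return est


def grow(
    X: pd.DataFrame,
    y: Sequence,
    *,
    min_improvement: float = 0.02,
    min_parent: int = 20,
    min_child: int = 3,
    max_depth: int = 2,
) -> CartClassifier:
    """Fit a :class:`CartClassifier`; thin functional wrapper."""
    return CartClassifier(
        min_improvement=min_improvement,
        min_parent=min_parent,
        min_child=min_child,
        max_depth=max_depth,
    ).fit(X, y)


def published_tree() -> CartClassifier:
    """The fixed published reference tree (see :meth:`CartClassifier.published`)."""
    return CartClassifier.published()


def stratified_kfold_indices(
    y: Sequence, n_folds: int, seed: int
) -> list[np.ndarray]:
    """Deterministic stratified fold assignment.

    Within each class, indices are shuffled with the seeded generator and
    dealt round-robin to folds, so fold class proportions match the
    overall proportions as closely as integer counts allow.
    """
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(n_folds)]
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        idx = rng.permutation(idx)
        for pos, i in enumerate(idx):
            folds[pos % n_folds].append(int(i))
    return [np.sort(np.asarray(f, dtype=int)) for f in folds]


def cross_validate(
    X: pd.DataFrame,
    y: Sequence,
    *,
    n_folds: int = 5,
    seed: int = 0,
    min_improvement: float = 0.02,
    min_parent: int = 20,
    min_child: int = 3,
    max_depth: int = 2,
) -> dict:
    """Seeded stratified k-fold cross-validation of the CART.

    Grows a tree on each training split, predicts the held-out fold, and
    pools the held-out predictions into one confusion table.  Also reports
    the resubstitution metrics of the tree grown on all data (the two can
    differ: resubstitution is optimistic).  Deterministic given ``seed``.
    """
    y = np.asarray(y)
    if y.size < n_folds * min_child:
        raise ValueError("too few sessions for the requested number of folds")
    folds = stratified_kfold_indices(y, n_folds, seed)
    pred = np.empty(y.size, dtype=object)
    per_fold = []
    hyper = dict(
        min_improvement=min_improvement,
        min_parent=min_parent,
        min_child=min_child,
        max_depth=max_depth,
    )
    for k, test_idx in enumerate(folds):
        train_mask = np.ones(y.size, dtype=bool)
        train_mask[test_idx] = False
        y_train = y[train_mask]
        if np.unique(y_train).size < 2:
            warnings.warn(
                f"fold {k}: training split contains a single class; "
                "metrics may be partially undefined",
                UserWarning,
                stacklevel=2,
            )
        est = CartClassifier(**hyper).fit(X[train_mask], y_train)
        fold_pred = est.predict(X.iloc[test_idx])
        pred[test_idx] = fold_pred
        per_fold.append(
            {
                "fold": k,
                "n_test": int(test_idx.size),
                "accuracy_pct": 100.0 * float(np.mean(fold_pred == y[test_idx])),
            }
        )
    pooled_table = ConfusionTable.from_labels(y, pred)
    full = CartClassifier(**hyper).fit(X, y)
    resub_table = ConfusionTable.from_labels(y, full.predict(X))
    return {
        "per_fold": per_fold,
        "cv_table": pooled_table,
        "cv_metrics": confusion_metrics(pooled_table),
        "resubstitution_table": resub_table,
        "resubstitution_metrics": confusion_metrics(resub_table),
        "tree": full,
    }
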