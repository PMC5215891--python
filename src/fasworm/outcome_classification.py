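"""Endpoint classes and classification trees linking injury to outcome.

The fixed points into which injured cycles collapse (the "endpoints") are
split into two behavioral classes by the sign of their projection onto the
leading principal axis of the endpoint cloud, thresholded at -0.01
(projections >= -0.01 are the "upper" class).  CART classification trees
then predict the class either from the injury vector itself or from the
normalized PD-curve shape, with 10-fold cross-validation and
shuffled-label baselines quantifying how much real signal the features
carry.

The tree builder is deliberately deterministic: greedy binary splits
maximizing Gini impurity decrease, candidate thresholds at midpoints of
consecutive sorted unique feature values, ties broken by lowest feature
index then lowest threshold, and a minimum leaf size enforced on every
split.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .shape_analysis import PDCurve, normalize_and_average

UPPER = "upper"
LOWER = "lower"

#: Default split threshold on leading-axis projections.
PROJECTION_THRESHOLD = -0.01
#: Minimum leaf size selected for the study's tree fits.
DEFAULT_MIN_LEAF = 40


class ClassificationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# endpoint classes


@dataclass
class EndpointSet:
    endpoints: np.ndarray          # (K, 2)
    principal_axis: np.ndarray     # unit 2-vector
    projections: np.ndarray        # (K,)
    labels: np.ndarray             # (K,) of UPPER/LOWER

    @property
    def upper_fraction(self) -> float:
        return float(np.mean(self.labels == UPPER))


def split_endpoints(
    endpoints: np.ndarray,
    threshold: float = PROJECTION_THRESHOLD,
    center: bool = True,
) -> EndpointSet:
    """Label endpoints upper/lower along the cloud's major axis.

    The leading principal orthogonal mode of the (by default mean-centered)
    endpoint cloud is found by SVD; points whose projection onto it is
    ``>= threshold`` are labeled upper.  ``center=False`` projects the raw
    coordinates instead (both variants are legitimate readings of the
    published procedure; the threshold is exposed so either can be
    calibrated).
    """
    pts = np.asarray(endpoints, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise ClassificationError("endpoints must be a (K>=2, 2) array")
    X = pts - pts.mean(axis=0) if center else pts
    _, S, Vt = np.linalg.svd(X, full_matrices=False)
    if S[0] <= 0:
        raise ClassificationError("degenerate endpoint cloud (zero variance)")
    axis = Vt[0]
    k = int(np.argmax(np.abs(axis)))
    if axis[k] < 0:
        axis = -axis
    proj = X @ axis
    labels = np.where(proj >= threshold, UPPER, LOWER).astype(object)
    return EndpointSet(pts, axis, proj, labels)


# ---------------------------------------------------------------------------
# CART


@dataclass
class TreeNode:
    feature: int | None = None
    threshold: float | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None
    label: object = None
    n: int = 0
    gini_decrease: float = 0.0   # impurity decrease weighted by node fraction

    @property
    def is_leaf(self) -> bool:
        return self.feature is None


@dataclass
class TreeModel:
    root: TreeNode
    min_leaf: int
    classes: list
    n_features: int

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        out = np.empty(X.shape[0], dtype=object)
        for i, row in enumerate(X):
            node = self.root
            while not node.is_leaf:
                node = node.left if row[node.feature] < node.threshold else node.right
            out[i] = node.label
        return out

    @property
    def features_used(self) -> set[int]:
        used: set[int] = set()

        def walk(node: TreeNode) -> None:
            if not node.is_leaf:
                used.add(node.feature)
                walk(node.left)
                walk(node.right)

        walk(self.root)
        return used

    def leaf_sizes(self) -> list[int]:
        sizes: list[int] = []

        def walk(node: TreeNode) -> None:
            if node.is_leaf:
                sizes.append(node.n)
            else:
                walk(node.left)
                walk(node.right)

        walk(self.root)
        return sizes

    def to_text(self, names: list[str] | None = None) -> str:
        lines: list[str] = []

        def fname(i: int) -> str:
            return names[i] if names else f"x{i}"

        def walk(node: TreeNode, depth: int) -> None:
            pad = "  " * depth
            if node.is_leaf:
                lines.append(f"{pad}-> {node.label} (n={node.n})")
            else:
                lines.append(f"{pad}{fname(node.feature)} < {node.threshold:.6g} ?")
                walk(node.left, depth + 1)
                walk(node.right, depth + 1)

        walk(self.root, 0)
        return "\n".join(lines)

    def to_json(self, path: str | Path) -> None:
        def encode(node: TreeNode) -> dict:
            if node.is_leaf:
                return {"label": node.label, "n": node.n}
            return {
                "feature": node.feature,
                "threshold": node.threshold,
                "n": node.n,
                "gini_decrease": node.gini_decrease,
                "left": encode(node.left),
                "right": encode(node.right),
            }

        Path(path).write_text(json.dumps(encode(self.root), indent=1))


def _gini(counts: np.ndarray) -> float:
    total = counts.sum()
    if total == 0:
        return 0.0
    p = counts / total
    return float(1.0 - (p**2).sum())


def _best_split(X: np.ndarray, y_enc: np.ndarray, n_classes: int, min_leaf: int):
    """Exhaustive search over (feature, midpoint-threshold) pairs.

    Returns ``(feature, threshold, decrease)`` of the best valid split or
    ``None``.  Ties in Gini decrease go to the lowest feature index, then the
    lowest threshold.
    """
    n, p = X.shape
    parent_counts = np.bincount(y_enc, minlength=n_classes).astype(float)
    parent_gini = _gini(parent_counts)
    best = None  # (decrease, feature, threshold)
    for j in range(p):
        order = np.argsort(X[:, j], kind="stable")
        xs = X[order, j]
        ys = y_enc[order]
        onehot = np.zeros((n, n_classes))
        onehot[np.arange(n), ys] = 1.0
        left_counts = np.cumsum(onehot, axis=0)       # counts if split after row i
        distinct = xs[1:] != xs[:-1]
        sizes_left = np.arange(1, n)
        valid = distinct & (sizes_left >= min_leaf) & ((n - sizes_left) >= min_leaf)
        if not valid.any():
            continue
        lc = left_counts[:-1][valid]
        rc = parent_counts[None, :] - lc
        nl = lc.sum(axis=1)
        nr = rc.sum(axis=1)
        gini_l = 1.0 - (lc**2).sum(axis=1) / nl**2
        gini_r = 1.0 - (rc**2).sum(axis=1) / nr**2
        decrease = parent_gini - (nl * gini_l + nr * gini_r) / n
        thresholds = 0.5 * (xs[:-1][valid] + xs[1:][valid])
        for dec, thr in zip(decrease, thresholds):
            if dec <= 1e-12:
                continue
            cand = (dec, j, thr)
            if (
                best is None
                or cand[0] > best[0] + 1e-12
                or (abs(cand[0] - best[0]) <= 1e-12 and (j, thr) < (best[1], best[2]))
            ):
                best = cand
    if best is None:
        return None
    return best[1], best[2], best[0]


def fit_tree(X: np.ndarray, y, min_leaf: int = 1) -> TreeModel:
    """Grow a deterministic CART tree with Gini impurity splitting."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=object)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ClassificationError("X rows must match labels")
    if min_leaf < 1:
        raise ClassificationError("min_leaf must be >= 1")
    classes = sorted(set(y.tolist()), key=str)
    cls_index = {cls: i for i, cls in enumerate(classes)}
    y_enc = np.array([cls_index[v] for v in y], dtype=int)
    n_classes = len(classes)
    n_total = X.shape[0]

    def majority(y_sub: np.ndarray) -> object:
        counts = np.bincount(y_sub, minlength=n_classes)
        # deterministic tie-break: lexicographically smallest class label
        winners = np.flatnonzero(counts == counts.max())
        return classes[winners[0]]

    def grow(idx: np.ndarray) -> TreeNode:
        y_sub = y_enc[idx]
        node = TreeNode(n=idx.size, label=majority(y_sub))
        if np.all(y_sub == y_sub[0]) or idx.size < 2 * min_leaf:
            return node
        found = _best_split(X[idx], y_sub, n_classes, min_leaf)
        if found is None:
            return node
        j, thr, dec = found
        mask = X[idx, j] < thr
        node.feature, node.threshold = j, float(thr)
        node.gini_decrease = float(dec) * idx.size / n_total
        node.left = grow(idx[mask])
        node.right = grow(idx[~mask])
        return node

    return TreeModel(grow(np.arange(n_total)), min_leaf, classes, X.shape[1])


# ---------------------------------------------------------------------------
# cross-validation and baselines


def kfold_cv_error(
    X: np.ndarray,
    y,
    min_leaf: int = DEFAULT_MIN_LEAF,
    folds: int = 10,
    seed: int = 0,
) -> float:
    """Held-out misclassification fraction under seeded k-fold CV.

    Fold assignment is uniform random (unstratified); the error is the total
    number of held-out misclassifications divided by n.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=object)
    n = X.shape[0]
    if n < folds:
        raise ClassificationError(f"need at least {folds} samples for {folds}-fold CV")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    errors = 0
    for part in np.array_split(perm, folds):
        train = np.setdiff1d(perm, part, assume_unique=True)
        tree = fit_tree(X[train], y[train], min_leaf=min_leaf)
        errors += int(np.sum(tree.predict(X[part]) != y[part]))
    return errors / n


def leaf_size_sweep(
    X: np.ndarray,
    y,
    sizes: list[int],
    folds: int = 10,
    seed: int = 0,
) -> list[tuple[int, float]]:
    """CV error per candidate minimum leaf size (for the size-selection plot)."""
    if not sizes:
        raise ClassificationError("sizes must be nonempty")
    return [(int(sz), kfold_cv_error(X, y, min_leaf=sz, folds=folds, seed=seed)) for sz in sizes]


def shuffled_baseline(
    X: np.ndarray,
    y,
    min_leaf: int = DEFAULT_MIN_LEAF,
    trials: int = 100,
    folds: int = 10,
    seed: int = 0,
) -> tuple[float, float]:
    """CV error under randomly permuted labels: (mean, std) over trials."""
    if trials < 2:
        raise ClassificationError("need at least 2 shuffle trials")
    y = np.asarray(y, dtype=object)
    rng = np.random.default_rng(seed)
    errs = []
    for t in range(trials):
        y_shuf = y[rng.permutation(y.shape[0])]
        errs.append(kfold_cv_error(X, y_shuf, min_leaf=min_leaf, folds=folds, seed=seed + 1 + t))
    errs = np.asarray(errs)
    return float(errs.mean()), float(errs.std())


def implicated_features(tree: TreeModel, names: list[str] | None = None) -> list[tuple[str, float]]:
    """Features appearing in splits, ordered by total Gini decrease."""
    totals: dict[int, float] = {}

    def walk(node: TreeNode) -> None:
        if not node.is_leaf:
            totals[node.feature] = totals.get(node.feature, 0.0) + node.gini_decrease
            walk(node.left)
            walk(node.right)

    walk(tree.root)
    ranked = sorted(totals.items(), key=lambda kv: (-kv[1], kv[0]))
    return [(names[j] if names else f"x{j}", val) for j, val in ranked]


def pd_curve_features(curve: PDCurve, grid_size: int = 25) -> np.ndarray:
    """Normalized PD-curve shape resampled to a fixed grid (tree feature row).

    Invariant to rescaling of the mu axis by mu* and of the PD axis by its
    maximum, so curves that differ only by overall severity produce
    identical features.
    """
    _, mean, _ = normalize_and_average([curve], which="pd", grid_size=grid_size)
    return mean
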