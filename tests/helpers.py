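"""Independent brute-force oracles used by the unit and acceptance tests.

These deliberately re-derive results by the dumbest correct route (grid
search, double loops, exhaustive recursion) and never call the library code
paths they are checking.
"""

from __future__ import annotations

import numpy as np


# ---------------------------------------------------------------------------
# Procrustes oracle: direct minimization over (b, theta, c)


def procrustes_oracle(A: np.ndarray, B: np.ndarray, coarse: int = 3600, refine_iters: int = 60):
    """Minimize ||B - (b A R(theta) + c)||^2 by 1-D search over theta.

    For fixed theta the optimal translation is given by centering and the
    optimal b by a scalar least squares, so the problem reduces to a 1-D
    minimization in theta, solved by coarse grid plus golden-section
    refinement.  Returns the standardized dissimilarity
    1 - trace^2/(|Ac|^2 |Bc|^2) evaluated at the optimum.
    """
    Ac = A - A.mean(axis=0)
    Bc = B - B.mean(axis=0)
    na2 = (Ac**2).sum()
    nb2 = (Bc**2).sum()

    def dissimilarity(theta: float) -> float:
        ct, st = np.cos(theta), np.sin(theta)
        R = np.array([[ct, -st], [st, ct]])
        inner = float((Bc * (Ac @ R)).sum())
        b = max(inner, 0.0) / na2
        resid = nb2 - 2 * b * inner + b**2 * na2
        return resid / nb2

    thetas = np.linspace(0.0, 2 * np.pi, coarse, endpoint=False)
    vals = np.array([dissimilarity(t) for t in thetas])
    k = int(np.argmin(vals))
    lo = thetas[k] - 2 * np.pi / coarse
    hi = thetas[k] + 2 * np.pi / coarse
    gr = (np.sqrt(5) - 1) / 2
    a, b_ = lo, hi
    c = b_ - gr * (b_ - a)
    d = a + gr * (b_ - a)
    for _ in range(refine_iters):
        if dissimilarity(c) < dissimilarity(d):
            b_ = d
        else:
            a = c
        c = b_ - gr * (b_ - a)
        d = a + gr * (b_ - a)
    return dissimilarity(0.5 * (a + b_))


# ---------------------------------------------------------------------------
# CART oracle: exhaustive recursive split search, written independently


def _oracle_gini(labels: list) -> float:
    n = len(labels)
    out = 1.0
    for v in set(labels):
        p = labels.count(v) / n
        out -= p * p
    return out


def cart_oracle(X: np.ndarray, y: list, min_leaf: int):
    """Grow a tree by exhaustive search over every (feature, midpoint) split.

    Returns a nested structure: ('leaf', label, n) or
    ('split', feature, threshold, left, right).  Tie-breaks: highest Gini
    decrease, then lowest feature index, then lowest threshold; leaf labels
    are the lexicographically smallest majority class.
    """
    X = np.asarray(X, dtype=float)
    y = list(y)
    n, p = X.shape

    def majority(labels: list):
        counts = {}
        for v in labels:
            counts[v] = counts.get(v, 0) + 1
        top = max(counts.values())
        return sorted([k for k, v in counts.items() if v == top], key=str)[0]

    def grow(rows: list):
        labels = [y[i] for i in rows]
        if len(set(labels)) == 1 or len(rows) < 2 * min_leaf:
            return ("leaf", majority(labels), len(rows))
        parent = _oracle_gini(labels)
        best = None
        for j in range(p):
            values = sorted(set(X[i, j] for i in rows))
            for a, b in zip(values[:-1], values[1:]):
                thr = 0.5 * (a + b)
                left = [i for i in rows if X[i, j] < thr]
                right = [i for i in rows if X[i, j] >= thr]
                if len(left) < min_leaf or len(right) < min_leaf:
                    continue
                dec = parent - (
                    len(left) * _oracle_gini([y[i] for i in left])
                    + len(right) * _oracle_gini([y[i] for i in right])
                ) / len(rows)
                if dec <= 1e-12:
                    continue
                cand = (dec, j, thr, left, right)
                if (
                    best is None
                    or cand[0] > best[0] + 1e-12
                    or (abs(cand[0] - best[0]) <= 1e-12 and (j, thr) < (best[1], best[2]))
                ):
                    best = cand
        if best is None:
            return ("leaf", majority(labels), len(rows))
        _, j, thr, left, right = best
        return ("split", j, thr, grow(left), grow(right))

    return grow(list(range(n)))


def tree_structure(model) -> tuple:
    """Serialize a fasworm TreeModel into the oracle's nested-tuple form."""

    def walk(node):
        if node.is_leaf:
            return ("leaf", node.label, node.n)
        return ("split", node.feature, round(node.threshold, 12), walk(node.left), walk(node.right))

    def normalize(t):
        if t[0] == "leaf":
            return t
        return ("split", t[1], round(t[2], 12), normalize(t[3]), normalize(t[4]))

    return walk(model.root)


def normalize_oracle(t) -> tuple:
    if t[0] == "leaf":
        return t
    return ("split", t[1], round(t[2], 12), normalize_oracle(t[3]), normalize_oracle(t[4]))


# ---------------------------------------------------------------------------
# shapes


def circle_points(N: int, r: float = 1.0, phase: float = 0.0, center=(0.0, 0.0)) -> np.ndarray:
    th = 2 * np.pi * np.arange(N) / N + phase
    return np.column_stack([center[0] + r * np.cos(th), center[1] + r * np.sin(th)])


def ellipse_points(N: int, a: float, b: float, phase: float = 0.0) -> np.ndarray:
    th = 2 * np.pi * np.arange(N) / N + phase
    return np.column_stack([a * np.cos(th), b * np.sin(th)])


def random_blob(rng: np.random.Generator, N: int = 10, spread: float = 1.0) -> np.ndarray:
    return rng.normal(scale=spread, size=(N, 2))
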