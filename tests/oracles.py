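"""Independent brute-force oracles the test suite checks the package against.

Everything here is deliberately naive and separate from the implementation:
batch information gain by exhaustive threshold scan, pairwise single-linkage
text grouping, root-to-leaf traversal, and the double-loop quadratic form.
"""

from __future__ import annotations

import math

import numpy as np


def entropy(counts: np.ndarray) -> float:
    counts = np.asarray(counts, dtype=float)
    tot = counts.sum()
    if tot <= 0:
        return 0.0
    p = counts[counts > 0] / tot
    return float(-(p * np.log2(p)).sum())


def batch_info_gain_argmax(X: np.ndarray, y: np.ndarray) -> tuple[int, float]:
    """Best attribute by exhaustive batch information gain over all cut points."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=object)
    classes = np.unique(y)
    prior = entropy(np.array([(y == c).sum() for c in classes]))
    n = len(y)
    best_attr, best_gain = -1, -1.0
    for a in range(X.shape[1]):
        order = np.argsort(X[:, a], kind="stable")
        ys = y[order]
        onehot = np.stack([(ys == c).astype(float) for c in classes], axis=1)
        cum = np.cumsum(onehot, axis=0)
        tot = cum[-1]
        left = cum[:-1]
        right = tot - left
        # vectorized entropies of every prefix/suffix
        def ent_rows(m):
            s = m.sum(axis=1, keepdims=True)
            with np.errstate(divide="ignore", invalid="ignore"):
                p = np.where(m > 0, m / np.maximum(s, 1e-300), 1.0)
                h = -(np.where(m > 0, p * np.log2(p), 0.0)).sum(axis=1)
            return h, s[:, 0]
        hl, nl = ent_rows(left)
        hr, nr = ent_rows(right)
        gains = prior - (nl * hl + nr * hr) / n
        g = float(gains.max()) if len(gains) else 0.0
        if g > best_gain:
            best_attr, best_gain = a, g
    return best_attr, best_gain


def batch_best_threshold(X: np.ndarray, y: np.ndarray, attr: int) -> tuple[float, float]:
    """Best (gain, threshold) for one attribute by exhaustive midpoint scan."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=object)
    classes = np.unique(y)
    prior = entropy(np.array([(y == c).sum() for c in classes]))
    vals = X[:, attr]
    order = np.argsort(vals, kind="stable")
    sv, sy = vals[order], y[order]
    best = (0.0, math.nan)
    for i in range(1, len(sy)):
        if sv[i] == sv[i - 1]:
            continue
        thr = (sv[i] + sv[i - 1]) / 2.0
        left = np.array([(sy[:i] == c).sum() for c in classes])
        right = np.array([(sy[i:] == c).sum() for c in classes])
        g = prior - (i * entropy(left) + (len(sy) - i) * entropy(right)) / len(sy)
        if g > best[0]:
            best = (g, thr)
    return best


def pairwise_group_count(texts, threshold, tokenize_fn, cosine_fn) -> int:
    """Number of single-linkage groups by literal all-pairs comparison."""
    n = len(texts)
    toks = [tokenize_fn(t) for t in texts]
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if cosine_fn(toks[i], toks[j]) >= threshold:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri
    return len({find(i) for i in range(n)})


def walk_tree(node, x):
    """Naive root-to-leaf walk, independent of the classifier's _route."""
    while hasattr(node, "attribute"):
        node = node.left if float(x[node.attribute]) <= node.threshold else node.right
    return node


def quadratic_form_double_loop(xi, xj, P) -> float:
    """Element-wise (x_i - x_j)^T P (x_i - x_j)."""
    d = [a - b for a, b in zip(xi, xj)]
    total = 0.0
    for r in range(len(d)):
        for c in range(len(d)):
            total += d[r] * P[r][c] * d[c]
    return total
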