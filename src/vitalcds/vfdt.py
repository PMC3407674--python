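"""Pointer-augmented Hoeffding-tree (VFDT) stream classifier.

A Hoeffding tree learns a decision tree from a stream one example at a
time: each leaf accumulates class counts and per-attribute sufficient
statistics, and every ``grace_period`` examples it asks whether the best
candidate split is reliably better than the runner-up. The Hoeffding bound

    epsilon = sqrt(R^2 * ln(1/delta) / (2 n))

guarantees with confidence 1 - delta that the observed gain ordering over
``n`` examples matches the true ordering, so the leaf splits as soon as
``G1 - G2 > epsilon``, or when ``epsilon < tau`` (the two candidates are a
statistical tie and waiting longer cannot separate them).

The clinical extension: every leaf carries a *pointer list*. During
training the Adder appends the trained record's pointer value to the leaf
the record was routed to, so a leaf — one illness class — indexes the
historical records of its class and downstream retrieval is a direct
lookup, with no offline clustering pass.

``HoeffdingTreeClassifier`` follows the scikit-learn estimator protocol
(``partial_fit`` / ``predict`` / ``predict_proba``, ``get_params`` /
``set_params``, fitted attributes with a trailing underscore) and adds the
streaming single-example surface ``learn_one`` / ``classify_one``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .errors import ConfigurationError, SchemaError, ValidationError

__all__ = [
    "VFDTConfig",
    "LeafNode",
    "SplitNode",
    "hoeffding_bound",
    "best_splits",
    "HoeffdingTreeClassifier",
]

_SQRT2 = math.sqrt(2.0)


def _phi(z: float) -> float:
    """Standard normal CDF via erf (no scipy dependency in the hot path)."""
    return 0.5 * (1.0 + math.erf(z / _SQRT2))


def hoeffding_bound(value_range: float, delta: float, n: int) -> float:
    """Hoeffding bound epsilon = sqrt(R^2 ln(1/delta) / (2 n)).

    Parameters
    ----------
    value_range : float
        Range R of the split metric (log2(#classes) for information gain).
    delta : float
        Allowed probability, in (0, 1], that the observed best split is not
        the true best.
    n : int
        Number of examples observed at the leaf.
    """
    if value_range < 0:
        raise ValidationError(f"value_range must be >= 0, got {value_range}")
    if not (0 < delta <= 1):
        raise ValidationError(f"delta must be in (0, 1], got {delta}")
    if n < 1:
        raise ValidationError(f"n must be >= 1, got {n}")
    return math.sqrt(value_range * value_range * math.log(1.0 / delta) / (2.0 * n))


@dataclass
class VFDTConfig:
    """Tunable parameters of the tree learner.

    delta : split confidence; smaller = more conservative splits.
    tau : tie-break threshold; once epsilon < tau a near-tie splits anyway.
    grace_period : examples between split attempts at a leaf.
    max_depth : optional depth bound (leaves at the bound never split).
    pointer_cap : optional per-leaf cap on the pointer list (keep most
        recent); None = unbounded, the default.
    seed : reserved for stochastic extensions; the learner itself is
        deterministic.
    """

    delta: float = 1e-6
    tau: float = 0.05
    grace_period: int = 200
    max_depth: int | None = None
    pointer_cap: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.delta < 1):
            raise ConfigurationError(f"delta must be in (0,1), got {self.delta}")
        if self.tau < 0:
            raise ConfigurationError(f"tau must be >= 0, got {self.tau}")
        if self.grace_period < 1:
            raise ConfigurationError(
                f"grace_period must be >= 1, got {self.grace_period}"
            )
        if self.max_depth is not None and self.max_depth < 0:
            raise ConfigurationError(f"max_depth must be >= 0, got {self.max_depth}")

    def to_dict(self) -> dict:
        return {
            "delta": self.delta,
            "tau": self.tau,
            "grace_period": self.grace_period,
            "max_depth": self.max_depth,
            "pointer_cap": self.pointer_cap,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "VFDTConfig":
        return cls(**d)


class _GaussianStats:
    """Running count/mean/variance (Welford) for one attribute, one class."""

    __slots__ = ("n", "mean", "m2")

    def __init__(self, n: int = 0, mean: float = 0.0, m2: float = 0.0) -> None:
        self.n = n
        self.mean = mean
        self.m2 = m2

    def update(self, x: float) -> None:
        self.n += 1
        d = x - self.mean
        self.mean += d / self.n
        self.m2 += d * (x - self.mean)

    @property
    def std(self) -> float:
        if self.n < 2:
            return 0.0
        return math.sqrt(self.m2 / (self.n - 1))

    def to_list(self) -> list:
        return [self.n, self.mean, self.m2]

    @classmethod
    def from_list(cls, v: list) -> "_GaussianStats":
        return cls(int(v[0]), float(v[1]), float(v[2]))


@dataclass
class CandidateSplit:
    """One evaluated split: gain of thresholding ``attribute <= threshold``."""

    gain: float
    attribute: int
    threshold: float


class LeafNode:
    """A leaf: class counts, per-attribute per-class Gaussians, pointers.

    ``pointer_version`` is a monotone counter bumped whenever the Adder
    appends a pointer; the prediction cache stamps entries with it so a
    stale cached extraction can be recognized without a global lock.
    """

    def __init__(self, leaf_id: str, n_attrs: int, depth: int = 0) -> None:
        self.leaf_id = leaf_id
        self.n_attrs = n_attrs
        self.depth = depth
        self.class_counts: dict[str, int] = {}
        # attr_stats[attr][class] -> _GaussianStats
        self.attr_stats: list[dict[str, _GaussianStats]] = [
            {} for _ in range(n_attrs)
        ]
        self.attr_min: list[float] = [math.inf] * n_attrs
        self.attr_max: list[float] = [-math.inf] * n_attrs
        self.pointer_list: list[int] = []
        self._pointer_set: set[int] = set()
        self.pointer_features: dict[int, list[float]] = {}
        self.pointer_version: int = 0
        self.samples_since_split_attempt: int = 0
        # prediction fallback inherited from the parent at split time, used
        # until this leaf has observed examples of its own
        self.fallback_class: str | None = None

    @property
    def total(self) -> int:
        return sum(self.class_counts.values())

    def majority_class(self) -> str | None:
        if not self.class_counts:
            return self.fallback_class
        # ties broken lexicographically for determinism
        return max(self.class_counts, key=lambda c: (self.class_counts[c], c))

    def observe(self, x: Sequence[float], label: str) -> None:
        self.class_counts[label] = self.class_counts.get(label, 0) + 1
        for a in range(self.n_attrs):
            v = float(x[a])
            stats = self.attr_stats[a].setdefault(label, _GaussianStats())
            stats.update(v)
            if v < self.attr_min[a]:
                self.attr_min[a] = v
            if v > self.attr_max[a]:
                self.attr_max[a] = v
        self.samples_since_split_attempt += 1

    def add_pointer(self, pointer: int, features: Sequence[float],
                    cap: int | None = None) -> None:
        if pointer in self._pointer_set:
            return
        self.pointer_list.append(pointer)
        self._pointer_set.add(pointer)
        self.pointer_features[pointer] = [float(v) for v in features]
        if cap is not None and len(self.pointer_list) > cap:
            old = self.pointer_list.pop(0)
            self._pointer_set.discard(old)
            self.pointer_features.pop(old, None)
        self.pointer_version += 1


class SplitNode:
    """Interior node: routes on ``x[attribute] <= threshold``."""

    def __init__(self, attribute: int, threshold: float,
                 left, right) -> None:
        self.attribute = attribute
        self.threshold = threshold
        self.left = left
        self.right = right

    def route(self, x: Sequence[float]):
        return self.left if float(x[self.attribute]) <= self.threshold else self.right


def _entropy(counts: np.ndarray) -> float:
    tot = counts.sum()
    if tot <= 0:
        return 0.0
    p = counts[counts > 0] / tot
    return float(-(p * np.log2(p)).sum())


def _candidate_thresholds(leaf: LeafNode, attr: int) -> list[float]:
    """Midpoints between per-class means plus range deciles, deduped."""
    means = sorted(s.mean for s in leaf.attr_stats[attr].values() if s.n > 0)
    cands = [(a + b) / 2.0 for a, b in zip(means, means[1:])]
    lo, hi = leaf.attr_min[attr], leaf.attr_max[attr]
    if math.isfinite(lo) and math.isfinite(hi) and hi > lo:
        cands.extend(lo + (hi - lo) * q / 10.0 for q in range(1, 10))
    out: list[float] = []
    for t in sorted(set(round(c, 12) for c in cands)):
        out.append(float(t))
    return out


_STD_FLOOR = 1e-9


def _split_gain(leaf: LeafNode, attr: int, threshold: float,
                prior_entropy: float) -> float:
    """Info gain of a threshold, classes modeled as per-leaf Gaussians."""
    labels = sorted(leaf.class_counts)
    left = np.zeros(len(labels))
    right = np.zeros(len(labels))
    for i, lab in enumerate(labels):
        stats = leaf.attr_stats[attr].get(lab)
        n = leaf.class_counts[lab]
        if stats is None or stats.n == 0:
            continue
        sd = max(stats.std, _STD_FLOOR)
        frac = _phi((threshold - stats.mean) / sd)
        left[i] = n * frac
        right[i] = n * (1.0 - frac)
    nl, nr = left.sum(), right.sum()
    tot = nl + nr
    if tot <= 0 or nl <= 0 or nr <= 0:
        return 0.0
    post = (nl * _entropy(left) + nr * _entropy(right)) / tot
    return max(0.0, prior_entropy - post)


def best_splits(leaf: LeafNode) -> tuple[CandidateSplit, CandidateSplit]:
    """Top two candidate splits by information gain, one per attribute.

    The Hoeffding race compares the best split of the leading attribute
    against the best split of the runner-up *attribute* (two thresholds of
    the same attribute estimate the same quantity and would tie forever).
    Deterministic: ties broken by lowest attribute index, then lowest
    threshold. A leaf with fewer than two observed classes yields two
    zero-gain no-split candidates.
    """
    prior = _entropy(np.array(list(leaf.class_counts.values()), dtype=float))
    null = CandidateSplit(0.0, -1, math.nan)
    if len(leaf.class_counts) < 2:
        return null, null
    per_attr: list[tuple[float, int, float]] = []
    for attr in range(leaf.n_attrs):
        best: tuple[float, int, float] | None = None
        for t in _candidate_thresholds(leaf, attr):
            g = _split_gain(leaf, attr, t, prior)
            # higher gain wins; equal gain -> lowest threshold
            if best is None or g > best[0] or (g == best[0] and t < best[2]):
                best = (g, attr, t)
        if best is not None:
            per_attr.append(best)
    if not per_attr:
        return null, null
    per_attr.sort(key=lambda r: (-r[0], r[1], r[2]))
    first = CandidateSplit(*per_attr[0])
    second = CandidateSplit(*per_attr[1]) if len(per_attr) > 1 else null
    return first, second


class HoeffdingTreeClassifier:
    """Incremental VFDT classifier with pointer-augmented leaves.

    Numeric attributes only; each leaf keeps one Gaussian per (attribute,
    class), so memory per leaf is fixed regardless of stream length.
    Class labels are opaque strings, registered on first sight.

    Parameters mirror :class:`VFDTConfig`. Fitted attributes:

    root_ : LeafNode | SplitNode
        The live tree.
    classes_ : list of str
        Sorted class labels seen so far.
    n_features_in_ : int
        Attribute count, fixed by the first example.

    Examples
    --------
    >>> tree = HoeffdingTreeClassifier(delta=1e-6)
    >>> leaf_id = tree.learn_one([1.0, 2.0], "flu", pointer=1)
    >>> tree.classify_one([1.0, 2.0])[1]
    'flu'
    """

    def __init__(self, delta: float = 1e-6, tau: float = 0.05,
                 grace_period: int = 200, max_depth: int | None = None,
                 pointer_cap: int | None = None, seed: int = 0) -> None:
        self.delta = delta
        self.tau = tau
        self.grace_period = grace_period
        self.max_depth = max_depth
        self.pointer_cap = pointer_cap
        self.seed = seed
        self._listeners: list[Callable[[str], None]] = []

    # -- sklearn parameter protocol --------------------------------------
    _param_names = ("delta", "tau", "grace_period", "max_depth",
                    "pointer_cap", "seed")

    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k) for k in self._param_names}

    def set_params(self, **params) -> "HoeffdingTreeClassifier":
        for k, v in params.items():
            if k not in self._param_names:
                raise ConfigurationError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    # -- construction ------------------------------------------------------
    @property
    def config(self) -> VFDTConfig:
        return VFDTConfig(self.delta, self.tau, self.grace_period,
                          self.max_depth, self.pointer_cap, self.seed)

    def _ensure_init(self, n_attrs: int) -> None:
        if not hasattr(self, "root_"):
            self._leaf_counter = 0
            self.root_ = self._new_leaf(n_attrs, depth=0)
            self.classes_ = []
            self.n_features_in_ = n_attrs
            self._class_set: set[str] = set()

    def _new_leaf(self, n_attrs: int, depth: int) -> LeafNode:
        self._leaf_counter += 1
        return LeafNode(f"C{self._leaf_counter}", n_attrs, depth)

    def _check_x(self, x: Sequence[float]) -> None:
        if len(x) != self.n_features_in_:
            raise SchemaError(
                f"expected {self.n_features_in_} features, got {len(x)}"
            )

    # -- event listeners (the Adder notifies the prediction cache) --------
    def add_pointer_listener(self, fn: Callable[[str], None]) -> None:
        """Register a callback invoked with the leaf_id on each Adder event."""
        self._listeners.append(fn)

    def _emit(self, leaf_id: str) -> None:
        for fn in self._listeners:
            fn(leaf_id)

    # -- routing -----------------------------------------------------------
    def _route(self, x: Sequence[float]) -> LeafNode:
        node = self.root_
        while isinstance(node, SplitNode):
            node = node.route(x)
        return node

    def _find_parent(self, target: LeafNode):
        """Return (parent, side) of a leaf, or (None, None) for the root."""
        if self.root_ is target:
            return None, None
        stack = [self.root_]
        while stack:
            node = stack.pop()
            if isinstance(node, SplitNode):
                for side in ("left", "right"):
                    child = getattr(node, side)
                    if child is target:
                        return node, side
                    stack.append(child)
        raise RuntimeError("leaf not found in tree")  # pragma: no cover

    # -- learning ----------------------------------------------------------
    def learn_one(self, x: Sequence[float], y: str,
                  pointer: int | None = None) -> str:
        """Route one labeled example to a leaf and update it.

        If ``pointer`` is given, the Adder appends it to the leaf's pointer
        list (with the example's features, so later splits can re-route it)
        and notifies cache listeners. Returns the id of the leaf reached
        (after any split this example triggered).
        """
        x = [float(v) for v in x]
        self._ensure_init(len(x))
        self._check_x(x)
        y = str(y)
        if y not in self._class_set:
            self._class_set.add(y)
            self.classes_ = sorted(self._class_set)
        leaf = self._route(x)
        leaf.observe(x, y)
        if pointer is not None:
            leaf.add_pointer(pointer, x, cap=self.pointer_cap)
            self._emit(leaf.leaf_id)
        leaf_id = leaf.leaf_id
        if leaf.samples_since_split_attempt >= self.grace_period:
            leaf.samples_since_split_attempt = 0
            new_node = self._attempt_split(leaf)
            if new_node is not None:
                leaf_id = self._route(x).leaf_id
        return leaf_id

    def _attempt_split(self, leaf: LeafNode) -> SplitNode | None:
        if len(leaf.class_counts) < 2:
            return None
        if self.max_depth is not None and leaf.depth >= self.max_depth:
            return None
        first, second = best_splits(leaf)
        if first.attribute < 0 or first.gain <= 0.0:
            return None
        n_classes = max(2, len(self._class_set))
        value_range = math.log2(n_classes)
        eps = hoeffding_bound(value_range, self.delta, leaf.total)
        if not (first.gain - second.gain > eps or eps < self.tau):
            return None
        return self._split_leaf(leaf, first)

    def _split_leaf(self, leaf: LeafNode, cand: CandidateSplit) -> SplitNode:
        left = self._new_leaf(leaf.n_attrs, leaf.depth + 1)
        right = self._new_leaf(leaf.n_attrs, leaf.depth + 1)
        split = SplitNode(cand.attribute, cand.threshold, left, right)
        # side-conditional majority under the leaf's Gaussian summaries
        # seeds each child's prediction until it sees its own examples
        lw: dict[str, float] = {}
        rw: dict[str, float] = {}
        for lab, n in leaf.class_counts.items():
            stats = leaf.attr_stats[cand.attribute].get(lab)
            if stats is None or stats.n == 0:
                continue
            frac = _phi((cand.threshold - stats.mean) / max(stats.std, _STD_FLOOR))
            lw[lab] = n * frac
            rw[lab] = n * (1.0 - frac)
        fallback = leaf.majority_class()
        left.fallback_class = (
            max(lw, key=lambda c: (lw[c], c)) if lw else fallback
        )
        right.fallback_class = (
            max(rw, key=lambda c: (rw[c], c)) if rw else fallback
        )
        # Pointers migrate to whichever child their stored features route to,
        # keeping the leaf -> records-of-its-class mapping correct after growth.
        for p in leaf.pointer_list:
            feats = leaf.pointer_features[p]
            child = split.route(feats)
            child.add_pointer(p, feats, cap=self.pointer_cap)
        parent, side = self._find_parent(leaf)
        if parent is None:
            self.root_ = split
        else:
            setattr(parent, side, split)
        # The old leaf id disappears: any cached prediction keyed on it is stale.
        self._emit(leaf.leaf_id)
        for child in (left, right):
            if child.pointer_list:
                self._emit(child.leaf_id)
        return split

    # -- inference ---------------------------------------------------------
    def classify_one(self, x: Sequence[float]) -> tuple[str, str | None, dict[str, float]]:
        """Route one example; return (leaf_id, majority label, posterior).

        The posterior is the Laplace-smoothed class distribution at the
        leaf over all classes the model has seen.
        """
        if not hasattr(self, "root_"):
            raise ValidationError("model has no leaves yet; train first")
        x = [float(v) for v in x]
        self._check_x(x)
        leaf = self._route(x)
        classes = self.classes_ or []
        tot = leaf.total + len(classes)
        posterior = {
            c: (leaf.class_counts.get(c, 0) + 1) / tot if tot else 0.0
            for c in classes
        }
        return leaf.leaf_id, leaf.majority_class(), posterior

    def find_leaf(self, leaf_id: str) -> LeafNode:
        for leaf in self.iter_leaves():
            if leaf.leaf_id == leaf_id:
                return leaf
        raise ValidationError(f"no leaf with id {leaf_id!r}")

    def iter_leaves(self):
        if not hasattr(self, "root_"):
            return
        stack = [self.root_]
        while stack:
            node = stack.pop()
            if isinstance(node, SplitNode):
                stack.append(node.right)
                stack.append(node.left)
            else:
                yield node

    @property
    def n_leaves(self) -> int:
        return sum(1 for _ in self.iter_leaves())

    # -- sklearn batch surface ---------------------------------------------
    def partial_fit(self, X, y, classes=None, pointers=None) -> "HoeffdingTreeClassifier":
        """Incrementally fit on a batch (row order = stream order)."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise SchemaError("X must be 2-dimensional")
        if classes is not None:
            self._ensure_init(X.shape[1])
            for c in classes:
                self._class_set.add(str(c))
            self.classes_ = sorted(self._class_set)
        for i, (row, lab) in enumerate(zip(X, y)):
            ptr = None if pointers is None else pointers[i]
            self.learn_one(row, lab, pointer=ptr)
        return self

    def fit(self, X, y) -> "HoeffdingTreeClassifier":
        return self.partial_fit(X, y)

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return np.array([self.classify_one(row)[1] for row in X], dtype=object)

    def predict_proba(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        out = np.zeros((X.shape[0], len(self.classes_)))
        for i, row in enumerate(X):
            _, _, post = self.classify_one(row)
            out[i] = [post[c] for c in self.classes_]
        return out

    def score(self, X, y) -> float:
        return float(np.mean(self.predict(X) == np.asarray(y, dtype=object)))

    # -- serialization -------------------------------------------------------
    def _node_to_dict(self, node) -> dict:
        if isinstance(node, SplitNode):
            return {
                "kind": "split",
                "attribute": node.attribute,
                "threshold": node.threshold,
                "left": self._node_to_dict(node.left),
                "right": self._node_to_dict(node.right),
            }
        return {
            "kind": "leaf",
            "leaf_id": node.leaf_id,
            "depth": node.depth,
            "class_counts": dict(node.class_counts),
            "attr_stats": [
                {lab: s.to_list() for lab, s in d.items()} for d in node.attr_stats
            ],
            "attr_min": [None if not math.isfinite(v) else v for v in node.attr_min],
            "attr_max": [None if not math.isfinite(v) else v for v in node.attr_max],
            "pointer_list": list(node.pointer_list),
            "pointer_features": {str(p): f for p, f in node.pointer_features.items()},
            "pointer_version": node.pointer_version,
            "samples_since_split_attempt": node.samples_since_split_attempt,
            "fallback_class": node.fallback_class,
        }

    def _node_from_dict(self, d: dict):
        if d["kind"] == "split":
            return SplitNode(
                d["attribute"], d["threshold"],
                self._node_from_dict(d["left"]), self._node_from_dict(d["right"]),
            )
        leaf = LeafNode(d["leaf_id"], len(d["attr_stats"]), d["depth"])
        leaf.class_counts = {str(k): int(v) for k, v in d["class_counts"].items()}
        leaf.attr_stats = [
            {lab: _GaussianStats.from_list(v) for lab, v in attr.items()}
            for attr in d["attr_stats"]
        ]
        leaf.attr_min = [math.inf if v is None else float(v) for v in d["attr_min"]]
        leaf.attr_max = [-math.inf if v is None else float(v) for v in d["attr_max"]]
        leaf.pointer_list = [int(p) for p in d["pointer_list"]]
        leaf._pointer_set = set(leaf.pointer_list)
        leaf.pointer_features = {
            int(p): [float(v) for v in f] for p, f in d["pointer_features"].items()
        }
        leaf.pointer_version = int(d["pointer_version"])
        leaf.samples_since_split_attempt = int(d["samples_since_split_attempt"])
        leaf.fallback_class = d.get("fallback_class")
        return leaf

    def to_dict(self) -> dict:
        if not hasattr(self, "root_"):
            return {"config": self.config.to_dict(), "fitted": False}
        return {
            "config": self.config.to_dict(),
            "fitted": True,
            "n_features_in": self.n_features_in_,
            "classes": list(self.classes_),
            "leaf_counter": self._leaf_counter,
            "root": self._node_to_dict(self.root_),
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_dict(cls, d: dict) -> "HoeffdingTreeClassifier":
        cfg = VFDTConfig.from_dict(d["config"])
        tree = cls(**cfg.to_dict())
        if d.get("fitted"):
            tree.n_features_in_ = int(d["n_features_in"])
            tree.classes_ = [str(c) for c in d["classes"]]
            tree._class_set = set(tree.classes_)
            tree._leaf_counter = int(d["leaf_counter"])
            tree.root_ = tree._node_from_dict(d["root"])
        return tree

    @classmethod
    def from_json(cls, text: str) -> "HoeffdingTreeClassifier":
        return cls.from_dict(json.loads(text))

    def clone_fitted(self) -> "HoeffdingTreeClassifier":
        """Deep logical copy (used by copy-train-swap); listeners not copied."""
        return self.from_dict(self.to_dict())

    # -- auditing ------------------------------------------------------------
    def all_pointers(self) -> list[int]:
        """Union of all leaf pointer lists (order: leaf traversal order)."""
        out: list[int] = []
        for leaf in self.iter_leaves():
            out.extend(leaf.pointer_list)
        return out
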