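"""Case retrieval, text-consensus extraction, caching, and the metric baseline.

A classified leaf indexes the historical records most similar to the
current situation. Their free-text descriptions were written by different
doctors, so the same treatment appears under varying wording; before
counting, texts are grouped by token-set cosine similarity (single
linkage, with an optional synonym table) so that "same meaning, different
expression" counts as one. The most frequent group per field becomes the
output: treatment history -> medical advice, diagnosis history -> system
diagnosis, illness history -> prognosis of the current situation.

Extractions are cached per leaf and stamped with the leaf's pointer-list
version, so a cache entry is transparently invalidated the moment a new
pointer is added to that leaf.

``lsml_distance`` is the quadratic-form distance d(x_i, x_j) =
(x_i - x_j)^T P (x_i - x_j) with a positive semidefinite metric matrix P —
the patient-similarity measure used by offline metric-learning systems,
kept here as a retrieval baseline (P is supplied, never learned).
"""

from __future__ import annotations

import math
import re
from collections import Counter
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import MetricMatrixError, SchemaError, ValidationError
from .record_store import RecordStore

__all__ = [
    "TextGroup",
    "group_descriptions",
    "most_frequent",
    "format_numbered",
    "PredictionResult",
    "PredictionCache",
    "Predictor",
    "lsml_distance",
    "check_metric_matrix",
    "tokenize",
    "load_synonym_table",
]

_PUNCT = re.compile(r"[^\w\s]")


def tokenize(text: str, synonyms: Mapping[str, str] | None = None) -> frozenset[str]:
    """Lowercase, strip punctuation, split; optionally map via a synonym table."""
    tokens = _PUNCT.sub(" ", text.lower()).split()
    if synonyms:
        tokens = [synonyms.get(t, t) for t in tokens]
    return frozenset(tokens)


def _token_cosine(a: frozenset[str], b: frozenset[str]) -> float:
    if not a and not b:
        return 1.0
    if not a or not b:
        return 0.0
    return len(a & b) / math.sqrt(len(a) * len(b))


@dataclass(frozen=True)
class TextGroup:
    """One cluster of equivalent descriptions.

    ``representative`` is the most frequent exact string in the group
    (ties broken lexicographically); ``count`` is the number of input
    texts in the group; ``members`` the distinct strings with counts.
    """

    group_id: int
    representative: str
    count: int
    members: tuple[tuple[str, int], ...]


def group_descriptions(
    texts: Sequence[str],
    threshold: float = 0.5,
    synonyms: Mapping[str, str] | None = None,
) -> list[TextGroup]:
    """Single-linkage grouping of texts under token-set cosine >= threshold.

    Every text lands in exactly one group, so group counts sum to
    ``len(texts)``. Similarity depends only on the token set, so exact
    duplicates are collapsed before the pairwise pass; the result is
    identical to grouping text-by-text. Groups are returned ordered by
    count (descending), ties by representative string.
    """
    if not texts:
        raise ValidationError("texts must be non-empty")
    if not (0.0 <= threshold <= 1.0):
        raise ValidationError(f"threshold must be in [0,1], got {threshold}")
    counts = Counter(texts)
    distinct = sorted(counts)
    toksets = [tokenize(t, synonyms) for t in distinct]
    # union-find over distinct strings
    parent = list(range(len(distinct)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(distinct)):
        for j in range(i + 1, len(distinct)):
            if _token_cosine(toksets[i], toksets[j]) >= threshold:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)

    clusters: dict[int, list[int]] = {}
    for i in range(len(distinct)):
        clusters.setdefault(find(i), []).append(i)

    groups: list[TextGroup] = []
    for members_idx in clusters.values():
        members = [(distinct[i], counts[distinct[i]]) for i in members_idx]
        # representative: most frequent exact string, ties lexicographic
        rep = min(members, key=lambda m: (-m[1], m[0]))[0]
        total = sum(c for _, c in members)
        members.sort(key=lambda m: (-m[1], m[0]))
        groups.append(TextGroup(0, rep, total, tuple(members)))
    groups.sort(key=lambda g: (-g.count, g.representative))
    return [
        TextGroup(i + 1, g.representative, g.count, g.members)
        for i, g in enumerate(groups)
    ]


def most_frequent(groups: Sequence[TextGroup], k: int = 3) -> list[tuple[str, int]]:
    """Top-k group representatives with counts, most frequent first.

    Ties broken by representative string so output is deterministic.
    """
    if k < 1:
        raise ValidationError(f"k must be >= 1, got {k}")
    ranked = sorted(groups, key=lambda g: (-g.count, g.representative))
    return [(g.representative, g.count) for g in ranked[:k]]


def format_numbered(items: Sequence[tuple[str, int]]) -> str:
    """Render ranked texts as a numbered list: ``1.XXX 2.YYY 3.ZZZ``."""
    return " ".join(f"{i + 1}.{text}" for i, (text, _) in enumerate(items))


# ---------------------------------------------------------------------------
# Prediction results and cache
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PredictionResult:
    """Actionable output for one classified leaf."""

    leaf_id: str
    class_label: str | None
    retrieved_rids: tuple[str, ...]
    treatments: tuple[tuple[str, int], ...]
    diagnoses: tuple[tuple[str, int], ...]
    prognoses: tuple[tuple[str, int], ...]
    cache_hit: bool
    empty_leaf: bool = False

    def formatted(self) -> dict[str, str]:
        return {
            "treatment": format_numbered(self.treatments),
            "diagnosis": format_numbered(self.diagnoses),
            "prognosis": format_numbered(self.prognoses),
        }

    def to_dict(self) -> dict:
        d = asdict(self)
        d["retrieved_rids"] = list(self.retrieved_rids)
        d["treatments"] = [list(t) for t in self.treatments]
        d["diagnoses"] = [list(t) for t in self.diagnoses]
        d["prognoses"] = [list(t) for t in self.prognoses]
        return d

    def same_content(self, other: "PredictionResult") -> bool:
        """Field equality ignoring the cache_hit flag."""
        return (
            self.leaf_id == other.leaf_id
            and self.class_label == other.class_label
            and self.retrieved_rids == other.retrieved_rids
            and self.treatments == other.treatments
            and self.diagnoses == other.diagnoses
            and self.prognoses == other.prognoses
            and self.empty_leaf == other.empty_leaf
        )


class PredictionCache:
    """Per-leaf memoized extractions stamped with the pointer-list version."""

    def __init__(self) -> None:
        self._entries: dict[str, tuple[int, PredictionResult]] = {}
        self.hits = 0
        self.misses = 0

    def get(self, leaf_id: str, version: int) -> PredictionResult | None:
        entry = self._entries.get(leaf_id)
        if entry is None or entry[0] != version:
            # version mismatch == stale: drop it eagerly
            self._entries.pop(leaf_id, None)
            return None
        return entry[1]

    def put(self, leaf_id: str, version: int, result: PredictionResult) -> None:
        self._entries[leaf_id] = (version, result)

    def invalidate(self, leaf_id: str) -> None:
        """Drop a leaf's entry; no-op when absent (idempotent)."""
        self._entries.pop(leaf_id, None)

    def __contains__(self, leaf_id: str) -> bool:
        return leaf_id in self._entries

    @property
    def hit_rate(self) -> float:
        tot = self.hits + self.misses
        return self.hits / tot if tot else 0.0


class Predictor:
    """Turns a classified leaf into retrieved cases plus text consensus.

    Subscribes to the tree's Adder events so cached extractions are cleared
    the moment a new pointer reaches their leaf; version stamps make the
    cache safe even if an event is missed (e.g. after deserialization).
    """

    def __init__(
        self,
        tree,
        store: RecordStore,
        threshold: float = 0.5,
        top_k: int = 3,
        synonyms: Mapping[str, str] | None = None,
        cache: PredictionCache | None = None,
    ) -> None:
        self.tree = tree
        self.store = store
        self.threshold = threshold
        self.top_k = top_k
        self.synonyms = dict(synonyms) if synonyms else None
        self.cache = cache if cache is not None else PredictionCache()
        tree.add_pointer_listener(self.cache.invalidate)

    def rebind(self, tree) -> None:
        """Point at a new live tree (after copy-train-swap)."""
        self.tree = tree
        tree.add_pointer_listener(self.cache.invalidate)

    def _extract(self, leaf) -> PredictionResult:
        records = self.store.resolve_many(leaf.pointer_list)
        label = leaf.majority_class()
        if not records:
            return PredictionResult(
                leaf.leaf_id, label, (), (), (), (),
                cache_hit=False, empty_leaf=True,
            )

        def consensus(texts: list[str]) -> tuple[tuple[str, int], ...]:
            groups = group_descriptions(texts, self.threshold, self.synonyms)
            return tuple(most_frequent(groups, self.top_k))

        return PredictionResult(
            leaf_id=leaf.leaf_id,
            class_label=label,
            retrieved_rids=tuple(r.rid for r in records),
            treatments=consensus([r.treatment_text for r in records]),
            diagnoses=consensus([r.diagnosis_text for r in records]),
            prognoses=consensus([r.illness_history_text for r in records]),
            cache_hit=False,
        )

    def predict(self, leaf_id: str) -> PredictionResult:
        """Cached extraction for a leaf; recomputes when the leaf changed."""
        leaf = self.tree.find_leaf(leaf_id)
        cached = self.cache.get(leaf_id, leaf.pointer_version)
        if cached is not None:
            self.cache.hits += 1
            return PredictionResult(**{**asdict(cached), "cache_hit": True})
        self.cache.misses += 1
        result = self._extract(leaf)
        self.cache.put(leaf_id, leaf.pointer_version, result)
        return result

    def predict_fresh(self, leaf_id: str) -> PredictionResult:
        """From-scratch extraction bypassing the cache (audit oracle)."""
        return self._extract(self.tree.find_leaf(leaf_id))


# ---------------------------------------------------------------------------
# Metric-distance baseline
# ---------------------------------------------------------------------------

_PSD_TOL = 1e-8


def check_metric_matrix(P: np.ndarray, tol: float = _PSD_TOL) -> np.ndarray:
    """Validate that P is square, symmetric, PSD (eigenvalues >= -tol)."""
    P = np.asarray(P, dtype=float)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise MetricMatrixError(f"P must be square, got shape {P.shape}")
    if not np.allclose(P, P.T, atol=tol):
        raise MetricMatrixError("P must be symmetric")
    eigmin = float(np.linalg.eigvalsh(P).min())
    if eigmin < -tol:
        raise MetricMatrixError(f"P not PSD: smallest eigenvalue {eigmin}")
    return P


def lsml_distance(x_i, x_j, P) -> float:
    """Quadratic-form patient distance (x_i - x_j)^T P (x_i - x_j).

    Nonnegative for PSD P; zero when x_i == x_j; with P = I it is the
    squared Euclidean distance.
    """
    x_i = np.asarray(x_i, dtype=float)
    x_j = np.asarray(x_j, dtype=float)
    if x_i.shape != x_j.shape or x_i.ndim != 1:
        raise SchemaError(f"shape mismatch: {x_i.shape} vs {x_j.shape}")
    P = check_metric_matrix(P)
    if P.shape[0] != x_i.shape[0]:
        raise SchemaError(
            f"P is {P.shape[0]}x{P.shape[0]} but vectors have {x_i.shape[0]} dims"
        )
    d = x_i - x_j
    return float(d @ P @ d)


def load_synonym_table(path) -> dict[str, str]:
    """Read a two-column TSV (term, canonical) into a substitution map."""
    table: dict[str, str] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            term, canonical = line.split("\t")
            table[term.strip().lower()] = canonical.strip().lower()
    return table
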