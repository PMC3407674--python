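"""End-to-end wiring: configuration, training, streaming, feedback, persistence.

The pipeline: vital-sign stream -> data units -> feature vectors -> the
pointer-augmented tree -> classified leaf -> case retrieval and text
consensus; doctor feedback loops back into the store and, via
copy-train-swap, into the live tree.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Callable, Iterable, Iterator

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError as _PydanticError

from .errors import ConfigurationError, StoreIOError, ValidationError
from .feedback import FeedbackEvent, normalize
from .prediction import PredictionResult, Predictor, load_synonym_table
from .record_store import MedicalRecord, RecordStore
from .stream_units import (
    DataUnit,
    StreamSegmenter,
    VitalSample,
    FEATURE_SCHEMES,
    featurize,
)
from .vfdt import HoeffdingTreeClassifier, VFDTConfig

__all__ = ["EngineConfig", "VFDTSettings", "Engine", "records_from_jsonl"]

logger = logging.getLogger("vitalcds")

MODEL_FILE = "model.json"
CONFIG_FILE = "config.json"
STORE_DIR = "store"


class VFDTSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")

    delta: float = 1e-6
    tau: float = 0.05
    grace_period: int = Field(default=200, ge=1)
    max_depth: int | None = None
    pointer_cap: int | None = None
    seed: int = 0

    def to_vfdt_config(self) -> VFDTConfig:
        return VFDTConfig(**self.model_dump())


class EngineConfig(BaseModel):
    """Validated engine configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    vfdt: VFDTSettings = Field(default_factory=VFDTSettings)
    unit_size: int = Field(default=3, ge=1)
    feature_scheme: str = "mean-slope-min-max"
    similarity_threshold: float = Field(default=0.5, ge=0.0, le=1.0)
    top_k: int = Field(default=3, ge=1)
    eager_reextract: bool = True
    synonym_table: str | None = None
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "EngineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "EngineConfig":
        try:
            cfg = cls(**raw)
        except _PydanticError as exc:
            raise ConfigurationError(str(exc)) from exc
        if cfg.feature_scheme not in FEATURE_SCHEMES:
            raise ConfigurationError(
                f"unknown feature scheme {cfg.feature_scheme!r}"
            )
        return cfg


def records_from_jsonl(path) -> Iterator[MedicalRecord]:
    """Read a record corpus: one JSON record per line."""
    try:
        fh = open(path, "r", encoding="utf-8")
    except OSError as exc:
        raise StoreIOError(f"cannot read record source {path}: {exc}") from exc
    with fh:
        for line in fh:
            line = line.strip()
            if line:
                yield MedicalRecord.from_json(line)


class Engine:
    """The assembled decision-support system.

    Holds the live tree, the record store, the predictor with its cache,
    and the stream segmenter. All mutation goes through methods that keep
    the invariants: every registered pointer lives in exactly one leaf,
    the mapping table stays a bijection, and the cache is semantically
    transparent.
    """

    def __init__(self, config: EngineConfig, directory: str | Path) -> None:
        self.config = config
        self.directory = Path(directory)
        self.directory.mkdir(parents=True, exist_ok=True)
        self.store = RecordStore(self.directory / STORE_DIR)
        self.tree = HoeffdingTreeClassifier(**config.vfdt.to_vfdt_config().to_dict())
        synonyms = (
            load_synonym_table(config.synonym_table) if config.synonym_table else None
        )
        self.predictor = Predictor(
            self.tree,
            self.store,
            threshold=config.similarity_threshold,
            top_k=config.top_k,
            synonyms=synonyms,
        )
        self.segmenter = StreamSegmenter(config.unit_size)

    # -- training ---------------------------------------------------------
    def train_record(self, record: MedicalRecord) -> tuple[int, str]:
        """Register one record and train the live tree with its pointer."""
        pointer = self.store.register_record(record)
        leaf_id = self.tree.learn_one(
            record.features, record.class_label, pointer=pointer
        )
        logger.debug("trained %s -> pointer %d -> leaf %s",
                     record.rid, pointer, leaf_id)
        return pointer, leaf_id

    def run_initial_training(self, records: Iterable[MedicalRecord]) -> dict:
        """Train from a historical record library; every record gets a pointer."""
        n = 0
        for record in records:
            self.train_record(record)
            n += 1
        summary = {
            "records_trained": n,
            "n_leaves": self.tree.n_leaves if hasattr(self.tree, "root_") else 0,
            "n_classes": len(getattr(self.tree, "classes_", [])),
        }
        logger.info("initial training: %s", summary)
        return summary

    # -- streaming --------------------------------------------------------
    def classify_unit(self, unit: DataUnit):
        feats = featurize(unit, self.config.feature_scheme)
        return feats, self.tree.classify_one(feats)

    def process_unit(self, unit: DataUnit, learn: bool = True) -> dict:
        """Featurize -> classify -> predict for one unit; optionally do the
        prequential train step when the unit carries a ground-truth label."""
        feats, (leaf_id, label, posterior) = self.classify_unit(unit)
        result = self.predictor.predict(leaf_id)
        out = {
            "unit_id": unit.unit_id,
            "leaf_id": leaf_id,
            "class_label": label,
            "posterior": posterior,
            "cache_hit": result.cache_hit,
            "retrieved_rids": list(result.retrieved_rids),
            **{k: v for k, v in result.formatted().items()},
            "empty_leaf": result.empty_leaf,
        }
        truth = unit.label
        if truth is not None:
            out["true_label"] = truth
            out["correct"] = truth == label
            if learn:
                self.tree.learn_one(feats, truth)
        return out

    def run_stream(
        self,
        samples: Iterable[VitalSample | None],
        learn: bool = True,
        sink: Callable[[dict], None] | None = None,
    ) -> dict:
        """Consume a stream; emit one result per complete unit.

        ``samples`` may contain ``None`` entries standing for rows that
        failed to parse; they are counted and skipped. Returns the run
        summary (counts, accuracy when labels were present, cache hit rate).
        """
        n_in = n_skipped = n_units = n_labeled = n_correct = 0
        window: list[bool] = []
        for s in samples:
            n_in += 1
            if s is None:
                n_skipped += 1
                continue
            for unit in self.segmenter.push([s]):
                res = self.process_unit(unit, learn=learn)
                n_units += 1
                if "correct" in res:
                    n_labeled += 1
                    n_correct += int(res["correct"])
                    window.append(res["correct"])
                if sink is not None:
                    sink(res)
        summary = {
            "samples_in": n_in,
            "rows_skipped": n_skipped,
            "units_out": n_units,
            "units_labeled": n_labeled,
            "prequential_accuracy": (n_correct / n_labeled) if n_labeled else None,
            "prequential_accuracy_last_1000": (
                sum(window[-1000:]) / len(window[-1000:]) if window else None
            ),
            "cache_hit_rate": self.predictor.cache.hit_rate,
            "carry_buffer": len(self.segmenter.carry),
        }
        logger.info("stream run: %s", summary)
        return summary

    # -- feedback (copy-train-swap) ---------------------------------------
    def ingest(self, event: FeedbackEvent,
               _before_swap: Callable[["Engine"], None] | None = None) -> int:
        """Fold a doctor-confirmed diagnosis into the system.

        Store append happens first (never lose the record), then the live
        tree is cloned, the clone trained with the new pointer, and the
        clone swapped in atomically. ``_before_swap`` is an audit hook
        invoked between clone-training and the swap; queries issued there
        are served by the untouched pre-ingest tree.
        """
        record = normalize(event, self.store.next_rid(), self.config.feature_scheme)
        pointer = self.store.register_record(record)
        clone = self.tree.clone_fitted()
        leaf_id = clone.learn_one(record.features, record.class_label, pointer=pointer)
        if _before_swap is not None:
            _before_swap(self)
        # atomic swap: one assignment makes the clone the live tree
        self.tree = clone
        self.predictor.rebind(clone)
        self.predictor.cache.invalidate(leaf_id)
        logger.info("ingested %s as pointer %d into leaf %s",
                    record.rid, pointer, leaf_id)
        if self.config.eager_reextract:
            self.predictor.predict(leaf_id)
        return pointer

    # -- persistence -------------------------------------------------------
    def save(self) -> None:
        (self.directory / CONFIG_FILE).write_text(
            json.dumps(self.config.model_dump(), indent=2) + "\n", encoding="utf-8"
        )
        (self.directory / MODEL_FILE).write_text(
            self.tree.to_json() + "\n", encoding="utf-8"
        )

    @classmethod
    def load(cls, directory: str | Path) -> "Engine":
        directory = Path(directory)
        cfg_path = directory / CONFIG_FILE
        if not cfg_path.exists():
            raise StoreIOError(f"no engine at {directory}")
        config = EngineConfig.from_dict(json.loads(cfg_path.read_text()))
        engine = cls(config, directory)
        model_path = directory / MODEL_FILE
        if model_path.exists():
            engine.tree = HoeffdingTreeClassifier.from_json(model_path.read_text())
            engine.predictor.rebind(engine.tree)
        engine._reconcile()
        return engine

    def _reconcile(self) -> None:
        """Re-train pointers that reached the store but not the saved tree
        (a crash between store append and tree swap leaves exactly these)."""
        if not len(self.store):
            return
        orphans = self.store.orphaned_records(self.tree.all_pointers())
        for pointer in orphans:
            record = self.store.resolve(pointer)
            leaf_id = self.tree.learn_one(
                record.features, record.class_label, pointer=pointer
            )
            logger.warning(
                "reconciled orphaned record %s (pointer %d) into leaf %s",
                record.rid, pointer, leaf_id,
            )

    # -- audit helpers ------------------------------------------------------
    def check_invariants(self) -> dict:
        """Pointer conservation + mapping bijection, as a machine-readable dict."""
        tree_pointers = self.tree.all_pointers() if hasattr(self.tree, "root_") else []
        mapping = self.store.mapping
        rids = [rid for rid, _ in mapping.values()]
        return {
            "n_pointers_in_tree": len(tree_pointers),
            "pointers_unique_across_leaves": len(tree_pointers) == len(set(tree_pointers)),
            "tree_store_pointer_sets_equal": set(tree_pointers) == set(mapping),
            "pointers_sequential": sorted(mapping) == list(range(1, len(mapping) + 1)),
            "rid_bijection": len(set(rids)) == len(rids),
        }
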