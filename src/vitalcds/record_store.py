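"""Persistent medical-record store with a pointer mapping table.

Records live in an append-only JSON-lines file; the mapping table is a TSV
of (pointer value, record ID, physical address) rows, where the physical
address is the record file name plus the byte offset of the record's line.
Pointer values are assigned sequentially from 1 in registration order, so
the first record R1 gets pointer P1 with value 1, and pointer <-> record ID
is a bijection for the life of the store. Pointers are never reused.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Sequence

from .errors import (
    DuplicateRecordError,
    SchemaError,
    StorageCorruptionError,
    UnknownPointerError,
)

__all__ = ["MedicalRecord", "RecordStore"]

RECORDS_FILE = "records.jsonl"
MAPPING_FILE = "mapping.tsv"
_MAPPING_HEADER = "pointer\trid\taddress"


@dataclass(frozen=True)
class MedicalRecord:
    """One historical case: features, class label, free-text description.

    The free text covers the treatment given, the diagnosis made, and the
    illness history — written by different doctors, so semantically
    equivalent descriptions vary in wording.
    """

    rid: str
    features: tuple[float, ...]
    class_label: str
    treatment_text: str
    diagnosis_text: str
    illness_history_text: str

    def to_json(self) -> str:
        d = asdict(self)
        d["features"] = list(self.features)
        return json.dumps(d, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "MedicalRecord":
        d = json.loads(text)
        return cls(
            rid=str(d["rid"]),
            features=tuple(float(v) for v in d["features"]),
            class_label=str(d["class_label"]),
            treatment_text=str(d["treatment_text"]),
            diagnosis_text=str(d["diagnosis_text"]),
            illness_history_text=str(d["illness_history_text"]),
        )


class RecordStore:
    """Append-only record store under a directory.

    Reopening the directory reloads the mapping table and record index;
    the store is the durable source of truth for the engine.
    """

    def __init__(self, directory: str | Path) -> None:
        self.directory = Path(directory)
        self.directory.mkdir(parents=True, exist_ok=True)
        self.records_path = self.directory / RECORDS_FILE
        self.mapping_path = self.directory / MAPPING_FILE
        # pointer -> (rid, address string)
        self._mapping: dict[int, tuple[str, str]] = {}
        self._rids: set[str] = set()
        self._schema_dim: int | None = None
        self._load()

    def _load(self) -> None:
        if not self.mapping_path.exists():
            return
        with open(self.mapping_path, "r", encoding="utf-8") as fh:
            header = fh.readline().rstrip("\n")
            if header != _MAPPING_HEADER:
                raise StorageCorruptionError(
                    f"bad mapping table header: {header!r}"
                )
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                p, rid, addr = line.split("\t")
                self._mapping[int(p)] = (rid, addr)
                self._rids.add(rid)
        if self._mapping:
            # Schema dim from any stored record.
            first = self.resolve(min(self._mapping))
            self._schema_dim = len(first.features)

    def __len__(self) -> int:
        return len(self._mapping)

    @property
    def next_pointer(self) -> int:
        return len(self._mapping) + 1

    def next_rid(self) -> str:
        """Mint the next sequential record ID (R1, R2, ...)."""
        return f"R{len(self._mapping) + 1}"

    @property
    def mapping(self) -> dict[int, tuple[str, str]]:
        """Pointer -> (rid, address); a copy, safe to mutate."""
        return dict(self._mapping)

    def register_record(self, record: MedicalRecord) -> int:
        """Persist a record; append a mapping row; return its pointer value."""
        if record.rid in self._rids:
            raise DuplicateRecordError(f"record ID {record.rid!r} already stored")
        if self._schema_dim is None:
            self._schema_dim = len(record.features)
        elif len(record.features) != self._schema_dim:
            raise SchemaError(
                f"record {record.rid}: {len(record.features)} features, "
                f"store schema has {self._schema_dim}"
            )
        line = record.to_json() + "\n"
        with open(self.records_path, "a", encoding="utf-8") as fh:
            offset = fh.tell()
            fh.write(line)
        pointer = len(self._mapping) + 1
        address = f"{RECORDS_FILE}:{offset}"
        write_header = not self.mapping_path.exists()
        with open(self.mapping_path, "a", encoding="utf-8") as fh:
            if write_header:
                fh.write(_MAPPING_HEADER + "\n")
            fh.write(f"{pointer}\t{record.rid}\t{address}\n")
        self._mapping[pointer] = (record.rid, address)
        self._rids.add(record.rid)
        return pointer

    def resolve(self, pointer: int) -> MedicalRecord:
        """Load the record a pointer maps to, via its physical address."""
        pointer = int(pointer)
        if pointer not in self._mapping:
            raise UnknownPointerError(f"pointer {pointer} not in mapping table")
        rid, address = self._mapping[pointer]
        fname, _, off = address.partition(":")
        path = self.directory / fname
        try:
            with open(path, "r", encoding="utf-8") as fh:
                fh.seek(int(off))
                line = fh.readline()
            record = MedicalRecord.from_json(line)
        except (OSError, ValueError, KeyError) as exc:
            raise StorageCorruptionError(
                f"address {address!r} for pointer {pointer} unreadable: {exc}"
            ) from exc
        if record.rid != rid:
            raise StorageCorruptionError(
                f"pointer {pointer}: address holds {record.rid!r}, mapping says {rid!r}"
            )
        return record

    def resolve_many(self, pointers: Iterable[int]) -> list[MedicalRecord]:
        """Resolve pointers in order; one bad pointer fails the whole batch."""
        ptrs = [int(p) for p in pointers]
        missing = [p for p in ptrs if p not in self._mapping]
        if missing:
            raise UnknownPointerError(f"pointers not in mapping table: {missing}")
        return [self.resolve(p) for p in ptrs]

    def rid_of(self, pointer: int) -> str:
        if int(pointer) not in self._mapping:
            raise UnknownPointerError(f"pointer {pointer} not in mapping table")
        return self._mapping[int(pointer)][0]

    def orphaned_records(self, trained_pointers: Iterable[int]) -> list[int]:
        """Pointers present in the store but absent from a trained model.

        Used by startup reconciliation: a crash between store append and
        tree swap leaves such an orphan, which is re-trained on startup.
        """
        trained = set(int(p) for p in trained_pointers)
        return sorted(p for p in self._mapping if p not in trained)
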