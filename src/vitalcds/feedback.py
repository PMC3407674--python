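"""Doctor feedback: normalization into records and copy-train-swap updates.

A confirmed diagnosis arrives as a free-form event; it is rewritten into
the uniform record format (canonical whitespace/casing/punctuation, a
freshly minted sequential record ID) and appended to the store, and the
live tree is updated by *copy-train-swap*: clone the running tree, train
the clone with the new record and its pointer, then atomically swap the
clone in. Classification is therefore never served by a half-trained
model — queries issued before the swap see exactly the pre-ingest tree.

The store append happens before the swap, so a crash in between can leave
an orphaned record (in the store, missing from the tree); startup
reconciliation detects and re-trains such orphans rather than ever losing
a doctor's record.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass

from .errors import ValidationError
from .record_store import MedicalRecord
from .stream_units import DataUnit, VitalSample, featurize

__all__ = ["FeedbackEvent", "canonicalize_text", "normalize"]

_WS = re.compile(r"\s+")
_TRAIL_PUNCT = re.compile(r"[\s\.\,\;\:\!]+$")


@dataclass(frozen=True)
class FeedbackEvent:
    """One doctor-confirmed diagnosis to be folded into the system.

    Either ``features`` (already in the classifier schema) or ``samples``
    (a raw data unit, to be featurized) must be present.
    """

    class_label: str
    treatment_text: str
    diagnosis_text: str
    illness_history_text: str
    features: tuple[float, ...] | None = None
    samples: tuple[VitalSample, ...] | None = None

    @classmethod
    def from_dict(cls, d: dict) -> "FeedbackEvent":
        samples = None
        if d.get("samples"):
            samples = tuple(
                VitalSample(float(s["timestamp"]), tuple(float(v) for v in s["channels"]))
                for s in d["samples"]
            )
        features = None
        if d.get("features") is not None:
            features = tuple(float(v) for v in d["features"])
        return cls(
            class_label=str(d.get("class_label", "")),
            treatment_text=str(d.get("treatment_text", "")),
            diagnosis_text=str(d.get("diagnosis_text", "")),
            illness_history_text=str(d.get("illness_history_text", "")),
            features=features,
            samples=samples,
        )

    @classmethod
    def from_json(cls, text: str) -> "FeedbackEvent":
        return cls.from_dict(json.loads(text))


def canonicalize_text(text: str) -> str:
    """Uniform format: lowercase, collapsed whitespace, no trailing punctuation.

    Idempotent: canonicalize(canonicalize(t)) == canonicalize(t).
    """
    t = _WS.sub(" ", text.strip()).lower()
    return _TRAIL_PUNCT.sub("", t)


def normalize(event: FeedbackEvent, rid: str,
              scheme: str = "mean-slope-min-max") -> MedicalRecord:
    """Rewrite a feedback event into the uniform medical-record format.

    The record ID is minted by the caller (the store assigns them
    sequentially). Features are taken as given, or computed from the raw
    data unit with the engine's featurization scheme — identical to a
    direct ``featurize`` call on the same unit.
    """
    if not event.class_label.strip():
        raise ValidationError("feedback event has no class label")
    if event.features is not None:
        features = tuple(float(v) for v in event.features)
    elif event.samples:
        unit = DataUnit(0, tuple(event.samples))
        features = tuple(float(v) for v in featurize(unit, scheme))
    else:
        raise ValidationError("feedback event has neither features nor samples")
    return MedicalRecord(
        rid=rid,
        features=features,
        class_label=canonicalize_text(event.class_label),
        treatment_text=canonicalize_text(event.treatment_text),
        diagnosis_text=canonicalize_text(event.diagnosis_text),
        illness_history_text=canonicalize_text(event.illness_history_text),
    )
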