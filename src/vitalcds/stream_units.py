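"""Vital-sign stream segmentation and featurization.

A monitored patient produces a multivariate time series: at each time point
a vector of numeric readings, one per monitor channel (blood pressure, an
ECG-derived rate, an EEG index, body temperature, ...). Consecutive time
points are grouped into fixed-length *data units* — e.g. with ``unit_size=3``
the stream T1, T2, ... becomes U1={T1,T2,T3}, U2={T4,T5,T6} — and each unit
is summarized into one feature vector, the instance the classifier consumes.
A unit therefore represents the short-term level and trend of the patient's
state over a small window of readings.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, MalformedStreamError, StreamOrderingError

__all__ = [
    "VitalSample",
    "DataUnit",
    "StreamSegmenter",
    "segment",
    "featurize",
    "feature_names",
    "read_stream_csv",
    "FEATURE_SCHEMES",
]


@dataclass(frozen=True)
class VitalSample:
    """One timestamped multichannel reading.

    Parameters
    ----------
    timestamp : float
        Monotone time index; used only for ordering, not for slopes.
    channels : tuple of float
        Ordered readings, one per monitor. The channel count must be
        constant across a stream.
    label : str or None
        Optional ground-truth class label (present on training/simulated
        streams, absent on live ones).
    """

    timestamp: float
    channels: tuple[float, ...]
    label: str | None = None


@dataclass(frozen=True)
class DataUnit:
    """A window of exactly ``unit_size`` consecutive samples."""

    unit_id: int
    samples: tuple[VitalSample, ...]

    @property
    def n_channels(self) -> int:
        return len(self.samples[0].channels)

    @property
    def label(self) -> str | None:
        """Majority label of the member samples (ties by first occurrence)."""
        labels = [s.label for s in self.samples if s.label is not None]
        if not labels:
            return None
        best, best_n = labels[0], 0
        counts: dict[str, int] = {}
        for lab in labels:
            counts[lab] = counts.get(lab, 0) + 1
            if counts[lab] > best_n:
                best, best_n = lab, counts[lab]
        return best


def _check_sample(sample: VitalSample, n_channels: int | None) -> int:
    k = len(sample.channels)
    if n_channels is not None and k != n_channels:
        raise MalformedStreamError(
            f"inconsistent channel count: expected {n_channels}, got {k} "
            f"at t={sample.timestamp}"
        )
    return k


class StreamSegmenter:
    """Stateful segmenter with a carry buffer for resumable streaming.

    Complete units are emitted as soon as ``unit_size`` consecutive samples
    have arrived; a trailing partial window is retained, never emitted.
    """

    def __init__(self, unit_size: int = 3) -> None:
        if unit_size < 1:
            raise ConfigurationError(f"unit_size must be >= 1, got {unit_size}")
        self.unit_size = unit_size
        self._carry: list[VitalSample] = []
        self._next_unit_id = 0
        self._last_ts: float | None = None
        self._n_channels: int | None = None

    @property
    def carry(self) -> tuple[VitalSample, ...]:
        return tuple(self._carry)

    def push(self, samples: Iterable[VitalSample]) -> list[DataUnit]:
        """Feed samples; return every complete unit they close."""
        out: list[DataUnit] = []
        for s in samples:
            self._n_channels = self._n_channels or _check_sample(s, self._n_channels)
            _check_sample(s, self._n_channels)
            if self._last_ts is not None and s.timestamp <= self._last_ts:
                raise StreamOrderingError(
                    f"timestamps must strictly increase: {s.timestamp} after {self._last_ts}"
                )
            self._last_ts = s.timestamp
            self._carry.append(s)
            if len(self._carry) == self.unit_size:
                out.append(DataUnit(self._next_unit_id, tuple(self._carry)))
                self._next_unit_id += 1
                self._carry.clear()
        return out

    # -- resumable-stream state ------------------------------------------
    def state_dict(self) -> dict:
        return {
            "unit_size": self.unit_size,
            "next_unit_id": self._next_unit_id,
            "last_ts": self._last_ts,
            "carry": [
                {"timestamp": s.timestamp, "channels": list(s.channels), "label": s.label}
                for s in self._carry
            ],
        }

    def to_json(self) -> str:
        return json.dumps(self.state_dict())

    @classmethod
    def from_state(cls, state: dict) -> "StreamSegmenter":
        seg = cls(state["unit_size"])
        seg._next_unit_id = state["next_unit_id"]
        seg._last_ts = state["last_ts"]
        seg._carry = [
            VitalSample(d["timestamp"], tuple(d["channels"]), d.get("label"))
            for d in state["carry"]
        ]
        if seg._carry:
            seg._n_channels = len(seg._carry[0].channels)
        return seg

    @classmethod
    def from_json(cls, text: str) -> "StreamSegmenter":
        return cls.from_state(json.loads(text))


def segment(
    samples: Sequence[VitalSample], unit_size: int
) -> tuple[list[DataUnit], tuple[VitalSample, ...]]:
    """Segment a finite sample sequence into complete units plus the carry.

    Returns ``floor(n / unit_size)`` units in order and the trailing
    ``n mod unit_size`` samples as the carry buffer.
    """
    if not samples:
        raise MalformedStreamError("empty sample sequence")
    seg = StreamSegmenter(unit_size)
    units = seg.push(samples)
    return units, seg.carry


# ---------------------------------------------------------------------------
# Featurization
# ---------------------------------------------------------------------------

def _mean_slope_min_max(values: np.ndarray) -> list[float]:
    # values: (n_samples,) for one channel; equispaced within the unit.
    n = values.shape[0]
    mean = float(values.mean())
    if n == 1:
        slope = 0.0
    else:
        t = np.arange(n, dtype=float)
        t -= t.mean()
        slope = float((t @ (values - mean)) / (t @ t))
    return [mean, slope, float(values.min()), float(values.max())]


def _mean_only(values: np.ndarray) -> list[float]:
    return [float(values.mean())]


FEATURE_SCHEMES: dict[str, tuple[tuple[str, ...], object]] = {
    "mean-slope-min-max": (("mean", "slope", "min", "max"), _mean_slope_min_max),
    "mean": (("mean",), _mean_only),
}


def featurize(unit: DataUnit, scheme: str = "mean-slope-min-max") -> np.ndarray:
    """Summarize a unit into one numeric vector, channel-major.

    The default scheme emits per-channel (mean, least-squares slope, min,
    max): the mean/min/max capture the level of the reading over the window
    and the slope its direction, i.e. the short-term trend. Slopes are fit
    against equispaced within-unit positions, so with ``unit_size=1`` the
    mean equals the raw reading and the slope is 0.
    """
    if scheme not in FEATURE_SCHEMES:
        raise ConfigurationError(
            f"unknown feature scheme {scheme!r}; known: {sorted(FEATURE_SCHEMES)}"
        )
    _, fn = FEATURE_SCHEMES[scheme]
    mat = np.array([s.channels for s in unit.samples], dtype=float)  # (n, k)
    out: list[float] = []
    for ch in range(mat.shape[1]):
        out.extend(fn(mat[:, ch]))
    return np.asarray(out, dtype=float)


def feature_names(n_channels: int, scheme: str = "mean-slope-min-max") -> list[str]:
    """Deterministic channel-major feature names, e.g. ``ch1_mean``."""
    if scheme not in FEATURE_SCHEMES:
        raise ConfigurationError(f"unknown feature scheme {scheme!r}")
    parts, _ = FEATURE_SCHEMES[scheme]
    return [f"ch{c + 1}_{p}" for c in range(n_channels) for p in parts]


# ---------------------------------------------------------------------------
# Stream I/O
# ---------------------------------------------------------------------------

def read_stream_csv(path) -> Iterator[VitalSample]:
    """Read a vital-sign stream CSV: ``timestamp,ch1,...,chk[,label]``."""
    df = pd.read_csv(path)
    cols = list(df.columns)
    if not cols or cols[0] != "timestamp":
        raise MalformedStreamError(
            f"stream CSV must start with a 'timestamp' column, got {cols[:1]}"
        )
    has_label = cols[-1] == "label"
    ch_cols = cols[1:-1] if has_label else cols[1:]
    if not ch_cols:
        raise MalformedStreamError("stream CSV has no channel columns")
    for row in df.itertuples(index=False):
        vals = tuple(float(getattr(row, c)) for c in ch_cols)
        if any(np.isnan(v) for v in vals):
            raise MalformedStreamError(
                f"missing channel reading at t={row.timestamp}"
            )
        label = str(row.label) if has_label else None
        yield VitalSample(float(row.timestamp), vals, label)


def write_stream_csv(path, samples: Iterable[VitalSample]) -> None:
    samples = list(samples)
    if not samples:
        raise MalformedStreamError("nothing to write")
    k = len(samples[0].channels)
    has_label = samples[0].label is not None
    rows = []
    for s in samples:
        row = {"timestamp": s.timestamp}
        row.update({f"ch{i + 1}": v for i, v in enumerate(s.channels)})
        if has_label:
            row["label"] = s.label
        rows.append(row)
    cols = ["timestamp"] + [f"ch{i + 1}" for i in range(k)] + (
        ["label"] if has_label else []
    )
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)
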