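"""Synthetic vital-sign streams and medical-record corpora with ground truth.

Each illness class is a *regime*: per-channel Gaussian means, noise
standard deviations, optional linear drift, and categorical phrase
distributions (treatment / diagnosis / illness history) with a designated
modal phrase. Streams are generated unit-by-unit — every unit is drawn
wholly from one regime, so a unit has a single ground-truth label — and
records pair one synthesized unit's features with sampled text fields.

The default regimes use four channels named after common bedside monitors
(systolic blood pressure, ECG-derived heart rate, an EEG index, body
temperature) with plausible values; tests rely only on the stated regime
parameters, not on physiological realism. Phrase distributions include
paraphrase variants sharing most of their tokens with the modal phrase,
exercising description grouping downstream.

A manifest records the regime parameters, the planted modal phrases, and
the Bayes error of the regime mixture (exact for two equal-covariance
classes, a pairwise union bound otherwise), so end-to-end accuracy checks
can be calibrated against what is achievable.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ValidationError
from .record_store import MedicalRecord
from .stream_units import DataUnit, VitalSample, featurize

__all__ = [
    "ClassRegime",
    "PhraseDistribution",
    "default_regimes",
    "generate_stream",
    "generate_records",
    "bayes_error",
    "build_manifest",
]

CHANNEL_NAMES = ("blood_pressure", "ecg_rate", "eeg_index", "temperature")


@dataclass(frozen=True)
class PhraseDistribution:
    """Categorical distribution over phrases; the first must be modal."""

    phrases: tuple[str, ...]
    probs: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.phrases) != len(self.probs):
            raise ValidationError("phrases and probs length mismatch")
        if abs(sum(self.probs) - 1.0) > 1e-9:
            raise ValidationError(f"probs must sum to 1, got {sum(self.probs)}")
        if any(p < 0 for p in self.probs):
            raise ValidationError("probs must be nonnegative")
        if len(self.probs) > 1 and self.probs[0] <= max(self.probs[1:]):
            raise ValidationError("modal phrase must have strictly highest probability")

    @property
    def modal(self) -> str:
        return self.phrases[0]

    def sample(self, rng: np.random.Generator) -> str:
        return self.phrases[rng.choice(len(self.phrases), p=self.probs)]


@dataclass(frozen=True)
class ClassRegime:
    """Channel statistics and text distributions for one illness class."""

    label: str
    means: tuple[float, ...]
    noise_sd: tuple[float, ...]
    drift: tuple[float, ...]
    treatment: PhraseDistribution
    diagnosis: PhraseDistribution
    history: PhraseDistribution

    def __post_init__(self) -> None:
        k = len(self.means)
        if len(self.noise_sd) != k or len(self.drift) != k:
            raise ValidationError("means, noise_sd, drift must share length")
        if any(s < 0 for s in self.noise_sd):
            raise ValidationError("noise sd must be >= 0")

    @property
    def n_channels(self) -> int:
        return len(self.means)


def _phrase_dist(modal: str, variant: str, alt1: str, alt2: str,
                 probs=(0.5, 0.2, 0.2, 0.1)) -> PhraseDistribution:
    return PhraseDistribution((modal, variant, alt1, alt2), probs)


def default_regimes() -> list[ClassRegime]:
    """Three well-separated illness regimes over the four default channels.

    Pairwise mean separation is several noise standard deviations on at
    least one channel, so the mixture's Bayes error is far below 1%.
    """
    sd = (5.0, 4.0, 3.0, 0.3)
    drift = (0.0, 0.0, 0.0, 0.0)
    return [
        ClassRegime(
            label="stable",
            means=(120.0, 75.0, 50.0, 36.8),
            noise_sd=sd, drift=drift,
            treatment=_phrase_dist(
                "continue routine observation and record vitals",
                "continue routine observation and chart vitals",
                "no intervention required at this time",
                "schedule follow up consultation next week",
            ),
            diagnosis=_phrase_dist(
                "patient condition stable no acute findings",
                "patient condition stable without acute findings",
                "normal sinus rhythm and normal pressure",
                "baseline readings within expected limits",
            ),
            history=_phrase_dist(
                "no prior cardiac events reported by patient",
                "no prior cardiac events reported by the patient",
                "history of mild seasonal allergies only",
                "previous admissions unremarkable per chart",
            ),
        ),
        ClassRegime(
            label="tachyarrhythmia",
            means=(100.0, 115.0, 55.0, 37.2),
            noise_sd=sd, drift=drift,
            treatment=_phrase_dist(
                "administer beta blocker and monitor heart rate closely",
                "administer beta blocker and monitor heart rate carefully",
                "perform synchronized cardioversion if unstable",
                "start intravenous antiarrhythmic infusion",
            ),
            diagnosis=_phrase_dist(
                "sustained tachyarrhythmia with elevated ventricular rate",
                "sustained tachyarrhythmia and elevated ventricular rate",
                "supraventricular tachycardia suspected on ecg",
                "rapid irregular rhythm consistent with fibrillation",
            ),
            history=_phrase_dist(
                "recurrent palpitations over the past six months",
                "recurrent palpitations during the past six months",
                "prior episode resolved after vagal maneuvers",
                "family history of arrhythmia in first degree relatives",
            ),
        ),
        ClassRegime(
            label="hypertensive_crisis",
            means=(185.0, 95.0, 50.0, 37.0),
            noise_sd=sd, drift=drift,
            treatment=_phrase_dist(
                "give intravenous antihypertensive and reassess pressure hourly",
                "give intravenous antihypertensive and reassess pressure frequently",
                "reduce pressure gradually over twenty four hours",
                "admit to intensive care for titration",
            ),
            diagnosis=_phrase_dist(
                "hypertensive crisis with severely elevated systolic pressure",
                "hypertensive crisis and severely elevated systolic pressure",
                "malignant hypertension with end organ risk",
                "acute blood pressure elevation requiring urgent care",
            ),
            history=_phrase_dist(
                "poorly controlled hypertension despite oral medication",
                "poorly controlled hypertension despite oral medications",
                "missed antihypertensive doses during recent travel",
                "chronic kidney disease noted on prior labs",
            ),
        ),
    ]


def generate_stream(
    regimes: Sequence[ClassRegime],
    n_units: int,
    unit_size: int = 3,
    seed: int = 0,
    t0: float = 0.0,
    dt: float = 1.0,
) -> list[VitalSample]:
    """Generate ``n_units * unit_size`` labeled samples, one regime per unit.

    The regime is chosen uniformly per unit with the seeded generator;
    channel values are mean + drift * (within-unit position) + Gaussian
    noise. Fully reproducible from the seed.
    """
    if not regimes:
        raise ValidationError("need at least one regime")
    if n_units < 1:
        raise ValidationError(f"n_units must be >= 1, got {n_units}")
    rng = np.random.default_rng(seed)
    k = regimes[0].n_channels
    samples: list[VitalSample] = []
    t = t0
    for _ in range(n_units):
        reg = regimes[rng.integers(len(regimes))]
        for pos in range(unit_size):
            noise = rng.standard_normal(k) * np.asarray(reg.noise_sd)
            vals = np.asarray(reg.means) + np.asarray(reg.drift) * pos + noise
            samples.append(VitalSample(t, tuple(float(v) for v in vals), reg.label))
            t += dt
    return samples


def generate_records(
    regimes: Sequence[ClassRegime],
    n: int,
    seed: int = 0,
    unit_size: int = 3,
    scheme: str = "mean-slope-min-max",
    rid_start: int = 1,
) -> list[MedicalRecord]:
    """Generate ``n`` records: features from one synthesized unit each,
    texts sampled from the record's regime phrase distributions."""
    if n < 1:
        raise ValidationError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    records: list[MedicalRecord] = []
    for i in range(n):
        reg = regimes[rng.integers(len(regimes))]
        k = reg.n_channels
        rows = []
        for pos in range(unit_size):
            noise = rng.standard_normal(k) * np.asarray(reg.noise_sd)
            vals = np.asarray(reg.means) + np.asarray(reg.drift) * pos + noise
            rows.append(VitalSample(float(pos), tuple(float(v) for v in vals)))
        unit = DataUnit(i, tuple(rows))
        feats = featurize(unit, scheme)
        records.append(
            MedicalRecord(
                rid=f"R{rid_start + i}",
                features=tuple(float(v) for v in feats),
                class_label=reg.label,
                treatment_text=reg.treatment.sample(rng),
                diagnosis_text=reg.diagnosis.sample(rng),
                illness_history_text=reg.history.sample(rng),
            )
        )
    return records


def bayes_error(regimes: Sequence[ClassRegime]) -> float:
    """Bayes error of the equiprobable regime mixture on raw channels.

    For two classes with equal diagonal covariances this is exact:
    Phi(-Delta/2) with Delta the Mahalanobis distance between the means.
    For more classes, the pairwise union bound (an upper bound) is
    returned: sum over pairs of Phi(-Delta_ij/2) / n_classes.
    """
    m = len(regimes)
    if m < 2:
        return 0.0

    def pair_err(a: ClassRegime, b: ClassRegime) -> float:
        sd = np.sqrt(
            (np.asarray(a.noise_sd) ** 2 + np.asarray(b.noise_sd) ** 2) / 2.0
        )
        sd = np.maximum(sd, 1e-12)
        delta = float(np.linalg.norm((np.asarray(a.means) - np.asarray(b.means)) / sd))
        return 0.5 * math.erfc(delta / (2.0 * math.sqrt(2.0)))

    if m == 2:
        return pair_err(regimes[0], regimes[1])
    total = 0.0
    for i in range(m):
        for j in range(i + 1, m):
            # each pair contributes error mass to both classes; priors 1/m
            total += 2.0 * pair_err(regimes[i], regimes[j]) / m
    return min(total, 1.0)


def build_manifest(regimes: Sequence[ClassRegime], seed: int,
                   n_units: int | None = None, n_records: int | None = None,
                   unit_size: int = 3) -> dict:
    """Ground-truth sidecar: regime parameters, planted modes, Bayes error."""
    return {
        "seed": seed,
        "unit_size": unit_size,
        "n_units": n_units,
        "n_records": n_records,
        "channel_names": list(CHANNEL_NAMES[: regimes[0].n_channels]),
        "bayes_error_upper_bound": bayes_error(regimes),
        "regimes": [
            {
                "label": r.label,
                "means": list(r.means),
                "noise_sd": list(r.noise_sd),
                "drift": list(r.drift),
                "modal_treatment": r.treatment.modal,
                "modal_diagnosis": r.diagnosis.modal,
                "modal_history": r.history.modal,
            }
            for r in regimes
        ],
    }


def write_manifest(path, manifest: dict) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)
        fh.write("\n")
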