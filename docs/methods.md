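# Methods

## Model and procedure

`vitalcds` couples three pieces: (1) a windowed featurization of a
multivariate vital-sign stream, (2) an incremental Hoeffding-tree (VFDT)
classifier whose leaves carry pointer lists into an append-only medical
record store, and (3) a prediction layer that resolves a classified leaf's
pointers to historical cases and extracts a frequency consensus of their
free-text fields. Doctor feedback re-enters the system as new records via
copy-train-swap retraining.

The core assumptions, in order of importance:

- **Stationarity.** Class-conditional channel distributions do not drift
  over the life of a model. No concept-drift adaptation is attempted; a
  drifting clinic would need to retire and retrain models.
- **Complete monitor output.** Every time point carries a reading for every
  channel. Missing readings are rejected, not imputed.
- **Within-leaf Gaussianity.** Numeric attributes are summarized per
  (attribute, class) by running Gaussians (count, mean, Welford variance),
  which fixes memory per leaf regardless of stream length. Split gains are
  therefore estimates under a normal model, not exact empirical gains; the
  split *decision* is still protected by the Hoeffding bound on the gain
  difference.
- **Text equivalence is lexical.** "Same meaning, different expression" is
  approximated by token-set cosine similarity with an optional synonym
  table, not by learned sentence embeddings. This is deterministic and
  auditable; it will not merge paraphrases that share few tokens.

## Windowing and features

A data unit is `unit_size` consecutive time points (default 3); the
trailing partial window is carried, never emitted. Each unit yields, per
channel: mean, least-squares slope against equispaced within-unit
positions, min, max — level and direction in the smallest set that
separates them. With `unit_size=1` the mean is the raw reading and the
slope is 0. True timestamps are used only for ordering; treating samples
as equispaced inside a 3-sample window loses nothing at typical monitor
rates. A `"mean"` scheme is available when trend is not wanted.

## Tree learning

Parameters (all on `HoeffdingTreeClassifier` / `VFDTSettings`):

| parameter | default | meaning |
|---|---|---|
| `delta` | 1e-6 | allowed probability the observed best attribute is not the true best at a split |
| `tau` | 0.05 | tie-break: split anyway once ε < τ |
| `grace_period` | 200 | examples at a leaf between split attempts |
| `max_depth` | none | optional growth bound |
| `pointer_cap` | none | optional keep-most-recent bound on a leaf's pointer list |

ε = √(R² ln(1/δ)/2n) with R = log₂(max(2, #classes)). Candidate thresholds
per attribute are the midpoints between per-class means plus nine interior
deciles of the observed range; split gain is information gain with
class-side masses estimated from the per-class Gaussian CDF. The race
compares the best thresholds of *different attributes*: two thresholds of
the same attribute estimate the same quantity and would tie indefinitely.

Two consequences worth knowing:

- With the default mean/slope/min/max features, the mean, min and max of
  the same channel are strongly correlated, so the top two attribute gains
  are often genuine ties and splitting proceeds through the ε < τ branch.
  At τ = 0.05 that needs roughly 7 000 examples at a leaf; the default
  therefore suits archives in the tens of thousands of records, which is
  also the scale at which this family of learners is meant to shine. For
  smaller corpora, raise τ (the examples and system tests use τ between
  0.2 and 0.9 for corpora of 300–4 000 records) — this is precisely the
  user-facing "sensitivity" knob.
- A fresh child leaf has no observations; it predicts the fallback class
  inherited from its parent's side-conditional class distribution until it
  has seen its own examples, so the model is a valid classifier after
  every prefix of the stream.

On a split, the parent's pointers migrate to whichever child their stored
feature vectors route to (each leaf keeps the features each pointer was
learned with), so the leaf → records-of-its-class mapping survives growth
without touching the store. Pointer lists are unbounded by default;
`pointer_cap` reconciles fixed-memory deployments with the index at the
cost of forgetting the oldest cases.

## Store, cache, feedback

Pointer values are the registration ordinals 1, 2, 3, …; the mapping table
row is (pointer, record ID, `records.jsonl:<byte offset>`). The file path +
offset plays the role of a physical address while remaining portable and
human-inspectable. Records are immutable; nothing is ever deleted, so
pointer ↔ record ID stays a bijection by construction.

Cached extractions are stamped with the leaf's pointer-list version
(a monotone counter bumped by the Adder). A cache entry is served only if
its stamp equals the leaf's current version, which makes the cache
semantically transparent even if an invalidation event is lost (e.g.
across serialization); Adder-event listeners additionally clear entries
eagerly.

Ingest order is: normalize → store append → clone tree → train clone →
swap → invalidate + (by default) eagerly re-extract the affected leaf.
The store append precedes the swap so a crash between them can only leave
an *orphaned* record, never a lost one; `Engine.load` reconciles orphans
by re-training them into the tree. Copy-train-swap is implemented as
snapshot semantics — a full logical clone and a single reference
assignment — rather than locks; a single-threaded deterministic replay
exercises the same observable contract (queries in the window see exactly
the pre-ingest tree), which is what the tests assert.

## Synthetic data

The generator emulates the study conditions end to end: each illness class
is a regime of per-channel Gaussian means, noise SDs and optional linear
drift, plus categorical phrase distributions for treatment / diagnosis /
illness history with a designated modal phrase (default masses 0.5 / 0.2 /
0.2 / 0.1, the 0.2-variant a paraphrase of the mode sharing ≥ 80% of its
tokens). Streams draw one regime per unit, uniformly; records pair one
synthesized unit's features with sampled texts. Everything is reproducible
from a single seed.

The three default regimes (stable, tachyarrhythmia, hypertensive crisis)
use plausible bedside values over four channels with pairwise mean
separations of many noise SDs; the manifest reports the mixture's Bayes
error — exact Φ(−Δ/2) for two equal-covariance classes, the pairwise union
bound for more — which is ≈ 10⁻⁸ here, so near-perfect downstream accuracy
is the *expected* outcome, not an impressive one. What passing tests show
is that the machinery loses nothing on clean, separable, stationary data;
they say nothing about overlapping classes, drifting physiology, irregular
sampling, or clinical text whose paraphrases share few tokens — real-data
phenomena the generator deliberately does not model.

Problem sizes used by the system-level checks: 20 000 training records and
1 100 streamed units for the end-to-end run (enough for the default
τ = 0.05 to separate all three classes, per the tie analysis above);
1 000 interleaved registrations/ingests for the integrity audit; 100
corpora of 1 500 records for modal-phrase recovery; 5 000 examples for the
root-split oracle.

## Numerical choices

- Gain ties break by lowest attribute index, then lowest threshold; group
  representatives break count ties lexicographically; majority classes
  break count ties lexicographically. All outputs are deterministic given
  (config, seed, input order).
- Gaussian SDs are floored at 1e-9 inside gain estimation; metric matrices
  are accepted as PSD down to eigenvalue −1e-8.
- Token-set cosine of two empty texts is 1 (empty strings group together);
  empty vs non-empty is 0.
- `group_descriptions` deduplicates exact strings before the pairwise
  pass — similarity depends only on token sets, so the result is identical
  to the all-pairs definition (property-tested against it) at a fraction
  of the cost.
- The split-off fraction Φ uses `math.erf` directly; no statistical
  library is needed in the hot path.

## Known limitations

- No categorical attributes, no drift detection, no leaf
  deactivation/memory-pressure heuristics.
- Token-set similarity is order-blind ("no pain" ≈ "pain"), mitigated only
  by the synonym table; clinical negation handling is out of scope.
- The tie-break analysis above means default settings under-split small
  corpora; this is by design (conservative splits) but surprises users who
  expect a tree from 500 records.
- `Engine` is single-process; the non-blocking guarantee is about model
  consistency, not thread-safety of concurrent Python callers.
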