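# vitalcds

Real-time clinical decision support from multivariate vital-sign streams.

Bedside monitors emit a continuous stream of readings — blood pressure, an
ECG-derived heart rate, an EEG index, body temperature — and a clinician
wants, at any moment, three things: what the current situation is, which
past cases it resembles, and what was done for those cases. Batch decision
trees cannot serve this setting: they rescan the whole archive on every
refresh and block while retraining. `vitalcds` instead builds the whole
system around a **Hoeffding tree** (VFDT), an incremental decision tree
that processes each example once in constant time and memory, and extends
its leaves with **pointer lists** into a historical medical-record store,
so that classification *is* retrieval.

## The method

**Windowing.** The stream of time points T1, T2, … is cut into fixed-size
*data units* (default 3 consecutive readings: U1 = {T1, T2, T3}); each unit
is summarized per channel by (mean, least-squares slope, min, max),
capturing the level and short-term trend of the patient's state.

**Incremental classification.** A Hoeffding tree learns from the labeled
feature vectors one at a time. A leaf accumulates class counts and
per-(attribute, class) Gaussian summaries; every `grace_period` examples it
compares the best split *G₁* against the runner-up attribute's best *G₂*
using the Hoeffding bound

&nbsp;&nbsp;&nbsp;&nbsp;ε = √( R² ln(1/δ) / 2n ),&nbsp;&nbsp; R = log₂(#classes),

splitting when G₁ − G₂ > ε (the ordering is correct with confidence 1 − δ)
or when ε < τ (a statistical tie not worth waiting out).

**Pointer-augmented leaves.** During training, the *Adder* appends each
record's pointer value to the leaf the record routes to. A *mapping table*
(pointer → record ID → physical address) turns a classified leaf directly
into its similar historical cases — no offline clustering or metric-learning
pass. The quadratic-form patient distance d(xᵢ,xⱼ) = (xᵢ−xⱼ)ᵀP(xᵢ−xⱼ) used
by such offline systems is provided as a retrieval baseline
(`vitalcds.prediction.lsml_distance`).

**Prediction.** The retrieved records' free-text fields are grouped by
token-set cosine similarity (doctors word the same treatment differently),
and the most frequent group per field becomes the output: treatment history
→ advice, diagnosis history → system diagnosis, illness history →
prognosis, formatted `1.… 2.… 3.…`. Results are cached per leaf and
invalidated the moment a new pointer reaches that leaf.

**Feedback.** A doctor-confirmed diagnosis is normalized into the record
format, appended to the store, and folded into the model by
*copy-train-swap*: clone the live tree, train the clone, swap it in
atomically — queries are never served by a half-trained model.

## Worked example

```bash
vitalcds simulate --out-dir data --n-records 300 --n-units 40 --seed 5
vitalcds train --records data/records.jsonl --engine-dir engine \
         --tau 0.5 --grace-period 50 --summary train.json
vitalcds stream --engine-dir engine --in data/stream.csv \
         --out results.jsonl --summary stream.json
```

`train.json` then contains

```json
{
  "records_trained": 300,
  "n_leaves": 3,
  "n_classes": 3,
  "n_pointers_in_tree": 300,
  "pointers_unique_across_leaves": true,
  "tree_store_pointer_sets_equal": true,
  "pointers_sequential": true,
  "rid_bijection": true
}
```

— the tree grew one leaf per simulated illness class, and every one of the
300 record pointers sits in exactly one leaf, matching the mapping table.
Each line of `results.jsonl` is one classified data unit, e.g.

```json
{"unit_id": 0, "leaf_id": "C5", "class_label": "tachyarrhythmia",
 "cache_hit": false,
 "treatment": "1.administer beta blocker and monitor heart rate closely 2.perform synchronized cardioversion if unstable 3.start intravenous antiarrhythmic infusion",
 "true_label": "tachyarrhythmia", "correct": true, "...": "..."}
```

The top-ranked treatment is the modal phrase planted for that class by the
simulator, recovered by grouping its paraphrase variants together. The
stream summary reports the prequential (test-then-train) accuracy and the
cache hit rate.

The same engine accepts feedback:

```bash
vitalcds feedback --engine-dir engine --in event.json
vitalcds inspect --engine-dir engine --what invariants
```

## Library surface

The classifier follows the scikit-learn estimator protocol:

```python
from vitalcds import HoeffdingTreeClassifier
tree = HoeffdingTreeClassifier(delta=1e-6, tau=0.05, grace_period=200)
tree.partial_fit(X, y)            # or tree.learn_one(x, label, pointer=7)
tree.predict(X), tree.predict_proba(X)
```

`Engine` wires the segmenter, store, tree, predictor and cache together;
see `vitalcds.engine` and `docs/methods.md`.

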