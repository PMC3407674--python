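import numpy as np
import pytest

from vitalcds import Engine, EngineConfig, VFDTSettings
from vitalcds import synthetic
from vitalcds.record_store import MedicalRecord


@pytest.fixture
def regimes():
    return synthetic.default_regimes()


@pytest.fixture
def small_records(regimes):
    """A small, seeded record corpus covering every class."""
    return synthetic.generate_records(regimes, 60, seed=101)


@pytest.fixture
def engine_factory(tmp_path):
    """Build an engine in a fresh subdirectory; optionally train it."""
    counter = {"n": 0}

    def make(records=None, **cfg_kwargs):
        counter["n"] += 1
        vfdt_kwargs = {
            k: cfg_kwargs.pop(k)
            for k in ("delta", "tau", "grace_period", "max_depth", "seed")
            if k in cfg_kwargs
        }
        cfg = EngineConfig(vfdt=VFDTSettings(**vfdt_kwargs), **cfg_kwargs)
        eng = Engine(cfg, tmp_path / f"engine{counter['n']}")
        if records is not None:
            eng.run_initial_training(records)
        return eng

    return make


def make_record(rid, features, label="flu", treatment="rest and fluids",
                diagnosis="seasonal influenza", history="no prior episodes"):
    return MedicalRecord(
        rid=rid,
        features=tuple(float(v) for v in features),
        class_label=label,
        treatment_text=treatment,
        diagnosis_text=diagnosis,
        illness_history_text=history,
    )


@pytest.fixture
def two_gaussian_stream():
    """Seeded 2-class, 4-attribute stream separated by 4 sd on attribute 1."""
    rng = np.random.default_rng(11)
    n = 5000
    X = rng.standard_normal((n, 4))
    y = np.where(rng.random(n) < 0.5, "sick", "well")
    X[y == "sick", 1] += 4.0
    return X, np.asarray(y, dtype=object)
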