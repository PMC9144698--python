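import os

# pin BLAS threading before numpy loads so results are identical across
# machines regardless of core count
for _var in ("OMP_NUM_THREADS", "OPENBLAS_NUM_THREADS", "MKL_NUM_THREADS",
             "NUMEXPR_NUM_THREADS"):
    os.environ.setdefault(_var, "1")

import numpy as np
import pytest

from boxseg.initializers import InitializerConfig
from boxseg.synthetic import (
    apply_mix_labels,
    benchmark_augment,
    benchmark_schedule,
    benchmark_suite,
)
from boxseg.trainer import run_weakly_supervised_training, train_variant


@pytest.fixture(scope="session")
def smoke_bench():
    """Small seeded scene set shared by wiring-level tests."""
    return benchmark_suite("smoke", seed=0)


@pytest.fixture(scope="session")
def smoke_mix_run():
    """One full weak-supervision run on the smoke suite with mixed
    supervision (some fixed human-mask images), target snapshots kept.

    Session-scoped: several invariants are checked against the same run.
    """
    bench = benchmark_suite("smoke", seed=0)
    split = apply_mix_labels(bench.split, fraction=0.3, seed=0)
    schedule = benchmark_schedule(epochs=(2, 2), seed=0)
    model, history = train_variant(
        split, "weak-mix", schedule, augment_cfg=benchmark_augment(64), seed=0
    )
    return {"split": split, "model": model, "history": history}


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
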