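import os

# single-threaded BLAS: the likelihood matmuls are far too small to gain from
# threads, and thread spin-up dominates runtime otherwise (must be set before
# numpy is first imported)
for _var in ("OMP_NUM_THREADS", "OPENBLAS_NUM_THREADS", "MKL_NUM_THREADS"):
    os.environ.setdefault(_var, "1")

import numpy as np
import pytest

import agefec
from agefec.glmm import ModelSpec


@pytest.fixture(scope="session")
def tiny_spec() -> ModelSpec:
    """Very short chains for structural tests where only labels/shapes matter."""
    return ModelSpec(chains=2, iterations=220, warmup=100)


@pytest.fixture(scope="session")
def fast_spec() -> ModelSpec:
    return ModelSpec.fast()


@pytest.fixture(scope="session")
def mixed_effects_dataset() -> agefec.FecundityDataset:
    """8 lines spanning null to strongly deleterious, with proportional aging."""
    delta = np.array([0.0, np.log(0.9), np.log(0.8), np.log(0.5)] * 2)
    cfg = agefec.SimConfig(
        n_mutations=8,
        vials_per_mutation=(20, 20),
        delta=delta,
        beta=delta / 30.0,
        vial_sd=0.2,
        seed=7,
    )
    return agefec.simulate_experiment(cfg)


@pytest.fixture(scope="session")
def mixed_effects_truth() -> dict:
    delta = np.array([0.0, np.log(0.9), np.log(0.8), np.log(0.5)] * 2)
    return {"delta": delta, "beta": delta / 30.0}
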