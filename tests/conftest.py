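import dataclasses

import numpy as np
import pytest

from puseq.datasets import PUDataset, SequenceRecord, holdout_split
from puseq.pu_core import SpyConfig, run_pu
from puseq.synthetic import benchmark_defaults, generate_benchmark, scaled_separation


@pytest.fixture(scope="session")
def default_dataset():
    """The packaged synthetic benchmark at its documented defaults (seed 42)."""
    return generate_benchmark(benchmark_defaults())


@pytest.fixture(scope="session")
def small_dataset():
    """A reduced benchmark for fast protocol tests."""
    params = dataclasses.replace(benchmark_defaults(), n_pos=80, n_unlabeled=300)
    return generate_benchmark(params)


@pytest.fixture(scope="session")
def default_model(default_dataset):
    """One converged original-variant run on the default benchmark."""
    train, holdout = holdout_split(default_dataset.P, 40, 42)
    dataset = PUDataset(P=train, U=default_dataset.U, truth=default_dataset.truth)
    model = run_pu(dataset, cfg=SpyConfig(seed=42))
    return model, dataset, holdout


def random_records(rng: np.random.Generator, n: int, length: int = 50, prefix: str = "r"):
    """Random sequences over the standard alphabet, for structural tests."""
    from puseq.datasets import STANDARD_AA

    alphabet = np.array(list(STANDARD_AA))
    return [
        SequenceRecord(f"{prefix}{i}", "".join(rng.choice(alphabet, size=length)))
        for i in range(n)
    ]


# ---------------------------------------------------------------------------
# Shared grid of full protocol runs used by the acceptance suite. Session
# scoped because ~60 end-to-end runs dominate suite runtime.

GRID_SEEDS = tuple(range(42, 52))
GRID_SEPARATIONS = (1.0, 0.7, 0.5)


@pytest.fixture(scope="session")
def protocol_grid():
    """{(separation, seed, variant): (model, dataset)} over the full grid."""
    results = {}
    for sep in GRID_SEPARATIONS:
        for seed in GRID_SEEDS:
            params = dataclasses.replace(
                scaled_separation(benchmark_defaults(), sep), seed=seed
            )
            dataset = generate_benchmark(params)
            for variant in ("original", "modified"):
                model = run_pu(dataset, cfg=SpyConfig(seed=seed, variant=variant))
                results[(sep, seed, variant)] = (model, dataset)
    return results
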