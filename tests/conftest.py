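import numpy as np
import pandas as pd
import pytest

from dasurv.da import TrainConfig, train_one_input, train_two_input
from dasurv.preprocess import preprocess_bundle
from dasurv.synthetic import SimConfig, simulate_bundle


@pytest.fixture(scope="session")
def small_sim():
    """A compact cohort with planted structure, shared across tests."""
    cfg = SimConfig(n_patients=150, n_genes=300, seed=11)
    bundle, truth = simulate_bundle(cfg)
    return cfg, bundle, truth


@pytest.fixture(scope="session")
def scaled_pair(small_sim):
    """Matched, [0,1]-scaled expression/CNA pair plus aligned clinical table."""
    _, bundle, _ = small_sim
    return preprocess_bundle(
        bundle.counts, bundle.gene_lengths, bundle.cna_log2, bundle.clinical
    )


@pytest.fixture(scope="session")
def trained_one(scaled_pair):
    se, _, _ = scaled_pair
    return train_one_input(se, TrainConfig(epochs=3, seed=5))


@pytest.fixture(scope="session")
def trained_two(scaled_pair):
    se, sc, _ = scaled_pair
    return train_two_input(se, sc, TrainConfig(epochs=3, seed=5), hidden1=40, hidden2=20)


@pytest.fixture(scope="session")
def survival_fixture():
    """8 patients, tie-free times, binary covariate; printed in full."""
    times = np.array([2.0, 5.0, 7.0, 11.0, 13.0, 17.0, 19.0, 23.0])
    events = np.array([1, 1, 0, 1, 1, 0, 1, 1])
    covar = np.array([1.0, 1.0, 0.0, 1.0, 0.0, 1.0, 0.0, 0.0])
    return times, events, covar
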