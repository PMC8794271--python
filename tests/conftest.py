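import numpy as np
import pytest
from hypothesis import settings

import genecircuits as gc

settings.register_profile("suite", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def truth4_and_data4():
    """Seeded 4-gene two-module ground truth and its noiseless dataset."""
    spec = gc.SynthesisSpec(n_genes=4, seed=0, noise_cv=0.0)
    return gc.make_synthetic_dataset(spec)


@pytest.fixture(scope="session")
def data3():
    """Noiseless 3-gene dataset from a seeded two-module circuit."""
    spec = gc.SynthesisSpec(n_genes=3, seed=1, noise_cv=0.0)
    _, dataset = gc.make_synthetic_dataset(spec)
    return dataset


@pytest.fixture(scope="session")
def light_config():
    """Reduced annealing/polish budget for desk-scale fitting tests."""
    return gc.FitConfig(n_steps=1500, polish_max_nfev=150)


@pytest.fixture(scope="session")
def ensemble4(truth4_and_data4, light_config):
    """Ensemble of 10 independent fits to the noiseless 4-gene dataset."""
    _, dataset = truth4_and_data4
    return gc.fit_ensemble(dataset, light_config, n_fits=10, base_seed=0)


@pytest.fixture
def decoupled_params():
    """3 decoupled genes (T = 0) with distinct rates."""
    return gc.GeneCircuitParams(
        ("a", "b", "c"), np.zeros((3, 3)),
        b=[0.5, -0.5, 0.0], h=[-0.3, 0.2, 0.6],
        R=[0.1, 0.05, 0.2], lam=[0.1, 0.05, 0.2])


def normalized_truth(params, dataset):
    """Ground-truth parameters re-expressed in the dataset's normalized
    units: T'_ij = T_ij * m_j, R'_i = R_i / m_i with m the per-gene max of
    the clean trajectories."""
    import genecircuits.model as M
    x0 = gc.progenitor_state(params)
    vals = np.stack([M.simulate(params, x0, c, dataset.times).values
                     for c in dataset.conditions])
    m = vals.max(axis=(0, 2))
    out = params.copy()
    out.T = params.T * m[None, :]
    out.R = params.R / m
    return out
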