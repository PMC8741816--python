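import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import sigmatch as sm

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_pair():
    """Two small signatures sharing genes in both directions."""
    a = sm.GeneSignature("A", {"G1": 3.0, "G2": 1.0, "G3": -2.0, "G4": -0.5, "G5": 0.0})
    b = sm.GeneSignature("B", {"G1": 1.0, "G3": -1.5, "G4": 2.0, "G5": -1.0, "G6": 4.0})
    return a, b


def make_balanced_signature(dataset_id, n_genes, n_up, n_down, rng, universe=None):
    """Signature with exactly n_up positive and n_down negative genes."""
    genes = universe or [f"G{i:05d}" for i in range(n_genes)]
    idx = rng.permutation(n_genes)
    vals = np.zeros(n_genes)
    vals[idx[:n_up]] = rng.uniform(1.5, 6.0, n_up)
    vals[idx[n_up:n_up + n_down]] = -rng.uniform(1.5, 6.0, n_down)
    return sm.GeneSignature(dataset_id, dict(zip(genes, vals)))


@pytest.fixture
def balanced_pair(rng):
    """Identical universe, disjoint 10-up/10-down sets in a universe of 100."""
    genes = [f"G{i:03d}" for i in range(100)]
    vals_a = np.zeros(100)
    vals_a[:10] = np.linspace(5, 2, 10)
    vals_a[10:20] = -np.linspace(5, 2, 10)
    vals_b = np.zeros(100)
    vals_b[20:30] = np.linspace(5, 2, 10)
    vals_b[30:40] = -np.linspace(5, 2, 10)
    a = sm.GeneSignature("A", dict(zip(genes, vals_a)))
    b = sm.GeneSignature("B", dict(zip(genes, vals_b)))
    return a, b


@pytest.fixture(scope="session")
def small_suite():
    """Session-wide small synthetic suite: truth, humans, models, portrait."""
    cfg = sm.SimulationConfig(seed=2024, n_genes=1500, n_human_datasets=8, n_models=12)
    truth, humans = sm.simulate_human_datasets(cfg)
    models = sm.simulate_models(cfg, truth)
    portrait = sm.build_portrait(humans, portrait_id="DEPRESSION_PORTRAIT")
    return cfg, truth, humans, models, portrait
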