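import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import omicsig as og

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=25)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def toy_matrix():
    """4 features × 6 samples with known structure."""
    vals = np.array([
        [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
        [0.0, 0.0, 0.0, 0.0, 0.0, 10.0],
        [5.0, 5.0, 5.0, 5.0, 5.0, 5.0],     # constant
        [-1.0, 1.0, -1.0, 1.0, -1.0, 1.0],
    ])
    return og.ExpressionMatrix(
        "toy", ["f1", "f2", "f3", "f4"],
        [f"s{i}" for i in range(6)], vals)


@pytest.fixture
def small_cohort():
    """Quick two-layer cohort with clear DE signal, no edge confounding."""
    cfg = og.SimConfig(
        n_samples=120,
        features_per_layer={"mRNA": 40, "protein": 30},
        network_density=0.05,
        edge_effect_range=(0.0, 0.0),
        de_fraction=0.25,
        de_effect=2.0,
        seed=7,
    )
    return og.simulate_cohort(cfg)


def make_clinical(purities, groups=None):
    n = len(purities)
    return pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(n)],
        "time": np.linspace(10, 100, n),
        "event": [1] * n,
        "group": groups or ["good", "poor"] * (n // 2) + ["good"] * (n % 2),
        "purity": purities,
    })
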