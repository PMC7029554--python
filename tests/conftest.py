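import sys
from pathlib import Path

import numpy as np
import pytest
from scipy.special import expit

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from sctwiner import SimulationDesign, simulate_cells


def make_logistic_instance(seed: int, n: int = 60, p: int = 10, weighted: bool = True):
    """Small random penalized-logistic instance with a fixed seed."""
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    beta = np.zeros(p)
    beta[: p // 3] = rng.normal(0, 1.2, p // 3)
    y = (rng.random(n) < expit(X @ beta)).astype(float)
    if y.sum() in (0, len(y)):  # ensure both classes
        y[0] = 1 - y[0]
    w = rng.uniform(0.05, 1.0, p) if weighted else None
    return X, y, w


@pytest.fixture(scope="session")
def small_dataset():
    """60+60+60 cells, 80 genes, strong planted structure, no dropout."""
    design = SimulationDesign(
        n_core=60,
        n_periph_neo=60,
        n_periph_norm=60,
        p=80,
        k_discriminative=5,
        effect_size=2.0,
        k_shared_module=8,
        k_divergent_module=8,
        module_correlation=0.6,
        dropout_rate=0.0,
        seed=11,
    )
    return simulate_cells(design), design


@pytest.fixture(scope="session")
def medium_dataset():
    """Default-design data (with dropout) for protocol-level tests."""
    design = SimulationDesign(
        n_core=120,
        n_periph_neo=120,
        n_periph_norm=120,
        p=200,
        k_discriminative=8,
        effect_size=2.0,
        k_shared_module=12,
        k_divergent_module=12,
        dropout_rate=0.0,
        seed=3,
    )
    return simulate_cells(design), design
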