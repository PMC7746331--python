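import numpy as np
import pytest
from hypothesis import settings

from mrkit import HarmonizedDataset, SimulationConfig, simulate_summary_data

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def make_dataset(bx, by, sy, sx=None, ids=None) -> HarmonizedDataset:
    bx = np.asarray(bx, float)
    sx = np.full_like(bx, 0.01) if sx is None else np.asarray(sx, float)
    ids = ids or [f"rs{i + 1}" for i in range(bx.size)]
    return HarmonizedDataset(ids, bx, sx, np.asarray(by, float), np.asarray(sy, float))


@pytest.fixture
def toy3() -> HarmonizedDataset:
    """Three instruments with mild heterogeneity."""
    return make_dataset(
        bx=[0.1, 0.2, 0.3], by=[0.02, 0.05, 0.09], sy=[0.01, 0.01, 0.02]
    )


@pytest.fixture
def homogeneous() -> HarmonizedDataset:
    """Every ratio exactly 0.4: zero heterogeneity by construction."""
    bx = np.array([0.05, 0.1, 0.15, 0.2, 0.25])
    return make_dataset(bx=bx, by=0.4 * bx, sy=[0.01, 0.02, 0.01, 0.03, 0.02])


@pytest.fixture
def simulated() -> HarmonizedDataset:
    data, _ = simulate_summary_data(SimulationConfig(n_snps=25, seed=11))
    return data


@pytest.fixture
def simulated_with_truth():
    cfg = SimulationConfig(n_snps=40, theta_true=0.25, seed=5)
    return simulate_summary_data(cfg)
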