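import numpy as np
import pytest

from genmh import Dataset, SimulationSpec, simulate_dataset


@pytest.fixture
def homogeneous_data():
    """n=2000 draw from a delta=0 model with common OR = 2 (one continuous,
    one binary covariate)."""
    spec = SimulationSpec.homogeneous(
        2000, np.log(2), [("normal", 0, 1), ("bernoulli", 0.4)], seed=7)
    return simulate_dataset(spec)


@pytest.fixture
def heterogeneous_data():
    """n=1500 draw with a nonzero heterogeneity contrast delta."""
    spec = SimulationSpec(
        1500, [("normal", 0, 1), ("bernoulli", 0.5)],
        alpha=(0.2, -0.1, 0.9),
        beta=[[0.4, 0.2], [-0.3, 0.5], [0.9, -0.4]], seed=11)
    return simulate_dataset(spec)


@pytest.fixture
def tiny_m0_data():
    """Covariate-free dataset with known cell counts (20, 10, 8, 25)."""
    counts = (20, 10, 8, 25)
    cat = np.repeat(np.arange(4), counts)
    return Dataset(cat // 2, cat % 2, np.empty((sum(counts), 0)))


def make_csv(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p
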