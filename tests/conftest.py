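import numpy as np
import pandas as pd
import pytest

from genratio.model import GrepConfig
from genratio.simulate import SyntheticConfig, generate_expression


@pytest.fixture
def toy_expression() -> pd.DataFrame:
    """4 genes x 6 samples, hand-sized values on a linear scale."""
    rng = np.random.default_rng(42)
    genes = ["GA", "GB", "GC", "GD"]
    samples = [f"s{i}" for i in range(6)]
    vals = rng.uniform(100, 2000, size=(4, 6))
    return pd.DataFrame(vals, index=genes, columns=samples)


@pytest.fixture(scope="session")
def planted_dataset():
    """One moderate planted-ratio dataset shared across tests."""
    cfg = SyntheticConfig(
        n_samples=200, n_genes=100, hypothesis_set_size=30, n_true_ratios=3,
        effect_size=2.0, seed=11,
    )
    return generate_expression(cfg)


@pytest.fixture(scope="session")
def fast_config() -> GrepConfig:
    return GrepConfig(seed=11)
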