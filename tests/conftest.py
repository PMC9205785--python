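import numpy as np
import pandas as pd
import pytest

from synomics.simulate import SimulationConfig, generate_counts


@pytest.fixture(scope="session")
def small_cohort():
    """A small paired two-arm cohort with known ground truth."""
    cfg = SimulationConfig(n_patients=20, n_paired=20, n_genes=30, sigma_b=0.4,
                           frac_interaction_genes=0.1, fixed_effect_magnitude=1.5,
                           seed=42)
    return generate_counts(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def random_counts(rng):
    """Random strictly positive count matrix, genes x samples."""
    x = rng.poisson(50, size=(40, 12)) + 1
    return pd.DataFrame(x,
                        index=[f"g{i}" for i in range(40)],
                        columns=[f"s{j}" for j in range(12)])
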