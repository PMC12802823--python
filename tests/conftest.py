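import numpy as np
import pandas as pd
import pytest

from soilcue import RunConfig, SyntheticConfig, generate_paired_dataset
from soilcue.io import build_paired_table


@pytest.fixture(scope="session")
def default_dataset() -> pd.DataFrame:
    """One default-condition synthetic dataset, fixed seed."""
    return generate_paired_dataset(SyntheticConfig(seed=2026))


@pytest.fixture(scope="session")
def paired(default_dataset) -> pd.DataFrame:
    """Paired analysis table built through the forward CUE pipeline."""
    paired, _ = build_paired_table(default_dataset, RunConfig(seed=2026))
    return paired


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


def make_sample(**overrides) -> dict:
    """A valid single-sample record for the stoichiometric estimator."""
    base = {"soc": 20.0, "tn": 2.0, "tp": 0.5, "mbc": 400.0, "mbn": 50.0,
            "mbp": 8.0, "bg": 100.0, "nag": 60.0, "lap": 40.0, "ap": 125.0}
    base.update(overrides)
    return base
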