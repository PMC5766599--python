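import numpy as np
import pandas as pd
import pytest

from lnckit.config import SimulationConfig
from lnckit.io import CountMatrix, SampleSheet
from lnckit.simulate import simulate_discovery_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_cfg():
    """A fast 3-pair discovery configuration used across tests."""
    return SimulationConfig(
        n_features=300,
        n_true_de=20,
        planted_set_size=8,
        n_tumor_confirm=80,
        n_normal_confirm=20,
        seed=42,
    )


@pytest.fixture
def small_cohort(small_cfg):
    return simulate_discovery_cohort(small_cfg)


@pytest.fixture
def paired_sheet():
    def make(n_pairs: int) -> SampleSheet:
        rows = []
        for i in range(n_pairs):
            p = f"P{i + 1:02d}"
            rows.append((f"{p}_T", p, "tumor", "II"))
            rows.append((f"{p}_N", p, "normal", "NA"))
        return SampleSheet(
            pd.DataFrame(rows, columns=["sample_id", "patient_id", "condition", "stage"])
        )

    return make


@pytest.fixture
def toy_counts():
    def make(values, feature_ids=None, sample_ids=None) -> CountMatrix:
        values = np.asarray(values)
        f, s = values.shape
        return CountMatrix(
            pd.DataFrame(
                values,
                index=feature_ids or [f"g{i}" for i in range(f)],
                columns=sample_ids or [f"s{j}" for j in range(s)],
            )
        )

    return make
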