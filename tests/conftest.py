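import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mil3d import (
    StructuralFeatureTable,
    SyntheticSpec,
    generate,
    label_by_signal,
    load_placeholder_table,
)

settings.register_profile(
    "suite", deadline=None, derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def table() -> StructuralFeatureTable:
    return load_placeholder_table()


@pytest.fixture(scope="session")
def random_table() -> StructuralFeatureTable:
    """A second, independent table so tests stay value-agnostic."""
    rng = np.random.default_rng(777)
    return StructuralFeatureTable(values=rng.normal(0, 2.0, (64, 6)), source_name="random-test-table")


@pytest.fixture(scope="session")
def planted_dataset(table):
    """Small planted-motif train/test pair with ground truth."""
    train_probes, train_truth = generate(SyntheticSpec(n_pos=100, n_neg=100, seed=42))
    test_probes, test_truth = generate(SyntheticSpec(n_pos=100, n_neg=100, seed=43))
    return {
        "train": label_by_signal(train_probes, 100, 100, tf_name="SIM"),
        "test": label_by_signal(test_probes, 100, 100, tf_name="SIM"),
        "train_truth": train_truth,
        "test_truth": test_truth,
    }
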