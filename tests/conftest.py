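import numpy as np
import pytest

from faidr.io import AnnotationTable, FeatureTable, IDRRecord
from faidr.synthetic import SyntheticSpec, generate_synthetic


@pytest.fixture
def tiny_table() -> FeatureTable:
    """Two proteins: A with two IDRs (with coordinates), B with one."""
    records = [
        IDRRecord("A", 1, [1.0, -0.5], start=1, end=45),
        IDRRecord("A", 2, [0.2, 2.0], start=60, end=90),
        IDRRecord("B", 1, [-1.0, 0.0], start=5, end=30),
    ]
    return FeatureTable(records, ["f1", "f2"])


def make_table(X: np.ndarray, r: list[int]) -> FeatureTable:
    """Feature table with given per-protein IDR counts, rows taken from X."""
    records = []
    k = 0
    for i, ri in enumerate(r):
        for j in range(ri):
            records.append(IDRRecord(f"P{i}", j + 1, X[k]))
            k += 1
    assert k == X.shape[0]
    return FeatureTable(records, [f"f{j}" for j in range(X.shape[1])])


@pytest.fixture(scope="session")
def small_dataset():
    """A modest synthetic dataset for fitting tests (fast, strong signal)."""
    return generate_synthetic(
        SyntheticSpec(n_proteins=300, m_features=24, support_size=5, seed=11)
    )


@pytest.fixture(scope="session")
def default_dataset():
    """The generator at its default study conditions (n=2000, m=164)."""
    return generate_synthetic(SyntheticSpec(seed=1))


@pytest.fixture
def two_function_annotations():
    return AnnotationTable(["A", "B"], ["fun1", "fun2"], np.array([[1, 0], [0, 0]]))
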