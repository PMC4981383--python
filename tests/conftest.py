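import numpy as np
import pytest

from mixmc.containers import CompositionMatrix, CountTable, NumericMatrix, SampleMetadata
from mixmc.synth import SynthConfig, simulate_counts


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_table():
    """3 samples x 4 OTUs with hand-checkable totals."""
    return CountTable(
        values=np.array([[2, 3, 5, 0], [1, 0, 2, 7], [4, 4, 4, 4]]),
        sample_ids=["s1", "s2", "s3"],
        feature_ids=["o1", "o2", "o3", "o4"],
    )


@pytest.fixture
def toy_metadata():
    return SampleMetadata.from_records(
        sample_ids=["s1", "s2", "s3"],
        subject_ids=["A", "A", "B"],
        class_labels=["gut", "oral", "gut"],
    )


def random_composition(rng, n, p):
    vals = rng.dirichlet(np.ones(p) * 0.8, size=n)
    vals = np.clip(vals, 1e-12, None)
    vals /= vals.sum(axis=1, keepdims=True)
    return CompositionMatrix(
        values=vals,
        sample_ids=[f"s{i}" for i in range(n)],
        feature_ids=[f"f{j}" for j in range(p)],
    )


def random_numeric(rng, n, p):
    return NumericMatrix(
        values=rng.normal(size=(n, p)),
        sample_ids=[f"s{i}" for i in range(n)],
        feature_ids=[f"f{j}" for j in range(p)],
    )


@pytest.fixture(scope="session")
def small_simulation():
    """A small repeated-measures simulation shared across tests."""
    cfg = SynthConfig(
        n_subjects=15, n_classes=3, n_otus=60, n_discriminative=5,
        effect_size=8.0, seed=7,
    )
    return simulate_counts(cfg)
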