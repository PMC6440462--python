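import numpy as np
import pytest

from mbstates import AbundanceTable, SyntheticSpec, generate_states_dataset


def blob_matrix(sizes, within=1.0, between=10.0, jitter=0.0, seed=0):
    """Distance matrix of well-separated blobs (within < between)."""
    rng = np.random.default_rng(seed)
    labels = np.repeat(np.arange(len(sizes)), sizes)
    n = len(labels)
    d = np.where(labels[:, None] == labels[None, :], within, between).astype(float)
    if jitter:
        noise = rng.uniform(0, jitter, size=(n, n))
        noise = 0.5 * (noise + noise.T)
        d = d + noise
    np.fill_diagonal(d, 0.0)
    return d, labels


@pytest.fixture
def blobs_2x10():
    d, labels = blob_matrix([10, 10])
    return d, labels


@pytest.fixture
def small_table():
    values = np.array([
        [0.6, 0.3, 0.1],
        [0.2, 0.5, 0.3],
        [0.1, 0.1, 0.8],
    ])
    return AbundanceTable(
        sample_ids=["s1", "s2", "s3"],
        taxon_ids=["t1", "t2", "t3"],
        values=values,
        taxonomy={
            "t1": ("k__Bacteria", "p__P1", "c__C1", "o__O1", "f__F1", "g__A", "s__x"),
            "t2": ("k__Bacteria", "p__P1", "c__C1", "o__O1", "f__F1", "g__A", "s__y"),
            "t3": ("k__Bacteria", "p__P2", "c__C2", "o__O2", "f__F2", "g__B", "s__z"),
        },
        metadata={"s1": {"subject_id": "u1", "time_index": 0},
                  "s2": {"subject_id": "u1", "time_index": 1},
                  "s3": {"subject_id": "u2", "time_index": 0}},
        normalized=True,
    )


@pytest.fixture(scope="session")
def planted_table():
    """Strongly separated 3-state table (n=60), shared across tests."""
    spec = SyntheticSpec(n_states=3, samples_per_state=20, n_taxa=60,
                         separation=50.0, depth=10_000, seed=42)
    return generate_states_dataset(spec)


def random_compositions(rng, n, t, sparse=False):
    alpha = np.full(t, 0.5 if sparse else 2.0)
    return rng.dirichlet(alpha, size=n)
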