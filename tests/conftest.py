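import numpy as np
import pytest

from nmaplan import ContrastDataset, ContrastRecord, example_network_spec


@pytest.fixture
def chain_dataset():
    """A -- C -- B chain with no direct A-B study; indirect se(A,B) = 0.5."""
    return ContrastDataset(
        [
            ContrastRecord("s1", "A", "C", 1.0, 0.3),
            ContrastRecord("s2", "C", "B", 0.5, 0.4),
        ]
    )


@pytest.fixture
def example_spec():
    return example_network_spec(seed=0)


def random_connected_dataset(rng: np.random.Generator, n_treat=None, n_study=None):
    """A random connected network for property tests (spanning tree + extras)."""
    n_treat = n_treat or rng.integers(2, 6)
    n_study = n_study or rng.integers(n_treat - 1, 9)
    n_study = max(n_study, n_treat - 1)
    labels = [chr(ord("A") + i) for i in range(n_treat)]
    records = []
    for i in range(1, n_treat):  # spanning tree first: connectivity guaranteed
        j = int(rng.integers(0, i))
        records.append(
            ContrastRecord(
                f"s{i}", labels[i], labels[j],
                float(rng.normal(0, 1)), float(rng.uniform(0.1, 1.0)),
            )
        )
    for k in range(n_treat - 1, n_study):
        i, j = rng.choice(n_treat, size=2, replace=False)
        records.append(
            ContrastRecord(
                f"s{k + 1}", labels[int(i)], labels[int(j)],
                float(rng.normal(0, 1)), float(rng.uniform(0.1, 1.0)),
            )
        )
    return ContrastDataset(records)
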