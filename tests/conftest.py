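import numpy as np
import pytest

from qhet import MetaDataset, StudyTable


def random_table(rng: np.random.Generator, n_min: int = 5, n_max: int = 200) -> StudyTable:
    n_t, n_c = (int(v) for v in rng.integers(n_min, n_max + 1, 2))
    return StudyTable(
        x=int(rng.integers(0, n_t + 1)),
        n_t=n_t,
        y=int(rng.integers(0, n_c + 1)),
        n_c=n_c,
    )


def random_dataset(
    rng: np.random.Generator,
    k: int,
    p: float = 0.3,
    n_min: int = 20,
    n_max: int = 80,
) -> MetaDataset:
    """K studies with binomial counts at a shared event probability."""
    tables = []
    for _ in range(k):
        n_t, n_c = (int(v) for v in rng.integers(n_min, n_max + 1, 2))
        tables.append(
            StudyTable(
                x=int(rng.binomial(n_t, p)),
                n_t=n_t,
                y=int(rng.binomial(n_c, p)),
                n_c=n_c,
            )
        )
    return MetaDataset(tables)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260924)


@pytest.fixture
def unrod_table() -> StudyTable:
    """The single added trial of the smoking-cessation worked example."""
    return StudyTable(x=28, n_t=237, y=18, n_c=228)
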