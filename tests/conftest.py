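import numpy as np
import pandas as pd
import pytest

from ubicore import CohortProfile, TaxonCountTable


@pytest.fixture
def toy_profile() -> CohortProfile:
    """4 donors x 3 taxa; taxon A is the only core member at 10%|75%
    (B ties at exactly 0.75 ubiquity and is excluded by strictness)."""
    ab = pd.DataFrame(
        [
            [0.6, 0.3, 0.1],
            [0.5, 0.5, 0.0],
            [0.9, 0.05, 0.05],
            [0.2, 0.8, 0.0],
        ],
        index=["d1", "d2", "d3", "d4"],
        columns=["A", "B", "C"],
    )
    return CohortProfile(ab)


@pytest.fixture
def toy_table() -> TaxonCountTable:
    df = pd.DataFrame(
        [[3, 1], [0, 4]], index=["d1", "d2"], columns=["tA", "tB"]
    )
    return TaxonCountTable(df)


def profile_from_columns(**columns) -> CohortProfile:
    """Build a profile from per-taxon abundance vectors, padding with a
    filler taxon so each row closes to 1."""
    df = pd.DataFrame(columns)
    filler = 1.0 - df.sum(axis=1)
    assert (filler >= -1e-12).all(), "columns exceed closure"
    df["_rest"] = filler.clip(lower=0.0)
    df.index = [f"d{i}" for i in range(len(df))]
    return CohortProfile(df)


def random_profile(rng: np.random.Generator, n_donors=None, n_taxa=None) -> CohortProfile:
    n = n_donors or int(rng.integers(2, 8))
    t = n_taxa or int(rng.integers(2, 6))
    counts = rng.integers(0, 50, size=(n, t))
    counts[:, 0] += 1  # ensure positive depth
    ab = counts / counts.sum(axis=1, keepdims=True)
    df = pd.DataFrame(ab, index=[f"d{i}" for i in range(n)], columns=[f"t{j}" for j in range(t)])
    return CohortProfile(df)
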