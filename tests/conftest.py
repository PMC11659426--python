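import numpy as np
import pandas as pd
import pytest

from assemblage.table import CommunityTable, PresenceAbsenceMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20240521)


@pytest.fixture
def small_counts():
    """3 taxa x 2 samples count table."""
    return CommunityTable(
        pd.DataFrame(
            [[2, 0], [2, 1], [4, 7]],
            index=["t1", "t2", "t3"],
            columns=["s1", "s2"],
        ),
        mode="counts",
    )


def random_counts_table(rng, n_taxa=8, n_samples=5, max_count=20) -> CommunityTable:
    values = rng.integers(0, max_count + 1, size=(n_taxa, n_samples))
    # keep every column nonzero so proportions are well defined
    for j in range(n_samples):
        if values[:, j].sum() == 0:
            values[rng.integers(n_taxa), j] = 1
    return CommunityTable(
        pd.DataFrame(
            values,
            index=[f"t{i}" for i in range(n_taxa)],
            columns=[f"s{j}" for j in range(n_samples)],
        ),
        mode="counts",
    )


def random_binary_matrix(rng, n_taxa=8, n_samples=6) -> PresenceAbsenceMatrix:
    values = (rng.random((n_taxa, n_samples)) < 0.5).astype(int)
    # avoid all-empty / all-full degenerate rows dominating
    return PresenceAbsenceMatrix(
        [f"t{i}" for i in range(n_taxa)],
        [f"s{j}" for j in range(n_samples)],
        values,
    )
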