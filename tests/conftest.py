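import numpy as np
import pandas as pd
import pytest

from refstab.data_model import CTTable


def make_ct_table(
    matrix,
    genes=None,
    levels=None,
    condition_set="test",
    assays=None,
) -> CTTable:
    """Build a collapsed CTTable from a gene x sample matrix.

    ``levels`` maps each sample column to a condition level; defaults to two
    alternating levels so group-based methods have something to chew on.
    """
    m = np.asarray(matrix, dtype=float)
    n_genes, n_samples = m.shape
    genes = genes or [f"g{i:02d}" for i in range(n_genes)]
    if levels is None:
        levels = [f"lv{j // max(1, n_samples // 2)}" for j in range(n_samples)]
    rows = []
    for j in range(n_samples):
        sample_id = f"s{j:02d}"
        for i in range(n_genes):
            rows.append(
                {
                    "sample_id": sample_id,
                    "condition_set": condition_set,
                    "level": levels[j],
                    "bio_rep": j + 1,
                    "gene": genes[i],
                    "ct": m[i, j],
                }
            )
    return CTTable(pd.DataFrame(rows), genes=assays)


@pytest.fixture
def toy_table() -> CTTable:
    """3 genes x 4 samples with distinct, hand-checkable CT values."""
    return make_ct_table(
        [[20.0, 21.0, 22.0, 20.5], [18.0, 18.5, 19.5, 18.2], [25.0, 24.0, 26.0, 25.5]]
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
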