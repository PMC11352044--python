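import numpy as np
import pandas as pd
import pytest

from foldbench import GroupedSample


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_matrix(tmp_path):
    """A 3-variable x 4-sample TSV matrix with matching labels, on disk."""
    matrix = pd.DataFrame(
        [[1.0, 2.0, 4.0, 8.0], [10.0, 12.0, 9.0, 11.0], [5.0, 5.0, 20.0, 20.0]],
        index=["gene1", "gene2", "gene3"],
        columns=["s1", "s2", "s3", "s4"],
    )
    matrix.index.name = "variable_id"
    labels = pd.DataFrame(
        {"sample_id": ["s1", "s2", "s3", "s4"],
         "group": ["reference", "reference", "treatment", "treatment"]}
    )
    mpath = tmp_path / "matrix.tsv"
    lpath = tmp_path / "labels.tsv"
    matrix.to_csv(mpath, sep="\t")
    labels.to_csv(lpath, sep="\t", index=False)
    return mpath, lpath, matrix


def random_positive_sample(rng, n_a=None, n_b=None):
    """A random strictly positive sample for property-style checks."""
    n_a = n_a or int(rng.integers(1, 12))
    n_b = n_b or int(rng.integers(1, 12))
    a = rng.lognormal(rng.normal(0, 2), rng.uniform(0.1, 2), n_a)
    b = rng.lognormal(rng.normal(0, 2), rng.uniform(0.1, 2), n_b)
    return GroupedSample(a=a, b=b, variable_id="prop")
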