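import numpy as np
import pandas as pd
import pytest

from cernanet import SimulationParams, generate_dataset
from cernanet.io import ExpressionMatrix


SMALL_PARAMS = SimulationParams(
    n_lncrna=30, n_mirna=20, n_mrna=40, n_triplets=5, decoy_interactions=20, seed=11
)


@pytest.fixture(scope="session")
def small_dataset():
    """A quick five-triplet synthetic dataset shared across tests."""
    return generate_dataset(SMALL_PARAMS)


@pytest.fixture
def groups10():
    samples = [f"Lean_{i}" for i in range(1, 6)] + [f"MetS_{i}" for i in range(1, 6)]
    return pd.Series(["Lean"] * 5 + ["MetS"] * 5, index=pd.Index(samples, name="sample_id"))


def make_matrix(values, kind="mRNA", groups=None, scale="counts", feature_ids=None):
    values = np.asarray(values)
    n_feat, n_samp = values.shape
    if groups is None:
        half = n_samp // 2
        samples = [f"Lean_{i}" for i in range(1, half + 1)] + [
            f"MetS_{i}" for i in range(1, n_samp - half + 1)
        ]
        groups = pd.Series(
            ["Lean"] * half + ["MetS"] * (n_samp - half),
            index=pd.Index(samples, name="sample_id"),
        )
    if feature_ids is None:
        feature_ids = [f"f{i}" for i in range(n_feat)]
    frame = pd.DataFrame(values, index=feature_ids, columns=list(groups.index))
    return ExpressionMatrix(values=frame, kind=kind, groups=groups, scale=scale)
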