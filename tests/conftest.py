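import numpy as np
import pandas as pd
import pytest

from stagepath import synthetic
from stagepath.io_formats import validate_metadata


@pytest.fixture
def tiny_matrix() -> pd.DataFrame:
    """3 genes x 4 samples with simple integer values."""
    return pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0],
         [4.0, 3.0, 2.0, 1.0],
         [5.0, 5.0, 5.0, 5.0]],
        index=["gA", "gB", "gC"],
        columns=["s1", "s2", "s3", "s4"],
    )


@pytest.fixture
def tiny_metadata() -> pd.DataFrame:
    meta = pd.DataFrame(
        {"phase": ["control", "control", "early", "late"],
         "stage": [pd.NA, pd.NA, "I", "III"]},
        index=pd.Index(["s1", "s2", "s3", "s4"], name="sample_id"),
    )
    return validate_metadata(meta)


@pytest.fixture(scope="session")
def small_cohort():
    """A modest simulated cohort shared by read-only tests."""
    return synthetic.simulate_dataset(
        n_genes=600, group_sizes=(40, 20, 30),
        n_de_early=40, n_de_late=40, n_shared=15,
        n_blocks=2, block_size=8, n_pathways=20, pathway_size=12,
        n_deviated=3, seed=101)


def control_cols(meta: pd.DataFrame) -> list[str]:
    return list(meta.index[meta["phase"] == "control"])
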