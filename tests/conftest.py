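import numpy as np
import pandas as pd
import pytest

from metabonet.data_io import AbundanceMatrix, GroupPair


@pytest.fixture
def small_matrix() -> AbundanceMatrix:
    """Tiny deterministic two-group matrix for I/O and plumbing tests."""
    rng = np.random.default_rng(42)
    values = pd.DataFrame(
        rng.lognormal(mean=5.0, sigma=1.0, size=(12, 6)),
        index=pd.Index([f"s{i}" for i in range(12)], name="sample_id"),
        columns=[f"met_{j}" for j in range(6)],
    )
    groups = pd.Series(["CRC"] * 6 + ["CTR"] * 6, index=values.index)
    return AbundanceMatrix(values=values, groups=groups)


@pytest.fixture
def crc_ctr() -> GroupPair:
    return GroupPair("CRC", "CTR")
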