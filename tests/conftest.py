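import numpy as np
import pandas as pd
import pytest

from phona.io_tables import OtuTable


@pytest.fixture
def tiny_table() -> OtuTable:
    """3 samples x 2 OTUs with easy-to-track counts."""
    return OtuTable(pd.DataFrame(
        [[5, 1], [3, 7], [0, 4]],
        index=["s1", "s2", "s3"], columns=["otuA", "otuB"]))


def make_table(counts, prefix_s="s", prefix_o="o") -> OtuTable:
    counts = np.asarray(counts)
    return OtuTable(pd.DataFrame(
        counts,
        index=[f"{prefix_s}{i}" for i in range(counts.shape[0])],
        columns=[f"{prefix_o}{j}" for j in range(counts.shape[1])]))
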