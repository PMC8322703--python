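import numpy as np
import pandas as pd
import pytest

from cernet.expression import ExpressionMatrix


@pytest.fixture
def toy_matrix() -> ExpressionMatrix:
    """3 genes x 4 samples, 2 case + 2 control, log2 scale."""
    df = pd.DataFrame(
        [[2.0, 2.0, 1.0, 1.0],
         [5.0, 6.0, 5.5, 5.5],
         [8.0, 8.2, 8.1, 7.9]],
        index=["GA", "GB", "GC"],
        columns=["s1", "s2", "s3", "s4"],
    )
    groups = {"s1": "case", "s2": "case", "s3": "control", "s4": "control"}
    return ExpressionMatrix(df, groups)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
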