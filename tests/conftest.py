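import pandas as pd
import pytest

from rgstab import CtMatrix

from _helpers import random_matrix


@pytest.fixture
def toy_matrix() -> CtMatrix:
    """Three genes whose pairwise variations are computable by hand."""
    vals = pd.DataFrame(
        {
            "S1": [20.0, 20.0, 20.0],
            "S2": [21.0, 21.0, 22.0],
            "S3": [22.0, 22.0, 21.0],
        },
        index=["G1", "G2", "G3"],
    )
    return CtMatrix(values=vals, condition={s: "CTRL" for s in vals.columns})


@pytest.fixture
def random_matrix_factory():
    return random_matrix
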