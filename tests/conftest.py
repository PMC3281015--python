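import numpy as np
import pandas as pd
import pytest

from qtlact.model import CODE_A, CODE_B, CODE_MISSING, GenotypeMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def toy_gmatrix():
    """8 homozygous strains at 5 markers on two chromosomes."""
    markers = pd.DataFrame(
        {
            "marker": ["m1", "m2", "m3", "m4", "m5"],
            "chromosome": ["1", "1", "1", "2", "2"],
            "position_mb": [10.0, 20.0, 30.0, 5.0, 15.0],
        }
    )
    codes = np.array(
        [
            [CODE_A, CODE_A, CODE_A, CODE_A, CODE_B],
            [CODE_A, CODE_A, CODE_A, CODE_A, CODE_B],
            [CODE_A, CODE_A, CODE_B, CODE_B, CODE_A],
            [CODE_A, CODE_B, CODE_B, CODE_B, CODE_A],
            [CODE_B, CODE_B, CODE_B, CODE_B, CODE_A],
            [CODE_B, CODE_B, CODE_A, CODE_A, CODE_B],
            [CODE_B, CODE_A, CODE_A, CODE_B, CODE_B],
            [CODE_B, CODE_B, CODE_MISSING, CODE_A, CODE_A],
        ],
        dtype=np.int8,
    )
    return GenotypeMatrix(
        panel_id="TOY",
        strains=[f"S{i}" for i in range(1, 9)],
        markers=markers,
        codes=codes,
    )


@pytest.fixture
def balanced_codes():
    return np.array([0, 0, 0, 0, 1, 1, 1, 1], dtype=np.int8)
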