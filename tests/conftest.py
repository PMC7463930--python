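import numpy as np
import pandas as pd
import pytest

from peptraits.peptide_io import GroupLabel, Peptide
from peptraits import synthetic_data as sd

MAGAININ_II = "GIGKFLHSAKKFGKAFVGEIMNS"


@pytest.fixture
def magainin():
    return Peptide("magainin_II", MAGAININ_II, group=GroupLabel("HA-RAMP", "magainin"))


@pytest.fixture
def random_set():
    """50 null-model peptides, fixed seed."""
    return sd.random_peptides(50, seed=11)


@pytest.fixture
def small_table():
    """Standardized-ish random descriptor table: 12 rows x 8 columns."""
    rng = np.random.default_rng(5)
    X = pd.DataFrame(
        rng.normal(size=(12, 8)),
        index=[f"p{i}" for i in range(12)],
        columns=[f"c{i}" for i in range(8)],
    )
    return (X - X.mean()) / X.std(ddof=1)
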