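import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from subtme.io import ExpressionMatrix
from subtme.preprocess import normalize
from subtme.simulate import SimulationConfig, simulate_cohort


def make_em(array, genes=None, obs=None, normalized=False) -> ExpressionMatrix:
    """Build an ExpressionMatrix from a dense genes x obs array."""
    array = np.asarray(array)
    genes = genes or [f"G{i + 1}" for i in range(array.shape[0])]
    obs = obs or [f"c{i + 1}" for i in range(array.shape[1])]
    m = ExpressionMatrix(pd.Index(genes), pd.Index(obs), sp.csr_matrix(array))
    return normalize(m) if normalized else m


def simple_annotation(obs, subtypes, sample_id="S1", tissue="tumor", major="M"):
    """One-sample annotation frame assigning the given subtype labels."""
    return pd.DataFrame(
        {
            "cell_id": list(obs),
            "sample_id": sample_id,
            "tissue": tissue,
            "major_type": major,
            "subtype": list(subtypes),
        }
    )


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort shared by read-only tests."""
    cfg = SimulationConfig(seed=0, n_samples=20, cells_per_sample=300)
    m, ann = simulate_cohort(cfg)
    return cfg, normalize(m), ann
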