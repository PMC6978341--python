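import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from famvar.io import ClinicalTable, ExpressionMatrix

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow], deadline=None
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def small_matrix():
    """4 samples x 5 genes, deterministic values."""
    rs = np.random.default_rng(7)
    df = pd.DataFrame(
        rs.uniform(0, 50, size=(4, 5)),
        index=[f"S{i}" for i in range(4)],
        columns=["GENEA", "GENEB", "GENEC", "GENED", "GENEE"],
    )
    return ExpressionMatrix(df)


@pytest.fixture
def small_clinical():
    df = pd.DataFrame(
        {
            "class_label": ["A", "A", "B", "B"],
            "mrnasi": [0.2, 0.5, np.nan, 0.8],
            "time": [12.0, 40.0, 7.5, 80.0],
            "event": [1, 0, 1, 0],
        },
        index=pd.Index([f"S{i}" for i in range(4)], name="sample_id"),
    )
    return ClinicalTable(df)
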