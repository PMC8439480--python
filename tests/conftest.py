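import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def tiny_beta() -> pd.DataFrame:
    """3 CpGs x 4 samples, one missing value, values spanning [0, 1]."""
    return pd.DataFrame(
        {
            "s1": [0.1, 0.5, 1.0],
            "s2": [0.3, 0.5, 0.0],
            "s3": [0.2, np.nan, 0.5],
            "s4": [0.1, 0.5, 0.5],
        },
        index=pd.Index(["cg1", "cg2", "cg3"], name="cpg_id"),
    )


@pytest.fixture
def tiny_annotation() -> pd.DataFrame:
    """cg1 multimaps to two genes; cg2/cg3 belong to GENEB."""
    return pd.DataFrame(
        {
            "cpg_id": ["cg1", "cg1", "cg2", "cg3"],
            "gene": ["GENEA", "GENEC", "GENEB", "GENEB"],
        }
    )


@pytest.fixture
def crypt_sheet() -> pd.DataFrame:
    """4 crypts within each of 2 individuals."""
    rows = []
    for ind in (1, 2):
        for crypt in range(1, 5):
            rows.append(
                {
                    "sample_id": f"i{ind}c{crypt}",
                    "group": f"i{ind}",
                    "tissue": "colon",
                    "time": 600.0,
                    "time_unit": "months",
                    "condition": "control",
                }
            )
    return pd.DataFrame(rows)
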