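import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from trinet import ExpressionMatrix

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


def make_matrix(values, gene_ids=None, sample_ids=None, types=None,
                log_transformed=False):
    """Small ExpressionMatrix builder for tests."""
    arr = np.asarray(values, dtype=float)
    g = gene_ids or [f"G{i}" for i in range(arr.shape[0])]
    s = sample_ids or [f"S{j}" for j in range(arr.shape[1])]
    t = types or ["mRNA"] * arr.shape[0]
    df = pd.DataFrame(arr, index=g, columns=s)
    return ExpressionMatrix(df, pd.Series(t, index=df.index),
                            log_transformed)


@pytest.fixture
def tiny_rpkm():
    """3 genes x 3 samples on the RPKM scale, with zeros to impute."""
    return make_matrix([[0.0, 2.0, 5.0],
                        [1.0, 0.0, 4.0],
                        [3.0, 6.0, 0.5]],
                       types=["mRNA", "lncRNA", "miRNA"])
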