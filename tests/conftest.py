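import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20200406)


@pytest.fixture
def toy_expression():
    """3 genes x 4 samples raw expression matrix."""
    from mutcorr import ExpressionMatrix
    values = pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0],
         [10.0, 10.0, 30.0, 50.0],
         [-1.0, 0.0, 1.0, 2.0]],
        index=["GA", "GB", "GC"], columns=["S1", "S2", "S3", "S4"])
    return ExpressionMatrix(values)


@pytest.fixture
def cell_cycle_labels():
    """124-gene synthetic pathway with engineered 73/19/16/16 tripartition
    and the two nested complexes reproducing the screen's worked examples."""
    from mutcorr import make_cell_cycle_fixture

    sets = make_cell_cycle_fixture()
    pathway = sets["cell_cycle"]
    mcm, cdk = sets["MCM"], sets["CDK4_6"]
    labels = {}
    # MCM complex: all 6 positive-only. CDK4/6 complex: 5 negative-only,
    # 6 positive-negative, 8 positive-only (=> 11 "negative" pooled, 6
    # positive-negative). Remaining pathway genes fill the margins to
    # 73 positive-only / 19 negative-only / 16 positive-negative /
    # 16 unclassified.
    for g in mcm:
        labels[g] = "positive_only"
    for i, g in enumerate(cdk):
        labels[g] = ("negative_only" if i < 5 else
                     "positive_negative" if i < 11 else "positive_only")
    rest = [g for g in pathway if g not in labels]
    n_pos = 73 - 6 - 8
    n_neg = 19 - 5
    n_pn = 16 - 6
    for i, g in enumerate(rest):
        labels[g] = ("positive_only" if i < n_pos else
                     "negative_only" if i < n_pos + n_neg else
                     "positive_negative" if i < n_pos + n_neg + n_pn else
                     "unclassified")
    return sets, labels
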