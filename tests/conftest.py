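import numpy as np
import pandas as pd
import pytest

import proberel as pr


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_beta_matrix():
    """3 probes x 4 samples, fixed values."""
    vals = pd.DataFrame(
        [[0.1, 0.2, 0.3, 0.4], [0.5, 0.5, 0.5, 0.5], [0.9, 0.8, 0.7, 0.6]],
        index=["cg01", "cg02", "cg03"],
        columns=["s1", "s2", "s3", "s4"],
    )
    return pr.BetaMatrix(vals, platform_label="450K")


@pytest.fixture
def paired_panel():
    """Small calibrated synthetic paired panel with ground truth."""
    cfg = pr.GeneratorConfig(n_probes=400, n_samples=60, seed=99)
    return pr.generate_paired(cfg)


@pytest.fixture
def reliability_table_small(paired_panel):
    paired, _truth = paired_panel
    return pr.reliability_table(paired)
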