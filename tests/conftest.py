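"""Shared fixtures.

The two session-scoped benchmark fixtures run the full semisupervised
workflow once (synthetic dataset -> features -> isolation forest ->
calibrated thresholds) and are shared by every test that needs a fitted,
calibrated model.
"""

import numpy as np
import pytest

from wearsqa.config import default_config
from wearsqa.pipeline import run_benchmark


@pytest.fixture(scope="session")
def ecg_benchmark():
    return run_benchmark(default_config("ECG"), seed=7)


@pytest.fixture(scope="session")
def resp_benchmark():
    return run_benchmark(default_config("RESP"), seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
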