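from datetime import date

import numpy as np
import pandas as pd
import pytest

from trusscast.config import PipelineConfig
from trusscast.thermal import DailySeries


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def constant_20c():
    """A daily series of 20 degrees C covering the autumn 2020 worked example."""
    idx = pd.date_range("2020-09-01", "2021-01-31", freq="D")
    return DailySeries(idx, np.full(len(idx), 20.0), np.ones(len(idx), dtype=bool))


@pytest.fixture
def default_config():
    cfg = PipelineConfig()
    cfg.seed = 7
    return cfg


@pytest.fixture
def bloom_sep1():
    return date(2020, 9, 1)
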