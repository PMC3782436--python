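import numpy as np
import pandas as pd
import pytest

from seasonfire.catalog import load_entry
from seasonfire.sem import Edge, PathModel


@pytest.fixture(scope="session")
def dry_best():
    return load_entry("dry_best")


@pytest.fixture(scope="session")
def dry_best_skeleton(dry_best):
    """The best dry-season structure with every coefficient freed."""
    m = dry_best.model
    return PathModel(m.variables, [Edge(e.source, e.target) for e in m.edges], name="dry_best_skeleton")


def daily_series(values, start="2000-01-01"):
    values = np.asarray(values, dtype=float)
    idx = pd.date_range(start, periods=len(values), freq="D")
    return pd.Series(values, index=idx, name="rain_mm")


@pytest.fixture
def make_daily():
    return daily_series
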