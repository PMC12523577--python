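import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from eaccd.cohort import EVENT_COL, ID_COL, TIME_COL, YEAR_COL

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=40,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_records(rows, factors=("T", "N", "M", "P", "G")):
    """Build a patient table in the shape read_patient_table produces.

    ``rows``: iterable of (levels_dict, time, event[, year]); time/event may
    be NaN for unknown.
    """
    data = []
    for i, row in enumerate(rows):
        levels, time, event = row[0], row[1], row[2]
        year = row[3] if len(row) > 3 else np.nan
        rec = {ID_COL: str(i + 1)}
        for f in factors:
            rec[f] = levels.get(f, "unknown")
        rec[TIME_COL] = float(time)
        rec[EVENT_COL] = float(event)
        rec[YEAR_COL] = year
        data.append(rec)
    return pd.DataFrame(data, columns=[ID_COL, *factors, TIME_COL, EVENT_COL, YEAR_COL])


def uniform_levels(scheme_levels, rng, factors=("T", "N", "M", "P", "G")):
    return {f: rng.choice(scheme_levels[f]) for f in factors}


@pytest.fixture
def records_factory():
    return make_records


def random_dissimilarity(rng, n, decimals=None):
    """Random symmetric zero-diagonal matrix; rounding forces ties."""
    v = rng.uniform(0.05, 1.0, size=(n, n))
    v = (v + v.T) / 2
    if decimals is not None:
        v = np.round(v, decimals)
        v = np.maximum(v, 0.05)
    np.fill_diagonal(v, 0.0)
    return v
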