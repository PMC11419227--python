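import numpy as np
import pandas as pd
import pytest

from rarkit import DayMatrix, EpochSeries

MIDNIGHT = pd.Timestamp("2024-03-01 00:00:00")


def make_dm(values, epoch_seconds=60, subject_id="s1", start=MIDNIGHT):
    values = np.asarray(values)
    if values.ndim == 1:
        values = values.reshape(-1, 86400 // epoch_seconds)
    return DayMatrix(subject_id, epoch_seconds, values, start)


def make_series(counts, epoch_seconds=60, start=MIDNIGHT, subject_id="s1"):
    return EpochSeries(subject_id, start, epoch_seconds, np.asarray(counts))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_day_dm(rng):
    return make_dm(rng.integers(0, 300, size=(2, 1440)))
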