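import numpy as np
import pandas as pd
import pytest

from admatch import AttributableDeathsEstimator
from admatch.simulate import generate_series, milan_like_config
from admatch.strata import DEATH_COLUMNS


@pytest.fixture(scope="session")
def milan_run():
    """One Milan-like 4-year simulation with a fitted pipeline (seed 1)."""
    series, truth = generate_series(milan_like_config(seed=1))
    est = AttributableDeathsEstimator().fit(series)
    return series, truth, est


@pytest.fixture(scope="session")
def short_series():
    """A cheap 1-year series for structural tests."""
    series, truth = generate_series(milan_like_config(seed=7, n_years=1))
    return series, truth


def tiny_design(n_treated: int = 3, n_control: int = 6, seed: int = 0) -> pd.DataFrame:
    """Hand-sized design table with all required covariate columns."""
    rng = np.random.default_rng(seed)
    n = n_treated + n_control
    df = pd.DataFrame({
        "date": pd.date_range("2003-01-04", periods=n),
        "w": [1] * n_treated + [0] * n_control,
        "x": np.r_[rng.uniform(40, 80, n_treated), rng.uniform(5, 39, n_control)],
        "temp03": rng.uniform(0, 25, n),
        "humidity": rng.uniform(40, 90, n),
        "day_of_year": np.arange(4, 4 + n),
        "year_length": 365,
        "day_of_week": np.arange(n) % 7,
        "weekend": (np.arange(n) % 7 >= 5).astype(int),
        "season": "DJF",
        "holiday": 0,
        "influenza": 0,
        "heat": 0,
        "julyaug": 0,
        "calendar_index": np.arange(n),
    })
    for col in DEATH_COLUMNS:
        df[col] = rng.poisson(3.0, n)
    return df
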