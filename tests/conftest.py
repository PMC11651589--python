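import numpy as np
import pandas as pd
import pytest

from ccburden import SynthConfig, generate


@pytest.fixture(scope="session")
def small_data():
    """One year, 4 districts, ~800 cases: shared by fit-level tests."""
    cfg = SynthConfig(
        n_districts=4,
        start="2015-01-01",
        end="2015-12-31",
        baseline_rate=0.5,
        seed=11,
    )
    panel, cases = generate(cfg)
    return cfg, panel, cases


@pytest.fixture(scope="session")
def medium_data():
    """~3,000 cases over two years: cross-implementation oracle fixture."""
    cfg = SynthConfig(
        n_districts=6,
        start="2015-01-01",
        end="2016-12-31",
        baseline_rate=0.7,
        seed=23,
    )
    panel, cases = generate(cfg)
    return cfg, panel, cases


def toy_panel(district="D1", start="2015-06-01", days=120, pm=None, temp=20.0,
              holidays=()):
    """Deterministic single-district panel for arithmetic-level tests."""
    dates = pd.date_range(start, periods=days)
    pm = np.full(days, 25.0) if pm is None else np.asarray(pm, dtype=float)
    return pd.DataFrame(
        {
            "district_id": district,
            "date": dates,
            "pm25": pm,
            "temperature": np.full(days, float(temp)),
            "holiday": [d in set(pd.to_datetime(list(holidays))) for d in dates],
        }
    )
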