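import pandas as pd
import pytest

from heatrisk import SyntheticConfig, apply_heat_index, build_features, generate_climate


@pytest.fixture(scope="session")
def short_series() -> pd.DataFrame:
    """One year of synthetic 3-hourly climate with default structure."""
    cfg = SyntheticConfig(
        start_date="2021-01-01", end_date="2021-12-31", seed=7
    )
    return generate_climate(cfg)


@pytest.fixture(scope="session")
def hi_series(short_series) -> pd.DataFrame:
    return apply_heat_index(short_series)


@pytest.fixture(scope="session")
def feature_matrix(hi_series) -> pd.DataFrame:
    return build_features(hi_series)
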