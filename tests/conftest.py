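import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from aquabatch.fixturegen import (
    StudyDesign, ToyCropParams, WeatherParams, generate_weather, simulate_run,
)

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow], deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_crop():
    return ToyCropParams()


@pytest.fixture(scope="session")
def three_year_seasons(default_crop):
    """Three simulated seasons under the default study conditions."""
    weather = generate_weather(WeatherParams(n_years=3, seed=11))
    return simulate_run(weather, default_crop)


@pytest.fixture(scope="session")
def tiny_design():
    """A 2x2 factorial used where only structure matters."""
    return StudyDesign(
        crop="Maize",
        factors={"location": ["Soroca", "Cahul"], "scenario": ["RCP26", "RCP85"]},
        overrides={"scenario": {"RCP26": {"warming_trend": 0.1},
                                "RCP85": {"warming_trend": 0.5}}},
    )


def canonical(frame: pd.DataFrame) -> pd.DataFrame:
    """Round a table to the dialect's printed precision, mapping the
    -9.00 sentinel to missing, for write->read comparisons."""
    out = frame.copy()
    for col in out.columns:
        if pd.api.types.is_float_dtype(out[col]) or pd.api.types.is_integer_dtype(out[col]):
            vals = pd.to_numeric(out[col]).astype(float).round(2)
            out[col] = vals.mask(vals == -9.0)
    return out


def assert_tables_equal_at_precision(written: pd.DataFrame, parsed: pd.DataFrame,
                                     columns):
    a = canonical(written[columns]).reset_index(drop=True)
    b = canonical(parsed[columns]).reset_index(drop=True)
    pd.testing.assert_frame_equal(a, b, check_dtype=False, atol=1e-9)
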