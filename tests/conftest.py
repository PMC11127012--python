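import numpy as np
import pytest

from baybloom import SynthConfig, apply_missingness, generate_panel
from baybloom.core import WeekIndex, WeeklySeries
from baybloom.synth import MissingnessConfig


@pytest.fixture(scope="session")
def small_config() -> SynthConfig:
    """10-year study conditions with a scaled-down missingness pattern."""
    return SynthConfig(
        n_years=10,
        seed=42,
        missingness=MissingnessConfig(
            point_rate=0.10,
            biweekly_spans=((1970, 1970),),
            block_gaps=((1975, 1975),),
        ),
    )


@pytest.fixture(scope="session")
def small_panel(small_config):
    """(masked panel, full panel, truth) for a 10-year synthetic record."""
    panel, truth = generate_panel(small_config)
    masked = apply_missingness(panel, small_config)
    return masked, panel, truth


def make_series(values, mask=None, name="x", year=2000, week=1) -> WeeklySeries:
    values = np.asarray(values, float)
    if mask is None:
        mask = np.isfinite(values)
    return WeeklySeries(name, values, np.asarray(mask, bool), WeekIndex(year, week))
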