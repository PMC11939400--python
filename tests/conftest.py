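import numpy as np
import pandas as pd
import pytest

from circaseason import ActigraphySeries, GeneratorConfig, SEASONS


def make_series(values: dict, start="2024-01-01 00:00", mask=None,
                pid="P01", season="winter") -> ActigraphySeries:
    return ActigraphySeries(participant_id=pid, season=season,
                            start=pd.Timestamp(start), channels=values, mask=mask)


@pytest.fixture
def week_minutes():
    """Clock hours for a 7-day, 1-minute grid starting at midnight."""
    return np.arange(7 * 1440) / 60.0


@pytest.fixture
def square_wave_series(week_minutes):
    """Activity 100 during 10:00-20:00 every day, 0 otherwise."""
    clock = week_minutes % 24.0
    act = np.where((clock >= 10.0) & (clock < 20.0), 100.0, 0.0)
    return make_series({"activity": act})


@pytest.fixture
def noiseless_config():
    """Generator with every noise source off and no sleep gating."""
    return GeneratorConfig(
        activity_mesor_sd=0.0, activity_amplitude_sd=0.0,
        activity_acrophase_sd=0.0, activity_noise_mean=0.0,
        light_noise_sd=0.0, habit_sd=0.0, phase_jitter_sd=0.0,
        night_light_lux=0.0,
        blue_noise_sd=0.0, temp_noise_sd=0.0, residual_sd=0.0,
        cq_reference_sd=0.0,
        sleep_window={s: None for s in SEASONS},
    )


@pytest.fixture
def expression_table():
    return pd.DataFrame({
        "participant_id": ["P01", "P02", "P03", "P04"],
        "season": ["winter", "winter", "summer", "summer"],
        "cq_target": [27.0, 27.0, 25.0, 26.0],
        "cq_reference": [20.0, 20.0, 20.0, 20.0],
    })
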