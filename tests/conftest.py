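import numpy as np
import pytest

from sleepstream import (
    NightConfig,
    OnsetConfig,
    PhysioConfig,
    Recording,
    StagingConfig,
    simulate_night,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20250901)


@pytest.fixture
def short_cfg():
    """Cascade config scaled to short test fixtures (minutes, not hours)."""
    return StagingConfig(
        win_size=60,
        smooth_win=5,
        sdnn_win=30,
        x3=20,
        x5=20,
        onset=OnsetConfig(baseline_win=120, stab_dur=60),
    )


@pytest.fixture
def short_night_cfg():
    """Night architecture compressed to ~25 minutes for fast end-to-end tests."""
    return NightConfig(
        duration=1500,
        wake_prologue=300,
        mean_episode={"WAKE": 120.0, "LIGHT": 300.0, "DEEP": 240.0, "REM": 280.0},
        min_episode=40,
    )


@pytest.fixture
def short_night(short_night_cfg):
    # seed chosen so all four stages are well represented in 25 minutes
    return simulate_night(short_night_cfg, PhysioConfig.exaggerated(), 19)


def make_recording(rng, n=300, start=0):
    """Random but physiologically valid recording for property tests."""
    hr = np.clip(rng.normal(65, 8, n), 30, 180)
    rr = np.clip(60000.0 / hr + rng.normal(0, 40, n), 300, 2500)
    acc = np.array([0.0, 0.0, 1.0]) + rng.normal(0, 0.02, (n, 3))
    return Recording(start_time=start, hr=hr, rr=rr, acc=acc, subject_id="fixture")
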