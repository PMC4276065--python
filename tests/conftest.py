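import numpy as np
import pandas as pd
import pytest

import wristacc as wa

DAY0 = pd.Timestamp("2012-06-04 00:00:00")


def make_series(
    n_days: int = 3,
    fill: float = 50.0,
    epoch_length_s: int = 5,
    start_slot: int = 0,
    n_epochs: int | None = None,
    pid: str = "T001",
) -> wa.EpochSeries:
    """Epoch series filled with a constant value, all epochs valid."""
    spd = 86400 // epoch_length_s
    n = n_days * spd if n_epochs is None else n_epochs
    return wa.EpochSeries(
        pid, DAY0, epoch_length_s, start_slot,
        np.full(n, float(fill)), np.zeros(n, dtype=np.int8),
    )


@pytest.fixture(scope="session")
def cfg() -> wa.PipelineConfig:
    return wa.PipelineConfig()


@pytest.fixture(scope="session")
def distorted_recording():
    """3-day recording with a known calibration distortion and one planted
    non-wear episode; shared across calibration/non-wear unit tests."""
    schedule = wa.build_schedule(
        day_count=3, seed=3, nonwear_episodes=[(1, "10:00", 2.0)]
    )
    distortion = wa.DistortionSpec((1.03, 0.98, 1.01), (0.015, -0.010, 0.005))
    rec, truth = wa.generate_recording(schedule, distortion)
    return rec, truth


@pytest.fixture(scope="session")
def protocol_recording():
    """5-day identity-distortion recording following the default protocol
    (30 min continuous MVPA at 200 mg per day); shared end-to-end fixture."""
    schedule = wa.build_schedule(day_count=5, seed=7)
    rec, truth = wa.generate_recording(schedule)
    return rec, truth


@pytest.fixture(scope="session")
def protocol_result(protocol_recording, cfg):
    rec, _ = protocol_recording
    return wa.process_recording(rec, cfg)
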