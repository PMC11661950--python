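"""Shared fixtures: small simulated wards and hand-built log frames."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from wardsense.simulate import (
    DurationDist,
    GroupEvent,
    RssiModel,
    WardConfig,
    generate_contact_schedule,
    render_badge_logs,
)


@pytest.fixture(scope="session")
def small_ward() -> WardConfig:
    """A 3-patient / 4-staff ward over 6 weekdays; quick to render."""
    return WardConfig(
        n_patients=3,
        n_staff=4,
        study_days=6,
        background_rate=6.0,
        spurious_rate=10.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_logs(small_ward):
    schedule = generate_contact_schedule(small_ward)
    detections, battery = render_badge_logs(schedule, small_ward)
    return schedule, detections, battery


@pytest.fixture()
def noiseless_ward() -> WardConfig:
    """Deterministic sensing: no packet loss, no RSSI noise, no far-field hits."""
    return WardConfig(
        n_patients=3,
        n_staff=3,
        study_days=2,
        packet_drop_prob=0.0,
        spurious_rate=0.0,
        rssi_model=RssiModel(noise_sd=0.0),
        background_rate=4.0,
        duration_dist=DurationDist(exponent=1.7, min_s=700.0, max_s=3000.0),
        event_schedule=(GroupEvent("lunch", "12:30", 1800.0, 0.9),),
        seed=5,
    )


def detection_frame(rows) -> pd.DataFrame:
    """Build a detection frame from (receiver, sender, rssi, ts) tuples."""
    return pd.DataFrame(rows, columns=["receiver_id", "sender_id", "rssi_dbm", "timestamp_unix_s"])


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
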