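import datetime
import pathlib
import sys

import numpy as np
import pytest

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parent))

from epochsleep import DeviceDay, DeviceModel, TruthParams, simulate_study
from epochsleep.timeutil import clock_to_slot


def make_day(
    lying_spans=(),
    sleeping_spans=(),
    nonwear_spans=(),
    anchor="2024-01-01",
    subject_id="S1",
    device_id="D1",
):
    """Build a DeviceDay from clock-time span specs.

    Spans are ``(start, end)`` pairs of ``"HH:MM"`` strings, half-open on
    the noon-anchored minute axis; times before 12:00 belong to the next
    calendar morning.
    """
    lying = np.zeros(1440, np.int8)
    sleeping = np.zeros(1440, np.int8)
    wearing = np.ones(1440, np.int8)
    for spans, arr, val in (
        (lying_spans, lying, 1),
        (sleeping_spans, sleeping, 1),
        (nonwear_spans, wearing, 0),
    ):
        for start, end in spans:
            a, b = clock_to_slot(start), clock_to_slot(end)
            if b == 0:
                b = 1440
            arr[a:b] = val
    return DeviceDay(
        subject_id=subject_id,
        device_id=device_id,
        anchor_date=datetime.date.fromisoformat(anchor),
        lying=lying,
        sleeping=sleeping,
        wearing=wearing,
    )


@pytest.fixture(scope="session")
def small_study():
    """A 6-subject x 7-day two-device study with default error models."""
    params = TruthParams(n_subjects=6, n_days=7, seed=42)
    return simulate_study(params, DeviceModel(), DeviceModel())
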