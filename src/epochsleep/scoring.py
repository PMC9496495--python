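"""Nightly sleep-window detection and sleep indices from epoch data.

The scorer consumes minute epochs carrying two binary indicators — lying
down and asleep — and locates, within a user-defined night window
(default 19:00 to 11:59 the next day), the nightly sleep window and bed
window, then derives eleven per-night indices: bedtime, sleep onset,
sleep offset, waketime, midpoint of sleep, time in bed (TIB), total
sleep time (TST), sleep efficiency (SE), sleep onset latency (SOL),
wake after sleep onset (WASO) and sleep fragmentations (SF).

Detection rules, applied on the noon-anchored minute axis:

1. The candidate sleep onset is the first night-window epoch classified
   as lying down *and* asleep.
2. While scanning forward before midnight, any wake bout of at least
   ``wake_reset_minutes`` (default 10) pushes the candidate onset to the
   next sleep epoch — evening dozing followed by extended wake does not
   start the night.
3. If the subject is awake at midnight, onset is the first sleep epoch
   after midnight.
4. The window ends one epoch past the last sleep epoch that is followed
   (before any further sleep) by at least ``upright_terminate_minutes``
   (default 90) of consecutive upright (not lying) time, or at the end
   of the night window.

Bedtime extends the onset backwards through the contiguous lying run
containing it; waketime extends the offset forwards likewise.  All
intervals are half-open: the sleep window is ``[onset, offset)`` and the
bed window ``[bedtime, waketime)``, which makes TST/TIB arithmetic exact.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
from typing import Optional

import numpy as np

from .epoch_io import DeviceDay
from .timeutil import clock_to_slot, minutes_to_epochs, slot_to_clock

__all__ = [
    "ScoringConfig",
    "SleepWindow",
    "BedWindow",
    "DailyIndices",
    "detect_sleep_window",
    "detect_bed_window",
    "count_waso_sf",
    "score_day",
]


@dataclasses.dataclass(frozen=True)
class ScoringConfig:
    """Tunable parameters of the nightly scorer.

    ``night_start``/``night_end`` bound the candidate night (start before
    midnight, end after); ``wake_reset_minutes`` is the evening wake-bout
    length that restarts the onset search; ``upright_terminate_minutes``
    is the consecutive upright time that closes the sleep window.
    """

    night_start: str = "19:00"
    night_end: str = "11:59"
    wake_reset_minutes: int = 10
    upright_terminate_minutes: int = 90
    epoch_seconds: int = 60

    def __post_init__(self) -> None:
        if self.wake_reset_minutes <= 0 or self.upright_terminate_minutes <= 0:
            raise ValueError("scoring thresholds must be positive")
        if clock_to_slot(self.night_start) >= 720:
            raise ValueError("night_start must precede midnight")
        if clock_to_slot(self.night_end) < 720:
            raise ValueError("night_end must follow midnight")

    # slot geometry, in epochs
    @property
    def epochs_per_minute_divisor(self) -> int:
        return self.epoch_seconds

    def _slot(self, clock: str) -> int:
        minutes = clock_to_slot(clock)
        return minutes_to_epochs(minutes, self.epoch_seconds)

    @property
    def night_start_slot(self) -> int:
        return self._slot(self.night_start)

    @property
    def night_end_slot(self) -> int:
        """Inclusive last slot of the night window."""
        return self._slot(self.night_end)

    @property
    def midnight_slot(self) -> int:
        return minutes_to_epochs(720, self.epoch_seconds)

    @property
    def wake_reset_epochs(self) -> int:
        return minutes_to_epochs(self.wake_reset_minutes, self.epoch_seconds)

    @property
    def upright_terminate_epochs(self) -> int:
        return minutes_to_epochs(self.upright_terminate_minutes, self.epoch_seconds)


@dataclasses.dataclass(frozen=True)
class SleepWindow:
    """Half-open sleep window ``[onset, offset)`` in slots since noon."""

    onset: int
    offset: int
    flags: tuple[str, ...] = ()


@dataclasses.dataclass(frozen=True)
class BedWindow:
    """Half-open bed window ``[bedtime, waketime)`` in slots since noon."""

    bedtime: int
    waketime: int


@dataclasses.dataclass(frozen=True)
class DailyIndices:
    """The eleven per-night sleep indices plus bookkeeping.

    Clock-valued fields (``bedtime`` through ``midpoint``) are minutes
    since the anchoring noon; ``midpoint`` may carry a half minute.
    """

    subject_id: str
    device_id: str
    anchor_date: _dt.date
    is_weekend: bool
    bedtime: int
    sleep_onset: int
    sleep_offset: int
    waketime: int
    midpoint: float
    tib: int
    tst: int
    se: float
    sol: int
    waso: int
    sf: int
    flags: tuple[str, ...] = ()

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["flags"] = ";".join(self.flags)
        return d

    def clock(self, field: str) -> str:
        """Render a clock-valued field (slots since noon) as HH:MM."""
        return slot_to_clock(getattr(self, field))


def _max_zero_run(values: np.ndarray) -> int:
    """Length of the longest run of zeros in a 1-D 0/1 array."""
    if values.size == 0:
        return 0
    is_zero = values == 0
    # run lengths via change-point indices
    padded = np.concatenate(([False], is_zero, [False]))
    changes = np.flatnonzero(padded[1:] != padded[:-1])
    if changes.size == 0:
        return 0
    return int((changes[1::2] - changes[0::2]).max())


def detect_sleep_window(day: DeviceDay, config: ScoringConfig | None = None) -> Optional[SleepWindow]:
    """Locate the nightly sleep window, or ``None`` if the night has no sleep."""
    config = config or ScoringConfig(epoch_seconds=day.epoch_seconds)
    if config.epoch_seconds != day.epoch_seconds:
        raise ValueError("config epoch length does not match the day's epochs")
    ns, ne, mid = config.night_start_slot, config.night_end_slot, config.midnight_slot
    ly = day.lying.astype(bool)
    sl = day.sleeping.astype(bool)
    flags: list[str] = []

    both = ly & sl
    cand = np.flatnonzero(both[ns : ne + 1])
    onset: Optional[int] = int(cand[0]) + ns if cand.size else None

    # rule 2: extended evening wake (>= wake_reset) restarts the onset search
    if onset is not None:
        pos = onset
        while pos < mid:
            wake = np.flatnonzero(~sl[pos : mid])
            if wake.size == 0:
                break
            bout_start = pos + int(wake[0])
            nxt = np.flatnonzero(sl[bout_start : ne + 1])
            if nxt.size == 0:
                break  # no further sleep; rule 3 below decides the night
            next_sleep = bout_start + int(nxt[0])
            if next_sleep - bout_start >= config.wake_reset_epochs:
                onset = next_sleep
                flags.append("onset_reset")
            pos = next_sleep

    # rule 3: awake at midnight -> onset is the first sleep epoch after it
    if not sl[mid]:
        after = np.flatnonzero(sl[mid + 1 : ne + 1])
        if after.size == 0:
            return None
        onset = mid + 1 + int(after[0])
        flags.append("onset_after_midnight")
    elif onset is None:
        return None

    # rule 4: terminate at the last sleep epoch followed by >= 90 min upright
    sleep_idx = np.flatnonzero(sl[onset : ne + 1]) + onset
    offset = int(sleep_idx[-1]) + 1
    for i in range(sleep_idx.size - 1):
        a, b = int(sleep_idx[i]), int(sleep_idx[i + 1])
        if b - a - 1 >= config.upright_terminate_epochs:
            if _max_zero_run(day.lying[a + 1 : b]) >= config.upright_terminate_epochs:
                offset = a + 1
                break
    if offset - 1 == ne:
        flags.append("truncated_at_night_end")
    return SleepWindow(onset=int(onset), offset=int(offset), flags=tuple(flags))


def detect_bed_window(day: DeviceDay, window: SleepWindow) -> BedWindow:
    """Extend the sleep window through the contiguous lying runs at each end.

    Bedtime is the first minute of the lying run containing the onset
    (the onset itself when that minute is not lying); waketime is one
    past the last minute of the lying run containing the final sleep
    minute.
    """
    ly = day.lying
    bedtime = window.onset
    if ly[bedtime]:
        while bedtime - 1 >= 0 and ly[bedtime - 1]:
            bedtime -= 1
    waketime = window.offset
    if ly[window.offset - 1]:
        n = day.slots_per_day
        while waketime < n and ly[waketime]:
            waketime += 1
    return BedWindow(bedtime=int(bedtime), waketime=int(waketime))


def count_waso_sf(day: DeviceDay, window: SleepWindow) -> tuple[int, int]:
    """Wake after sleep onset (minutes) and sleep fragmentations (wake bouts).

    WASO counts every in-window epoch not classified as sleep; SF counts
    the maximal runs of such epochs (a single wake minute is one
    fragmentation).
    """
    seg = day.sleeping[window.onset : window.offset] == 0
    waso_epochs = int(seg.sum())
    sf = int(np.count_nonzero(np.diff(np.concatenate(([0], seg.view(np.int8)))) == 1))
    return waso_epochs * day.epoch_seconds // 60, sf


def score_day(day: DeviceDay, config: ScoringConfig | None = None) -> Optional[DailyIndices]:
    """Score one noon day into its nightly indices, or ``None`` without sleep.

    Wear-rule enforcement is the caller's job (see :mod:`epochsleep.pipeline`);
    nonwear epochs inside the night are scored as upright wake and flagged.
    """
    config = config or ScoringConfig(epoch_seconds=day.epoch_seconds)
    window = detect_sleep_window(day, config)
    if window is None:
        return None
    bed = detect_bed_window(day, window)
    waso, sf = count_waso_sf(day, window)
    to_min = day.epoch_seconds / 60.0
    span = window.offset - window.onset
    tst = int(span * to_min) - waso
    se = 100.0 * tst / (span * to_min)
    flags = list(window.flags)
    if np.any(day.wearing[bed.bedtime : bed.waketime] == 0):
        flags.append("nonwear_in_tib")
    return DailyIndices(
        subject_id=day.subject_id,
        device_id=day.device_id,
        anchor_date=day.anchor_date,
        is_weekend=day.is_weekend,
        bedtime=int(bed.bedtime * to_min),
        sleep_onset=int(window.onset * to_min),
        sleep_offset=int(window.offset * to_min),
        waketime=int(bed.waketime * to_min),
        midpoint=(window.onset + span / 2.0) * to_min,
        tib=int((bed.waketime - bed.bedtime) * to_min),
        tst=tst,
        se=se,
        sol=int((window.onset - bed.bedtime) * to_min),
        waso=waso,
        sf=sf,
        flags=tuple(flags),
    )
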