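"""Clock-time helpers on the noon-anchored minute axis.

A "noon day" runs from 12:00 to 11:59 the next calendar day so that a
night of sleep is never split across analysis days.  Internally every
clock time is a *slot*: minutes elapsed since the anchoring noon
(slot 0 = 12:00, slot 719 = 23:59, slot 720 = 00:00, slot 1439 = 11:59).
Overnight times are therefore monotone integers, which keeps means,
standard deviations and midpoints free of circular-arithmetic pitfalls.
"""

from __future__ import annotations

MINUTES_PER_DAY = 1440
NOON_MINUTE = 720
#: slot index of midnight (00:00) on the noon-anchored axis
MIDNIGHT_SLOT = 720


def parse_clock(text: str) -> int:
    """Parse ``"HH:MM"`` into minutes since midnight (0..1439)."""
    parts = text.strip().split(":")
    if len(parts) not in (2, 3):
        raise ValueError(f"clock time must be HH:MM, got {text!r}")
    h, m = int(parts[0]), int(parts[1])
    if not (0 <= h < 24 and 0 <= m < 60):
        raise ValueError(f"clock time out of range: {text!r}")
    return h * 60 + m


def clock_to_slot(text: str) -> int:
    """Convert ``"HH:MM"`` to its slot on the noon-anchored axis."""
    return (parse_clock(text) - NOON_MINUTE) % MINUTES_PER_DAY


def slot_to_clock(slot: float) -> str:
    """Format a slot (minutes since noon, may be half-integer) as a clock time.

    Integer slots render as ``HH:MM``; a trailing half minute renders as
    ``HH:MM:30`` so midpoints keep their 0.5-minute precision.
    """
    msm = (float(slot) + NOON_MINUTE) % MINUTES_PER_DAY
    whole = int(msm)
    frac = msm - whole
    h, m = divmod(whole, 60)
    if abs(frac - 0.5) < 1e-9:
        return f"{h:02d}:{m:02d}:30"
    return f"{h:02d}:{m:02d}"


def minutes_to_epochs(minutes: int, epoch_seconds: int) -> int:
    """Convert a threshold given in minutes to a count of epochs.

    Raises if the conversion is not exact; all scoring thresholds must be
    whole numbers of epochs.
    """
    total_seconds = minutes * 60
    if total_seconds % epoch_seconds:
        raise ValueError(
            f"{minutes} min is not a whole number of {epoch_seconds}-s epochs"
        )
    return total_seconds // epoch_seconds
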