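"""Per-subject weekly summaries of nightly sleep indices.

A weekly summary is the mean and sample SD of each nightly index across
a subject's valid nights, produced only when the week itself is valid
(at least two valid weekdays and one valid weekend night).  Sleep
regularity is the sample SD of waketime, in minutes.  Clock-valued
indices are averaged on the minutes-since-noon axis, where overnight
times are monotone, and reported back as clock times.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .scoring import DailyIndices
from .timeutil import slot_to_clock

__all__ = ["VARIABLES", "CLOCK_VARIABLES", "sleep_regularity", "weekly_summary", "weekly_table", "nightly_table"]

#: nightly index columns summarised per subject, in report order
VARIABLES = (
    "bedtime",
    "sleep_onset",
    "sleep_offset",
    "waketime",
    "midpoint",
    "tib",
    "tst",
    "se",
    "sol",
    "waso",
    "sf",
)

#: variables that live on the minutes-since-noon clock axis
CLOCK_VARIABLES = ("bedtime", "sleep_onset", "sleep_offset", "waketime", "midpoint")


class InsufficientDataError(ValueError):
    """Raised when a statistic needs more observations than were given."""


def sleep_regularity(waketimes: Sequence[float]) -> float:
    """Sample SD of waketime (minutes since noon), the regularity index.

    Needs at least two nights; identical waketimes give exactly 0.
    """
    wk = np.asarray(waketimes, dtype=float)
    if wk.size < 2:
        raise InsufficientDataError("sleep regularity needs at least two waketimes")
    return float(np.std(wk, ddof=1))


def nightly_table(nights: Iterable[DailyIndices]) -> pd.DataFrame:
    """Collect scored nights into a tidy frame (one row per subject-night)."""
    rows = [n.as_dict() for n in nights]
    if not rows:
        return pd.DataFrame(
            columns=["subject_id", "device_id", "anchor_date", "is_weekend", *VARIABLES, "flags"]
        )
    return pd.DataFrame(rows)[
        ["subject_id", "device_id", "anchor_date", "is_weekend", *VARIABLES, "flags"]
    ]


def weekly_summary(
    nightly: pd.DataFrame,
    min_weekdays: int = 2,
    min_weekend: int = 1,
) -> Optional[pd.Series]:
    """Summarise one subject-device's nights into weekly mean +/- SD.

    Returns ``None`` when the week rule fails.  The result carries
    ``<var>_mean`` and ``<var>_sd`` for each nightly index plus
    ``regularity`` (SD of waketime, minutes) and ``n_valid_days``.
    """
    if nightly["subject_id"].nunique() > 1 or nightly["device_id"].nunique() > 1:
        raise ValueError("weekly_summary expects nights from a single subject-device")
    n_we = int(nightly["is_weekend"].sum())
    n_wd = len(nightly) - n_we
    if n_wd < min_weekdays or n_we < min_weekend:
        return None
    out: dict[str, object] = {
        "subject_id": nightly["subject_id"].iloc[0],
        "device_id": nightly["device_id"].iloc[0],
        "n_valid_days": len(nightly),
    }
    for var in VARIABLES:
        vals = nightly[var].to_numpy(dtype=float)
        out[f"{var}_mean"] = float(np.mean(vals))
        out[f"{var}_sd"] = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
    out["regularity"] = sleep_regularity(nightly["waketime"].to_numpy(dtype=float))
    return pd.Series(out)


def weekly_table(
    nightly: pd.DataFrame,
    min_weekdays: int = 2,
    min_weekend: int = 1,
) -> pd.DataFrame:
    """Weekly summaries for every subject-device group passing the week rule."""
    rows = []
    for _, grp in nightly.groupby(["subject_id", "device_id"], sort=True):
        summ = weekly_summary(grp, min_weekdays=min_weekdays, min_weekend=min_weekend)
        if summ is not None:
            rows.append(summ)
    if not rows:
        return pd.DataFrame()
    return pd.DataFrame(rows).reset_index(drop=True)


def format_weekly_clocks(weekly: pd.DataFrame) -> pd.DataFrame:
    """Add HH:MM renderings of the clock-valued weekly means for reporting."""
    out = weekly.copy()
    for var in CLOCK_VARIABLES:
        col = f"{var}_mean"
        if col in out.columns:
            out[f"{var}_clock"] = out[col].map(lambda v: slot_to_clock(round(v * 2) / 2))
    return out
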