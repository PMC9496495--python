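"""Reading, aligning and noon-day slicing of minute-level epoch data.

Input is one delimited-text file per subject-device: one row per epoch
with a timestamp, a binary lying-down indicator, a binary sleep
indicator and an optional binary wear indicator.  Rows missing from the
stream are treated as nonwear.  Analysis days run noon-to-noon; a day is
valid when it reaches the configured wear-time minimum (default 1361
minutes, i.e. 95% of a day), and a week is valid when it contains at
least two valid weekdays and one valid weekend day.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import warnings
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .timeutil import MINUTES_PER_DAY

__all__ = [
    "EpochInputError",
    "EpochSeries",
    "DeviceDay",
    "read_epoch_csv",
    "write_epoch_csv",
    "assign_noon_days",
    "validate_day",
    "validate_week",
    "align_two_devices",
    "MIN_WEAR_MINUTES",
]

#: default valid-day wear threshold: 95% of 1440 minutes
MIN_WEAR_MINUTES = 1361

CANONICAL_COLUMNS = ("subject_id", "device_id", "timestamp", "lying", "sleeping", "wearing")


class EpochInputError(ValueError):
    """Raised for malformed epoch input (bad timestamps, duplicates, non-binary values)."""


@dataclasses.dataclass
class EpochSeries:
    """One subject-device stream of epoch records, sorted by time."""

    subject_id: str
    device_id: str
    epoch_seconds: int
    data: pd.DataFrame  # columns: timestamp, lying, sleeping, wearing

    def __len__(self) -> int:
        return len(self.data)

    def equals(self, other: "EpochSeries") -> bool:
        return (
            self.subject_id == other.subject_id
            and self.device_id == other.device_id
            and self.epoch_seconds == other.epoch_seconds
            and self.data.reset_index(drop=True).equals(other.data.reset_index(drop=True))
        )


@dataclasses.dataclass
class DeviceDay:
    """A noon-to-noon slice of an epoch stream.

    Slot ``k`` is ``k`` epochs after 12:00 on ``anchor_date``; with
    60-second epochs slot 0 = 12:00 and slot 1439 = 11:59 the next
    calendar day.  Slots with no record, and recorded slots with
    ``wearing = 0``, expose ``lying = sleeping = 0``: nonwear is not
    interpretable and is scored as upright wake.
    """

    subject_id: str
    device_id: str
    anchor_date: _dt.date
    lying: np.ndarray
    sleeping: np.ndarray
    wearing: np.ndarray
    epoch_seconds: int = 60
    is_valid: bool | None = None
    flags: tuple[str, ...] = ()

    @property
    def slots_per_day(self) -> int:
        return len(self.lying)

    @property
    def wear_minutes(self) -> int:
        return int(self.wearing.sum()) * self.epoch_seconds // 60

    @property
    def is_weekend(self) -> bool:
        return self.anchor_date.weekday() >= 5


def _default_column_map(columns: Sequence[str]) -> dict:
    mapping = {}
    for key in ("timestamp", "lying", "sleeping", "wearing"):
        if key in columns:
            mapping[key] = key
    return mapping


def read_epoch_csv(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    epoch_seconds: int = 60,
    subject_id: str | None = None,
    device_id: str | None = None,
) -> EpochSeries:
    """Read one subject-device epoch stream from a delimited-text file.

    Parameters
    ----------
    path
        CSV file with a header row.
    column_map
        Maps the canonical keys ``timestamp``, ``lying``, ``sleeping`` and
        optionally ``wearing`` to the file's column names.  When omitted,
        canonical names are expected in the file.
    epoch_seconds
        Fixed epoch length; timestamps must fall on this grid.
    subject_id, device_id
        Override or supply identifiers; otherwise taken from ``subject_id``
        / ``device_id`` columns when present (which must be constant).
    """
    path = Path(path)
    raw = pd.read_csv(path)
    cmap = dict(column_map) if column_map else _default_column_map(raw.columns)
    for key in ("timestamp", "lying", "sleeping"):
        if key not in cmap or cmap[key] not in raw.columns:
            raise EpochInputError(f"{path}: required column {key!r} not found (map: {cmap})")

    ts = pd.to_datetime(raw[cmap["timestamp"]], errors="coerce")
    if ts.isna().any():
        row = int(np.flatnonzero(ts.isna().to_numpy())[0])
        raise EpochInputError(
            f"{path}: unparseable timestamp at row {row}: {raw[cmap['timestamp']].iloc[row]!r}"
        )

    out = pd.DataFrame({"timestamp": ts})
    for key in ("lying", "sleeping"):
        out[key] = _as_binary(raw[cmap[key]], key, path)
    if "wearing" in cmap and cmap["wearing"] in raw.columns:
        out["wearing"] = _as_binary(raw[cmap["wearing"]], "wearing", path)
    else:
        out["wearing"] = np.int8(1)

    out = out.sort_values("timestamp", kind="stable").reset_index(drop=True)
    dup = out["timestamp"].duplicated()
    if dup.any():
        first = out.loc[dup, "timestamp"].iloc[0]
        raise EpochInputError(f"{path}: duplicate timestamp {first}")

    # timestamps must sit on the epoch grid (minute grid for 60-s epochs)
    sec = out["timestamp"].dt.second.to_numpy() + out["timestamp"].dt.microsecond.to_numpy() / 1e6
    offsets = (out["timestamp"].dt.minute.to_numpy() * 60 + sec) % epoch_seconds
    if np.any(offsets != 0):
        row = int(np.flatnonzero(offsets != 0)[0])
        raise EpochInputError(
            f"{path}: timestamp at row {row} not aligned to {epoch_seconds}-s epochs"
        )

    n_bad = int(((out["sleeping"] == 1) & (out["wearing"] == 0)).sum())
    if n_bad:
        warnings.warn(
            f"{path}: {n_bad} epochs record sleep while not worn; "
            "these are treated as nonwear",
            stacklevel=2,
        )

    if subject_id is None:
        subject_id = _constant_id(raw, "subject_id", path, default="S1")
    if device_id is None:
        device_id = _constant_id(raw, "device_id", path, default="D1")
    return EpochSeries(subject_id=subject_id, device_id=device_id,
                       epoch_seconds=epoch_seconds, data=out)


def _as_binary(col: pd.Series, name: str, path: Path) -> np.ndarray:
    vals = pd.to_numeric(col, errors="coerce")
    ok = vals.isin([0, 1])
    if not ok.all():
        row = int(np.flatnonzero(~ok.to_numpy())[0])
        raise EpochInputError(f"{path}: non-binary value {col.iloc[row]!r} in column {name!r} at row {row}")
    return vals.to_numpy(dtype=np.int8)


def _constant_id(raw: pd.DataFrame, col: str, path: Path, default: str) -> str:
    if col in raw.columns:
        uniq = raw[col].astype(str).unique()
        if len(uniq) != 1:
            raise EpochInputError(f"{path}: column {col!r} must be constant within one file")
        return str(uniq[0])
    return default


def write_epoch_csv(series: EpochSeries, path: str | Path) -> None:
    """Write a stream in the canonical epoch CSV layout (ISO-8601 minute timestamps)."""
    df = series.data.copy()
    df.insert(0, "subject_id", series.subject_id)
    df.insert(1, "device_id", series.device_id)
    df["timestamp"] = df["timestamp"].dt.strftime("%Y-%m-%dT%H:%M")
    df.to_csv(path, index=False, columns=list(CANONICAL_COLUMNS))


def assign_noon_days(series: EpochSeries) -> list[DeviceDay]:
    """Partition a stream into noon-anchored days.

    Every record lands in exactly one day: a record at 11:59 belongs to
    the day anchored at the previous day's noon, a record at 12:00 starts
    a new day.  Slots with no record become nonwear.
    """
    if len(series) == 0:
        raise EpochInputError("cannot slice an empty series into days")
    spd = 86400 // series.epoch_seconds
    ts = series.data["timestamp"]
    anchor = (ts - pd.Timedelta(hours=12)).dt.normalize()
    slot = ((ts - (anchor + pd.Timedelta(hours=12))).dt.total_seconds() // series.epoch_seconds).astype(int)

    days: list[DeviceDay] = []
    lying = series.data["lying"].to_numpy(np.int8)
    sleeping = series.data["sleeping"].to_numpy(np.int8)
    wearing = series.data["wearing"].to_numpy(np.int8)
    anchor_dates = anchor.dt.date.to_numpy()
    slots = slot.to_numpy()
    for anc in sorted(set(anchor_dates)):
        pos = np.flatnonzero(anchor_dates == anc)
        sl = slots[pos]
        day = DeviceDay(
            subject_id=series.subject_id,
            device_id=series.device_id,
            anchor_date=anc,
            lying=np.zeros(spd, np.int8),
            sleeping=np.zeros(spd, np.int8),
            wearing=np.zeros(spd, np.int8),
            epoch_seconds=series.epoch_seconds,
        )
        worn = wearing[pos] == 1
        day.wearing[sl[worn]] = 1
        day.lying[sl[worn]] = lying[pos][worn]
        day.sleeping[sl[worn]] = sleeping[pos][worn]
        days.append(day)
    return days


def validate_day(day: DeviceDay, min_wear: int = MIN_WEAR_MINUTES) -> bool:
    """Apply the wear-time validity rule (default >= 1361 min/day) and record it."""
    day.is_valid = day.wear_minutes >= min_wear
    return day.is_valid


def validate_week(days: Sequence[DeviceDay], min_weekdays: int = 2, min_weekend: int = 1) -> bool:
    """True iff the valid days include >= ``min_weekdays`` weekdays and >= ``min_weekend`` weekend days."""
    n_wd = sum(1 for d in days if d.is_valid and not d.is_weekend)
    n_we = sum(1 for d in days if d.is_valid and d.is_weekend)
    return n_wd >= min_weekdays and n_we >= min_weekend


def align_two_devices(
    a: EpochSeries,
    b: EpochSeries,
    min_wear: int = MIN_WEAR_MINUTES,
) -> pd.DataFrame:
    """Intersect two streams into a paired epoch table.

    Rows are timestamps worn on both devices, restricted to noon days
    that pass the wear rule on *both* devices.  Columns:
    ``subject_id, timestamp, lying_a, sleeping_a, lying_b, sleeping_b``.
    """
    if a.epoch_seconds != b.epoch_seconds:
        raise EpochInputError(
            f"epoch length mismatch: {a.epoch_seconds}s vs {b.epoch_seconds}s"
        )
    if a.subject_id != b.subject_id:
        raise EpochInputError(
            f"paired streams must share a subject: {a.subject_id!r} vs {b.subject_id!r}"
        )
    valid_anchors = []
    for series in (a, b):
        days = assign_noon_days(series)
        valid_anchors.append({d.anchor_date for d in days if validate_day(d, min_wear)})
    shared_anchors = valid_anchors[0] & valid_anchors[1]

    left = a.data.rename(columns={"lying": "lying_a", "sleeping": "sleeping_a", "wearing": "wearing_a"})
    right = b.data.rename(columns={"lying": "lying_b", "sleeping": "sleeping_b", "wearing": "wearing_b"})
    merged = left.merge(right, on="timestamp", how="inner")
    merged = merged[(merged["wearing_a"] == 1) & (merged["wearing_b"] == 1)]
    anchor = (merged["timestamp"] - pd.Timedelta(hours=12)).dt.date
    merged = merged[anchor.isin(shared_anchors)]
    merged.insert(0, "subject_id", a.subject_id)
    return merged[
        ["subject_id", "timestamp", "lying_a", "sleeping_a", "lying_b", "sleeping_b"]
    ].reset_index(drop=True)
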