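"""End-to-end orchestration: streams -> nightly -> weekly -> agreement report."""

from __future__ import annotations

import logging
from typing import Mapping, Optional, Sequence

import pandas as pd

from . import agreement
from .epoch_io import (
    MIN_WEAR_MINUTES,
    EpochSeries,
    align_two_devices,
    assign_noon_days,
    validate_day,
)
from .scoring import DailyIndices, ScoringConfig, score_day
from .summaries import nightly_table, weekly_table

log = logging.getLogger("epochsleep")

__all__ = ["score_series", "score_streams", "compare_devices"]


def score_series(
    series: EpochSeries,
    config: Optional[ScoringConfig] = None,
    min_wear: int = MIN_WEAR_MINUTES,
) -> list[DailyIndices]:
    """Score every valid noon day of one stream; invalid days are dropped."""
    config = config or ScoringConfig(epoch_seconds=series.epoch_seconds)
    nights = []
    for day in assign_noon_days(series):
        if not validate_day(day, min_wear):
            log.info("%s/%s %s: invalid day (wear %d < %d min)", day.subject_id,
                     day.device_id, day.anchor_date, day.wear_minutes, min_wear)
            continue
        indices = score_day(day, config)
        if indices is None:
            log.info("%s/%s %s: no sleep window found", day.subject_id,
                     day.device_id, day.anchor_date)
            continue
        nights.append(indices)
    return nights


def score_streams(
    streams: Mapping[str, EpochSeries] | Sequence[EpochSeries],
    config: Optional[ScoringConfig] = None,
    min_wear: int = MIN_WEAR_MINUTES,
) -> pd.DataFrame:
    """Nightly table across a collection of subject streams."""
    if isinstance(streams, Mapping):
        streams = list(streams.values())
    nights: list[DailyIndices] = []
    for series in streams:
        nights.extend(score_series(series, config, min_wear))
    return nightly_table(nights)


def compare_devices(
    nightly_a: pd.DataFrame,
    nightly_b: pd.DataFrame,
    paired_epochs: Optional[pd.DataFrame] = None,
    margins: Optional[dict[str, float]] = None,
    reference: str = "a",
    min_weekdays: int = 2,
    min_weekend: int = 1,
    alpha: float = 0.05,
) -> dict:
    """Full agreement report between two devices' nightly tables.

    Equivalence (TOST) runs on per-subject weekly summaries; intraclass
    correlations and Bland-Altman statistics run on matched person-days,
    variable by variable; epoch confusion metrics are computed when the
    paired epoch table is supplied.  Device A minus device B throughout;
    ``reference`` names the criterion device for confusion metrics.
    """
    merged = nightly_a.merge(
        nightly_b, on=["subject_id", "anchor_date"], suffixes=("_a", "_b")
    )
    if merged.empty:
        missing = sorted(
            set(nightly_a["subject_id"]).symmetric_difference(nightly_b["subject_id"])
        )
        raise ValueError(
            f"no overlapping subject-days between devices; unmatched subjects: {missing}"
        )

    weekly_a = weekly_table(nightly_a, min_weekdays, min_weekend)
    weekly_b = weekly_table(nightly_b, min_weekdays, min_weekend)
    shared = set(weekly_a.get("subject_id", pd.Series(dtype=str))) & set(
        weekly_b.get("subject_id", pd.Series(dtype=str))
    )
    report: dict = {"n_person_days": len(merged), "n_weekly_subjects": len(shared)}

    if shared:
        report["equivalence"] = agreement.equivalence_table(
            weekly_a[weekly_a["subject_id"].isin(shared)],
            weekly_b[weekly_b["subject_id"].isin(shared)],
            margins=margins,
            alpha=alpha,
        )

    icc_rows, ba_rows, ba_points = [], [], []
    for var in (
        "bedtime", "sleep_onset", "sleep_offset", "waketime", "midpoint",
        "tib", "tst", "se", "sol", "waso", "sf",
    ):
        pairs = merged[["subject_id", f"{var}_a", f"{var}_b"]].rename(
            columns={f"{var}_a": "a", f"{var}_b": "b"}
        )
        icc = agreement.icc_shrout_fleiss(pairs[["a", "b"]].to_numpy())
        icc_rows.append({"variable": var, "icc_2_1": icc.icc_2_1, "icc_3_1": icc.icc_3_1})
        if pairs["subject_id"].nunique() >= 2:
            ba = agreement.bland_altman_rm(pairs)
            ba_rows.append({
                "variable": var, "bias": ba.bias, "loa_low": ba.loa_low,
                "loa_high": ba.loa_high, "slope": ba.slope,
                "slope_ci_low": ba.slope_ci[0], "slope_ci_high": ba.slope_ci[1],
                "slope_p": ba.slope_p,
            })
        pts = pairs.copy()
        pts["mean"] = (pts["a"] + pts["b"]) / 2.0
        pts["diff"] = pts["a"] - pts["b"]
        pts.insert(0, "variable", var)
        ba_points.append(pts[["variable", "subject_id", "mean", "diff"]])
    report["icc"] = pd.DataFrame(icc_rows)
    report["bland_altman"] = pd.DataFrame(ba_rows)
    report["bland_altman_points"] = pd.concat(ba_points, ignore_index=True)

    if paired_epochs is not None and not paired_epochs.empty:
        report["confusion"] = agreement.epoch_confusion(paired_epochs, reference=reference)
    return report


def build_paired_epochs(
    streams_a: Mapping[str, EpochSeries],
    streams_b: Mapping[str, EpochSeries],
    min_wear: int = MIN_WEAR_MINUTES,
) -> pd.DataFrame:
    """Concatenate per-subject aligned epoch tables across a study."""
    frames = []
    for sid in sorted(set(streams_a) & set(streams_b)):
        frames.append(align_two_devices(streams_a[sid], streams_b[sid], min_wear))
    if not frames:
        return pd.DataFrame()
    return pd.concat(frames, ignore_index=True)
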