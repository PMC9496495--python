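"""Synthetic two-device epoch streams with known ground truth.

The generator emulates the design of a free-living wearable validation
study: a cohort of adults (default 30) wears two imperfect devices for
seven consecutive noon-to-noon days while a latent true sleep process
unfolds each night.  Per subject-night the truth process draws a
bedtime and waketime (defaults 22:44 +/- 60 min and 06:46 +/- 62 min,
typical self-reported values in middle-aged adults), a sleep onset
latency, a handful of nocturnal awakenings, and a short lying-awake
tail before rising.  The truth table records exactly the indices
implied by the generated epochs, so scoring a noiseless stream must
reproduce it night by night.

Device observation error is independent Bernoulli epoch
misclassification: a true-sleep epoch is recorded as sleep with
probability ``sleep_detect_prob`` and a true-wake epoch as wake with
probability ``wake_detect_prob`` (defaults 0.94 / 0.88, typical
sensitivity/specificity of consumer sleep wearables), plus integer
jitter on the boundaries of lying runs and an optional constant shift
of the nightly sleep end (to inject a systematic offset/waketime bias).
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .epoch_io import EpochSeries, write_epoch_csv
from .timeutil import MIDNIGHT_SLOT, MINUTES_PER_DAY, clock_to_slot

__all__ = ["TruthParams", "DeviceModel", "simulate_truth", "apply_device_model", "simulate_study"]

_NIGHT_START_SLOT = clock_to_slot("19:00")   # 420
_NIGHT_END_SLOT = clock_to_slot("11:59")     # 1439


@dataclasses.dataclass(frozen=True)
class TruthParams:
    """Parameters of the latent true sleep process.

    Clock parameters are ``"HH:MM"`` strings; scales are minutes.  The
    defaults describe a 30-subject, 7-night study of adults going to bed
    around 22:44 +/- 60 min and rising around 06:46 +/- 62 min, with a
    ~14-min onset latency, about ten awakenings per night of ~5 min
    each (so WASO near 50 min), a short lying-awake tail before rising,
    and half an hour of daytime nonwear.
    """

    n_subjects: int = 30
    n_days: int = 7
    bedtime_mean: str = "22:44"
    bedtime_sd: float = 60.0
    waketime_mean: str = "06:46"
    waketime_sd: float = 62.0
    sol_mean: float = 14.0
    n_awakenings_mean: float = 10.0
    awakening_len_mean: float = 5.0
    terminal_wake_mean: float = 5.0
    nonwear_rate: float = 30.0
    start_date: str = "2024-01-01"   # a Monday: 7 days give 5 weekdays + 2 weekend days
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("bedtime_sd", "waketime_sd", "sol_mean", "n_awakenings_mean",
                     "awakening_len_mean", "terminal_wake_mean", "nonwear_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclasses.dataclass(frozen=True)
class DeviceModel:
    """Observation-error model of one device.

    ``sleep_detect_prob`` is the per-epoch probability that true sleep
    is recorded as sleep (target sensitivity); ``wake_detect_prob`` the
    probability that true wake is recorded as wake (target specificity).
    ``lying_jitter_minutes`` bounds a uniform integer shift applied to
    each lying-run boundary; ``offset_shift_minutes`` extends (or
    shrinks) every night's sleep end by a constant, injecting a
    systematic sleep-offset / waketime bias.
    """

    sleep_detect_prob: float = 0.94
    wake_detect_prob: float = 0.88
    lying_jitter_minutes: int = 0
    offset_shift_minutes: int = 0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        for p in (self.sleep_detect_prob, self.wake_detect_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("detection probabilities must lie in [0, 1]")


def _geometric(rng: np.random.Generator, mean: float, size=None, minimum: int = 1):
    """Integer draws with the given mean, support >= ``minimum``."""
    excess = mean - minimum
    if excess <= 0:
        return np.full(size if size is not None else (), minimum, dtype=int)
    p = 1.0 / (excess + 1.0)
    return rng.geometric(p, size=size) - 1 + minimum


def _draw_night(rng: np.random.Generator, p: TruthParams) -> dict:
    """Draw one night's truth schedule, in slots since noon."""
    bed_mu = clock_to_slot(p.bedtime_mean)
    wake_mu = clock_to_slot(p.waketime_mean)
    for _ in range(100):
        bed = int(round(rng.normal(bed_mu, p.bedtime_sd)))
        wake = int(round(rng.normal(wake_mu, p.waketime_sd)))
        sol = int(_geometric(rng, p.sol_mean, minimum=0))
        tail = int(_geometric(rng, p.terminal_wake_mean, minimum=0))
        onset = bed + sol
        offset = wake - tail
        if (
            _NIGHT_START_SLOT < bed
            and MIDNIGHT_SLOT < wake < _NIGHT_END_SLOT
            and offset > MIDNIGHT_SLOT
            and offset - onset >= 120
        ):
            return {"bed": bed, "wake": wake, "onset": onset, "offset": offset}
    raise RuntimeError("could not draw a consistent night in 100 attempts; check parameters")


def _place_awakenings(rng: np.random.Generator, p: TruthParams, night: dict) -> np.ndarray:
    """Build the in-window wake mask, respecting the scorer's night rules.

    The first and last sleep epochs stay asleep; wake bouts that start
    before midnight are capped just below the 10-min onset-reset
    threshold, and the midnight epoch is kept asleep when onset precedes
    midnight, so the generated truth is exactly what the scorer reports.
    """
    onset, offset = night["onset"], night["offset"]
    mask = np.zeros(MINUTES_PER_DAY, dtype=bool)
    lo, hi = onset + 1, offset - 2
    if hi >= lo:
        n_bouts = rng.poisson(p.n_awakenings_mean)
        if n_bouts:
            starts = rng.integers(lo, hi + 1, size=n_bouts)
            lengths = _geometric(rng, p.awakening_len_mean, size=n_bouts, minimum=1)
            for s, L in zip(starts, lengths):
                mask[s : min(s + int(L), hi + 1)] = True
    # enforce scorer-consistency constraints
    if onset < MIDNIGHT_SLOT:
        mask[MIDNIGHT_SLOT] = False
        # cap pre-midnight wake runs below the onset-reset threshold
        runs = _runs(mask)
        for s, e in runs:
            if s < MIDNIGHT_SLOT and e - s >= 10:
                mask[s + 9 : e] = False
    mask[onset] = False
    mask[offset - 1] = False
    return mask


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, end) spans of the True runs."""
    padded = np.concatenate(([False], mask, [False]))
    changes = np.flatnonzero(padded[1:] != padded[:-1])
    return list(zip(changes[0::2], changes[1::2]))


def simulate_truth(params: TruthParams) -> tuple[dict[str, EpochSeries], pd.DataFrame]:
    """Generate noiseless truth streams and their exact nightly indices.

    Returns one ``EpochSeries`` per subject (device id ``"TRUTH"``)
    covering ``n_days`` noon days, plus a truth table with the same
    columns as the scorer's nightly output.
    """
    rng = np.random.default_rng(params.seed)
    start = _dt.date.fromisoformat(params.start_date)
    streams: dict[str, EpochSeries] = {}
    truth_rows = []
    for si in range(params.n_subjects):
        sid = f"S{si + 1:02d}"
        lying = np.zeros(params.n_days * MINUTES_PER_DAY, np.int8)
        sleeping = np.zeros_like(lying)
        wearing = np.ones_like(lying)
        for di in range(params.n_days):
            anchor = start + _dt.timedelta(days=di)
            night = _draw_night(rng, params)
            wake_mask = _place_awakenings(rng, params, night)
            base = di * MINUTES_PER_DAY
            bed, wake = night["bed"], night["wake"]
            onset, offset = night["onset"], night["offset"]
            lying[base + bed : base + wake] = 1
            asleep = np.zeros(MINUTES_PER_DAY, dtype=bool)
            asleep[onset:offset] = True
            asleep[wake_mask] = False
            sleeping[base : base + MINUTES_PER_DAY] = asleep.view(np.int8)
            if params.nonwear_rate > 0:
                nw = int(round(params.nonwear_rate))
                nw_start = int(rng.integers(0, _NIGHT_START_SLOT - nw)) if nw < _NIGHT_START_SLOT else 0
                wearing[base + nw_start : base + nw_start + nw] = 0
            in_window = wake_mask[onset:offset]
            waso = int(in_window.sum())
            sf = len(_runs(in_window))
            span = offset - onset
            truth_rows.append({
                "subject_id": sid,
                "device_id": "TRUTH",
                "anchor_date": anchor,
                "is_weekend": anchor.weekday() >= 5,
                "bedtime": bed,
                "sleep_onset": onset,
                "sleep_offset": offset,
                "waketime": wake,
                "midpoint": onset + span / 2.0,
                "tib": wake - bed,
                "tst": span - waso,
                "se": 100.0 * (span - waso) / span,
                "sol": onset - bed,
                "waso": waso,
                "sf": sf,
            })
        t0 = pd.Timestamp(start) + pd.Timedelta(hours=12)
        timestamps = pd.date_range(t0, periods=len(lying), freq="min")
        streams[sid] = EpochSeries(
            subject_id=sid,
            device_id="TRUTH",
            epoch_seconds=60,
            data=pd.DataFrame({
                "timestamp": timestamps,
                "lying": lying,
                "sleeping": sleeping,
                "wearing": wearing,
            }),
        )
    return streams, pd.DataFrame(truth_rows)


def apply_device_model(
    truth: EpochSeries,
    model: DeviceModel,
    device_id: str = "DEV",
    rng: Optional[np.random.Generator] = None,
) -> EpochSeries:
    """Overlay observation error on a truth stream.

    Applies, in order: the constant nightly sleep-end shift, Bernoulli
    sleep/wake misclassification on every epoch, and uniform integer
    jitter on lying-run boundaries.  Wearing is copied unchanged.
    """
    if rng is None:
        rng = np.random.default_rng(model.seed)
    lying = truth.data["lying"].to_numpy(np.int8).copy()
    sleeping = truth.data["sleeping"].to_numpy(np.int8).copy()
    wearing = truth.data["wearing"].to_numpy(np.int8)

    if model.offset_shift_minutes:
        s = model.offset_shift_minutes
        for start, end in _runs(lying.astype(bool)):
            new_end = int(np.clip(end + s, start + 1, len(lying)))
            if s > 0:
                lying[end:new_end] = 1
                sleeping[end:new_end] = 1
            else:
                lying[new_end:end] = 0
                sleeping[new_end:end] = 0

    is_sleep = sleeping == 1
    u = rng.random(len(sleeping))
    observed = np.where(
        is_sleep,
        (u < model.sleep_detect_prob),
        ~(u < model.wake_detect_prob),
    ).astype(np.int8)

    if model.lying_jitter_minutes:
        j = model.lying_jitter_minutes
        jittered = np.zeros_like(lying)
        for start, end in _runs(lying.astype(bool)):
            ns = int(np.clip(start + rng.integers(-j, j + 1), 0, len(lying)))
            ne = int(np.clip(end + rng.integers(-j, j + 1), ns + 1, len(lying)))
            jittered[ns:ne] = 1
        lying = jittered

    data = pd.DataFrame({
        "timestamp": truth.data["timestamp"],
        "lying": lying,
        "sleeping": observed,
        "wearing": wearing,
    })
    return EpochSeries(subject_id=truth.subject_id, device_id=device_id,
                       epoch_seconds=truth.epoch_seconds, data=data)


def simulate_study(
    truth_params: TruthParams,
    model_a: DeviceModel,
    model_b: DeviceModel,
    outdir: Optional[str | Path] = None,
) -> dict:
    """Simulate a full two-device study.

    Returns a dict with ``truth_streams``, ``truth_indices``, and per-
    device stream dicts ``device_a`` / ``device_b``.  When ``outdir`` is
    given, writes ``deviceA.csv``, ``deviceB.csv`` (canonical epoch
    format, all subjects concatenated), ``truth_indices.csv`` and
    ``params.json`` with the full provenance including seeds.
    """
    truth_streams, truth_indices = simulate_truth(truth_params)
    ss = np.random.SeedSequence(truth_params.seed)
    seed_a, seed_b = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2))
    rng_a = np.random.default_rng(model_a.seed if model_a.seed is not None else seed_a)
    rng_b = np.random.default_rng(model_b.seed if model_b.seed is not None else seed_b)
    device_a = {sid: apply_device_model(s, model_a, "A", rng_a) for sid, s in truth_streams.items()}
    device_b = {sid: apply_device_model(s, model_b, "B", rng_b) for sid, s in truth_streams.items()}
    bundle = {
        "truth_streams": truth_streams,
        "truth_indices": truth_indices,
        "device_a": device_a,
        "device_b": device_b,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        _write_streams(device_a, outdir / "deviceA.csv")
        _write_streams(device_b, outdir / "deviceB.csv")
        truth_indices.to_csv(outdir / "truth_indices.csv", index=False)
        provenance = {
            "truth_params": dataclasses.asdict(truth_params),
            "device_a": {**dataclasses.asdict(model_a), "effective_seed": seed_a},
            "device_b": {**dataclasses.asdict(model_b), "effective_seed": seed_b},
        }
        (outdir / "params.json").write_text(json.dumps(provenance, indent=2))
    return bundle


def _write_streams(streams: dict[str, EpochSeries], path: Path) -> None:
    frames = []
    for sid in sorted(streams):
        s = streams[sid]
        df = s.data.copy()
        df.insert(0, "subject_id", s.subject_id)
        df.insert(1, "device_id", s.device_id)
        df["timestamp"] = df["timestamp"].dt.strftime("%Y-%m-%dT%H:%M")
        frames.append(df)
    pd.concat(frames).to_csv(path, index=False)
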