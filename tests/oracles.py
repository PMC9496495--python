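"""Independent brute-force reference implementations used as test oracles.

Everything here is written as plain forward scans and explicit
enumeration, deliberately sharing no code with the package, so that
agreement between the two routes is evidence of correctness.
"""

from __future__ import annotations

import itertools

import numpy as np


def reference_score_night(
    lying,
    sleeping,
    night_start: int = 420,
    night_end: int = 1439,
    midnight: int = 720,
    wake_reset: int = 10,
    upright: int = 90,
):
    """Literal forward-scan scorer for one noon day; returns a dict or None.

    Rules: onset at the first lying+sleeping night minute; every >= 10-min
    wake bout before midnight pushes the onset to the next sleep minute;
    awake at midnight means onset is the first sleep minute after it; the
    window closes after the last sleep minute followed by >= 90 consecutive
    upright minutes (before any further sleep) or at the night end.
    """
    lying = [bool(v) for v in lying]
    sleeping = [bool(v) for v in sleeping]

    onset = None
    for k in range(night_start, night_end + 1):
        if lying[k] and sleeping[k]:
            onset = k
            break

    if onset is not None:
        k = onset
        while k < midnight:
            if sleeping[k]:
                k += 1
                continue
            j = k  # start of a wake bout before midnight
            while j <= night_end and not sleeping[j]:
                j += 1
            if j > night_end:
                break  # no sleep again this night
            if j - k >= wake_reset:
                onset = j
            k = j

    if not sleeping[midnight]:
        onset = None
        for k in range(midnight + 1, night_end + 1):
            if sleeping[k]:
                onset = k
                break
        if onset is None:
            return None
    elif onset is None:
        return None

    sleep_slots = [k for k in range(onset, night_end + 1) if sleeping[k]]
    offset = sleep_slots[-1] + 1
    for a, b in zip(sleep_slots, sleep_slots[1:]):
        run = best = 0
        for k in range(a + 1, b):
            if not lying[k]:
                run += 1
                best = max(best, run)
            else:
                run = 0
        if best >= upright:
            offset = a + 1
            break

    bedtime = onset
    if lying[onset]:
        while bedtime - 1 >= 0 and lying[bedtime - 1]:
            bedtime -= 1
    waketime = offset
    if lying[offset - 1]:
        while waketime < len(lying) and lying[waketime]:
            waketime += 1

    waso = 0
    sf = 0
    in_wake = False
    for k in range(onset, offset):
        if not sleeping[k]:
            waso += 1
            if not in_wake:
                sf += 1
            in_wake = True
        else:
            in_wake = False

    span = offset - onset
    return {
        "bedtime": bedtime,
        "sleep_onset": onset,
        "sleep_offset": offset,
        "waketime": waketime,
        "midpoint": onset + span / 2.0,
        "tib": waketime - bedtime,
        "tst": span - waso,
        "se": 100.0 * (span - waso) / span,
        "sol": onset - bedtime,
        "waso": waso,
        "sf": sf,
    }


def wilcoxon_exact_p(values, alternative: str) -> float:
    """One-sided signed-rank p by full enumeration of sign assignments.

    Zeros dropped, midranks for ties; the exact permutation distribution
    of the observed absolute values.
    """
    x = [v for v in values if v != 0]
    n = len(x)
    if n == 0:
        return 1.0
    absx = sorted((abs(v), i) for i, v in enumerate(x))
    ranks = [0.0] * n
    i = 0
    pos = 1
    while i < n:
        j = i
        while j + 1 < n and absx[j + 1][0] == absx[i][0]:
            j += 1
        mid = (pos + (pos + (j - i))) / 2.0
        for t in range(i, j + 1):
            ranks[absx[t][1]] = mid
        pos += j - i + 1
        i = j + 1
    w_obs = sum(r for v, r in zip(x, ranks) if v > 0)
    count = total = 0
    for signs in itertools.product((0, 1), repeat=n):
        w = sum(r for s, r in zip(signs, ranks) if s)
        total += 1
        if alternative == "greater" and w >= w_obs - 1e-12:
            count += 1
        elif alternative == "less" and w <= w_obs + 1e-12:
            count += 1
    return count / total


def icc_two_way(table) -> tuple[float, float]:
    """Spreadsheet-style two-way ANOVA ICC(2,1) and ICC(3,1) for an n x k table."""
    table = [list(map(float, row)) for row in table]
    n = len(table)
    k = len(table[0])
    grand = sum(sum(r) for r in table) / (n * k)
    row_means = [sum(r) / k for r in table]
    col_means = [sum(table[i][j] for i in range(n)) / n for j in range(k)]
    ss_rows = k * sum((m - grand) ** 2 for m in row_means)
    ss_cols = n * sum((m - grand) ** 2 for m in col_means)
    ss_tot = sum((table[i][j] - grand) ** 2 for i in range(n) for j in range(k))
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = (ss_tot - ss_rows - ss_cols) / ((n - 1) * (k - 1))
    icc21 = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    icc31 = (msr - mse) / (msr + (k - 1) * mse)
    return icc21, icc31


def random_night(rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """A random lying/sleeping night with mixed bout lengths and stray flips."""
    lying = np.zeros(1440, np.int8)
    sleeping = np.zeros(1440, np.int8)
    for _ in range(int(rng.integers(1, 4))):
        start = int(rng.integers(360, 1380))
        end = min(start + int(rng.integers(30, 700)), 1440)
        lying[start:end] = 1
        t = start
        while t < end:
            t += int(rng.integers(0, 30))      # wake gap
            s_len = int(rng.integers(1, 300))  # sleep bout
            sleeping[t : min(t + s_len, end)] = 1
            t += s_len
    flip_sleep = rng.random(1440) < 0.004
    flip_lying = rng.random(1440) < 0.003
    sleeping[flip_sleep] ^= 1
    lying[flip_lying] ^= 1
    return lying, sleeping
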