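"""Actigraphic sleep/wake scoring and per-night sleep parameters.

Scoring uses the classical 1-min weighted-window discriminant of the
Cole–Kripke family: a 7-epoch moving sum of rescaled activity counts,

    D_t = 0.001·(106·a_{t−4} + 54·a_{t−3} + 58·a_{t−2} + 76·a_{t−1}
                 + 230·a_t + 74·a_{t+1} + 67·a_{t+2}),

with an epoch scored *sleep* iff D_t < 1.  The published coefficients were
derived for wrist counts of a specific magnitude, so raw device counts (PIM
here) are divided by a configurable ``scale`` first.

Nights are anchored on diary rest intervals (bedtime/waketime markers); the
summary reports bedtime, wake time, time in bed, sleep onset (first run of
``onset_rule`` consecutive sleep minutes), latency, total sleep time, sleep
efficiency, WASO, and sleep phase (clock midpoint of bedtime and waketime).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ParameterError, ResolutionError
from .io import EpochSeries

#: published 1-min-epoch weights for a_{t-4} ... a_{t+2}
COLE_WEIGHTS = np.array([106.0, 54.0, 58.0, 76.0, 230.0, 74.0, 67.0])
COLE_FACTOR = 0.001


@dataclass
class RestInterval:
    """A diary- or config-derived in-bed interval."""

    bedtime: pd.Timestamp
    waketime: pd.Timestamp
    source: str = "diary_event"  # {"diary_event", "config_default"}

    def __post_init__(self) -> None:
        self.bedtime = pd.Timestamp(self.bedtime)
        self.waketime = pd.Timestamp(self.waketime)
        if not self.waketime > self.bedtime:
            raise ParameterError("waketime must be after bedtime")
        if self.waketime - self.bedtime >= pd.Timedelta(hours=24):
            raise ParameterError("rest interval must be shorter than 24 h")


@dataclass
class SleepNight:
    """Per-night sleep summary.  ``scorable`` is False when no sleep onset was found."""

    bedtime: pd.Timestamp
    waketime: pd.Timestamp
    scorable: bool
    time_in_bed: float  # minutes
    sleep_phase: float  # clock hours, midpoint of bedtime and waketime
    sleep_onset: pd.Timestamp | None = None
    sleep_latency: float | None = None  # minutes
    total_sleep_time: float | None = None  # minutes
    sleep_efficiency: float | None = None  # percent
    waso: float | None = None  # minutes


def cole_score(activity, scale: float = 1.0) -> np.ndarray:
    """Score per-minute activity to sleep(=True)/wake(=False) flags.

    ``activity`` must be 1-min epochs; boundaries are zero-padded.
    """
    if not scale > 0:
        raise ParameterError("scale must be positive")
    a = np.asarray(activity, dtype=float) / scale
    padded = np.concatenate([np.zeros(4), a, np.zeros(2)])
    d = COLE_FACTOR * np.correlate(padded, COLE_WEIGHTS, mode="valid")
    return d < 1.0


def cole_discriminant(activity, scale: float = 1.0) -> np.ndarray:
    """The raw D_t values behind :func:`cole_score` (for inspection/tests)."""
    a = np.asarray(activity, dtype=float) / scale
    padded = np.concatenate([np.zeros(4), a, np.zeros(2)])
    return COLE_FACTOR * np.correlate(padded, COLE_WEIGHTS, mode="valid")


def webster_rescore(flags: np.ndarray) -> np.ndarray:
    """Apply the classical wake-rescoring rules to sleep/wake flags.

    Off by default in every caller (the scoring method reference here names
    only the weighted-window discriminant); exposed behind a flag for parity
    with clinical actigraphy software.  Rules: after ≥4/10/15 min of wake the
    first 1/3/4 min of sleep are rescored wake; sleep bouts ≤6 min flanked by
    ≥10 min wake, and ≤10 min flanked by ≥20 min wake, are rescored wake.
    """
    f = np.asarray(flags, dtype=bool).copy()
    n = len(f)

    def run_lengths(arr):
        # (value, start, length) runs
        runs = []
        i = 0
        while i < n:
            j = i
            while j < n and arr[j] == arr[i]:
                j += 1
            runs.append((arr[i], i, j - i))
            i = j
        return runs

    runs = run_lengths(f)
    for k, (val, start, length) in enumerate(runs):
        if val:
            continue
        # val is False (wake) — rescore the head of the following sleep run
        if k + 1 < len(runs):
            nval, nstart, nlen = runs[k + 1]
            if nval:
                if length >= 15:
                    f[nstart : nstart + min(4, nlen)] = False
                elif length >= 10:
                    f[nstart : nstart + min(3, nlen)] = False
                elif length >= 4:
                    f[nstart : nstart + min(1, nlen)] = False
    runs = run_lengths(f)
    for k, (val, start, length) in enumerate(runs):
        if not val or k == 0 or k == len(runs) - 1:
            continue
        _, _, before = runs[k - 1]
        _, _, after = runs[k + 1]
        if length <= 6 and before >= 10 and after >= 10:
            f[start : start + length] = False
        elif length <= 10 and before >= 20 and after >= 20:
            f[start : start + length] = False
    return f


def score_series(series: EpochSeries, scale: float = 1000.0) -> np.ndarray:
    """Sleep/wake flags for a whole series (requires 1-min epochs)."""
    if series.epoch_length != 60:
        raise ResolutionError(
            f"Cole scoring requires 1-min epochs; got {series.epoch_length} s — "
            "resample the series first"
        )
    return cole_score(series.channel("activity_pim"), scale=scale)


def _clock_hours(ts: pd.Timestamp) -> float:
    return ts.hour + ts.minute / 60.0 + ts.second / 3600.0


def summarize_night(
    flags: np.ndarray,
    times: pd.DatetimeIndex,
    interval: RestInterval,
    onset_rule: int = 5,
) -> SleepNight:
    """Summarize one rest interval from per-minute sleep/wake flags.

    Sleep onset is the start of the first run of ≥ ``onset_rule`` consecutive
    sleep minutes at or after bedtime; TST and WASO are counted on
    ``[sleep_onset, waketime)`` so that TST + WASO = waketime − sleep_onset.
    A night with no qualifying sleep run is returned with ``scorable=False``.
    """
    if onset_rule < 1:
        raise ParameterError("onset_rule must be ≥ 1")
    flags = np.asarray(flags, dtype=bool)
    sel = (times >= interval.bedtime) & (times < interval.waketime)
    tib = (interval.waketime - interval.bedtime).total_seconds() / 60.0
    mid = interval.bedtime + (interval.waketime - interval.bedtime) / 2
    phase = _clock_hours(mid)
    night = SleepNight(
        bedtime=interval.bedtime,
        waketime=interval.waketime,
        scorable=False,
        time_in_bed=tib,
        sleep_phase=phase,
    )
    f = flags[sel]
    t = times[sel]
    if len(f) == 0:
        return night

    onset_idx = None
    run = 0
    for i, s in enumerate(f):
        run = run + 1 if s else 0
        if run >= onset_rule:
            onset_idx = i - onset_rule + 1
            break
    if onset_idx is None:
        return night

    onset_time = t[onset_idx]
    period = f[onset_idx:]
    tst = float(np.sum(period))
    waso = float(len(period) - tst)
    night.scorable = True
    night.sleep_onset = onset_time
    night.sleep_latency = (onset_time - interval.bedtime).total_seconds() / 60.0
    night.total_sleep_time = tst
    night.waso = waso
    night.sleep_efficiency = 100.0 * tst / tib if tib > 0 else float("nan")
    return night


def rest_intervals_from_events(events) -> list[RestInterval]:
    """Pair consecutive ``bedtime``→``waketime`` diary markers into intervals."""
    intervals = []
    pending = None
    for ts, label in sorted(events, key=lambda e: pd.Timestamp(e[0])):
        if label == "bedtime":
            pending = pd.Timestamp(ts)
        elif label == "waketime" and pending is not None:
            wake = pd.Timestamp(ts)
            if wake > pending and wake - pending < pd.Timedelta(hours=24):
                intervals.append(RestInterval(pending, wake, source="diary_event"))
            pending = None
    return intervals


def default_rest_intervals(
    series: EpochSeries, bedtime: str = "23:00", waketime: str = "07:00"
) -> list[RestInterval]:
    """Config-default nightly windows when no diary events exist."""
    bed_h, bed_m = (int(v) for v in bedtime.split(":"))
    wake_h, wake_m = (int(v) for v in waketime.split(":"))
    day0 = series.start_time.normalize()
    last = series.times[-1]
    intervals = []
    day = day0
    while day <= last:
        bt = day + pd.Timedelta(hours=bed_h, minutes=bed_m)
        wt = day + pd.Timedelta(days=1, hours=wake_h, minutes=wake_m)
        if wt - bt >= pd.Timedelta(hours=24):
            wt = bt + pd.Timedelta(hours=23, minutes=59)
        if bt >= series.start_time and wt <= last:
            intervals.append(RestInterval(bt, wt, source="config_default"))
        day += pd.Timedelta(days=1)
    return intervals


def sleep_summary(
    series: EpochSeries,
    scale: float = 1000.0,
    onset_rule: int = 5,
    intervals: list[RestInterval] | None = None,
    webster: bool = False,
) -> list[SleepNight]:
    """Score a series and summarize every rest interval.

    Intervals come from diary events when present, otherwise from the
    config-default window.
    """
    if intervals is None:
        intervals = rest_intervals_from_events(series.events)
        if not intervals:
            intervals = default_rest_intervals(series)
    flags = score_series(series, scale=scale)
    if webster:
        flags = webster_rescore(flags)
    times = series.times
    return [summarize_night(flags, times, iv, onset_rule=onset_rule) for iv in intervals]


def mean_sleep_parameters(nights: list[SleepNight]) -> dict[str, float]:
    """Per-participant means over scorable nights (clock times averaged circularly)."""
    sc = [n for n in nights if n.scorable]
    out = {
        "n_nights": float(len(nights)),
        "n_scorable": float(len(sc)),
    }
    if not sc:
        return out

    def circ_mean_hours(hours):
        ang = np.asarray(hours) * 2 * np.pi / 24.0
        m = np.arctan2(np.mean(np.sin(ang)), np.mean(np.cos(ang)))
        return float(np.mod(m * 24.0 / (2 * np.pi), 24.0))

    out["bedtime"] = circ_mean_hours([_clock_hours(n.bedtime) for n in sc])
    out["waketime"] = circ_mean_hours([_clock_hours(n.waketime) for n in sc])
    out["sleep_phase"] = circ_mean_hours([n.sleep_phase for n in sc])
    out["time_in_bed"] = float(np.mean([n.time_in_bed for n in sc]))
    out["total_sleep_time"] = float(np.mean([n.total_sleep_time for n in sc]))
    out["sleep_efficiency"] = float(np.mean([n.sleep_efficiency for n in sc]))
    out["sleep_latency"] = float(np.mean([n.sleep_latency for n in sc]))
    out["waso"] = float(np.mean([n.waso for n in sc]))
    return out
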