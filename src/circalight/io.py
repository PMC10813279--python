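"""Epoch-level actigraphy data model and delimited-text I/O.

The raw unit of analysis is a 7-day, 1-min multichannel wrist recording:
activity counts (PIM), wrist skin temperature (°C), illuminance (lx) and
blue-light irradiance (μW/cm²).  Everything downstream (rhythmometry, sleep
scoring, light-hygiene indices, time-resolved association) consumes the
:class:`EpochSeries` built here or the 48-bin :class:`DailyProfile` derived
from it.

Timestamps are timezone-naive local clock time throughout: the analyses are
clock-aligned (bins, acrophases, onsets are clock times) and the recordings
avoid DST transitions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    FormatError,
    InsufficientDataError,
    IntegrityError,
    ParameterError,
)

#: canonical channel names, in serialization order
CHANNELS = ("activity_pim", "wrist_temp", "lux", "blue")

#: channels constrained to be non-negative where unmasked
NONNEGATIVE_CHANNELS = ("activity_pim", "lux", "blue")

BIN_MINUTES = 30
N_BINS = 48


@dataclass
class EpochSeries:
    """One participant's timestamped multichannel actigraphy record.

    Parameters
    ----------
    participant_id : str
        Opaque identifier.
    start_time : pandas.Timestamp
        Timezone-naive local clock time of the first epoch.
    epoch_length : int
        Epoch duration in seconds (60 for the 1-min device export).
    channels : dict of str -> ndarray
        Named float arrays over epochs; keys from :data:`CHANNELS`.
    valid : ndarray of bool
        Per-epoch validity flag.  ``False`` marks masked epochs, which are
        excluded from every downstream mean/variance.
    events : list of (Timestamp, str)
        Optional diary markers (e.g. ``bedtime`` / ``waketime``).
    """

    participant_id: str
    start_time: pd.Timestamp
    channels: dict[str, np.ndarray]
    valid: np.ndarray
    epoch_length: int = 60
    events: list[tuple[pd.Timestamp, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.start_time = pd.Timestamp(self.start_time)
        if self.start_time.tzinfo is not None:
            raise IntegrityError("timestamps must be timezone-naive local clock time")
        if self.epoch_length <= 0:
            raise ParameterError("epoch_length must be positive")
        if not self.channels:
            raise IntegrityError("EpochSeries needs at least one channel")
        lengths = {name: len(arr) for name, arr in self.channels.items()}
        if len(set(lengths.values())) != 1:
            raise IntegrityError(f"channel arrays have unequal lengths: {lengths}")
        n = next(iter(lengths.values()))
        self.channels = {k: np.asarray(v, dtype=float) for k, v in self.channels.items()}
        self.valid = np.asarray(self.valid, dtype=bool)
        if len(self.valid) != n:
            raise IntegrityError("valid mask length differs from channel length")
        for name in NONNEGATIVE_CHANNELS:
            if name in self.channels:
                vals = self.channels[name][self.valid]
                if np.any(vals < 0):
                    raise IntegrityError(f"channel {name!r} has negative unmasked values")

    @property
    def n_epochs(self) -> int:
        return len(self.valid)

    @property
    def times(self) -> pd.DatetimeIndex:
        return self.start_time + pd.to_timedelta(
            np.arange(self.n_epochs) * self.epoch_length, unit="s"
        )

    @property
    def hours_elapsed(self) -> np.ndarray:
        """Hours since local midnight of the first day (continuous, multi-day)."""
        offset = (self.start_time - self.start_time.normalize()).total_seconds() / 3600.0
        return offset + np.arange(self.n_epochs) * (self.epoch_length / 3600.0)

    @property
    def clock_hours(self) -> np.ndarray:
        """Clock time of each epoch in fractional hours [0, 24)."""
        return np.mod(self.hours_elapsed, 24.0)

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.channels[name]
        except KeyError:
            raise LookupError(
                f"unknown channel {name!r}; available: {sorted(self.channels)}"
            ) from None


@dataclass
class ParticipantMeta:
    """Per-participant metadata: anthropometrics, hormones and genotype."""

    participant_id: str
    bmi: float | None = None
    leptin: float | None = None
    cortisol: float | None = None
    sex: str | None = None  # {"female", "male"}
    age: float | None = None
    population: str | None = None  # {"native", "non_native"}
    genotype: str = "missing"  # MTNR1B rs10830963: {"CC", "CG", "GG", "missing"}

    def __post_init__(self) -> None:
        if self.genotype not in ("CC", "CG", "GG", "missing"):
            raise ParameterError(f"unknown genotype {self.genotype!r}")
        if self.bmi is not None and not self.bmi > 0:
            raise ParameterError("bmi must be positive when present")

    @property
    def g_carrier(self) -> bool | None:
        """True iff the genotype carries a G allele; None when genotype is missing."""
        if self.genotype == "missing":
            return None
        return "G" in self.genotype


@dataclass
class DailyProfile:
    """Clock-aligned 48-bin (30-min) mean profile of one channel.

    Bin ``b`` covers local clock time ``[b*30 min, (b+1)*30 min)``; bin 0
    starts at 00:00.  Bins with no contributing unmasked epoch hold NaN and
    are flagged by :attr:`missing_bins`; they are never imputed.
    """

    values: np.ndarray  # 48 floats, NaN = missing
    n_contrib: np.ndarray  # 48 ints
    channel: str
    transform: str = "raw"  # {"raw", "log10"}

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.n_contrib = np.asarray(self.n_contrib, dtype=int)
        if self.values.shape != (N_BINS,) or self.n_contrib.shape != (N_BINS,):
            raise IntegrityError(f"DailyProfile needs exactly {N_BINS} bins")
        if self.transform not in ("raw", "log10"):
            raise ParameterError(f"unknown transform {self.transform!r}")

    @property
    def missing_bins(self) -> list[int]:
        return [int(b) for b in np.flatnonzero(self.n_contrib == 0)]

    @staticmethod
    def bin_midpoints_hours() -> np.ndarray:
        """Clock-hour midpoints of the 48 bins: 0.25, 0.75, ..., 23.75."""
        return (np.arange(N_BINS) + 0.5) * (BIN_MINUTES / 60.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin": np.arange(N_BINS),
                "mid_hour": self.bin_midpoints_hours(),
                "value": self.values,
                "n_contrib": self.n_contrib,
            }
        )


@dataclass
class EpochDialect:
    """Column mapping and parsing options for a delimited epoch file.

    The device's native layout is vendor-specific, so the reader is driven by
    this dialect rather than a hard-coded format.
    """

    timestamp_col: str = "timestamp"
    columns: dict[str, str] = field(
        default_factory=lambda: {name: name for name in CHANNELS}
    )
    mask_col: str | None = "masked"  # nonzero/true ⇒ epoch masked; optional
    delimiter: str = ","
    decimal: str = "."
    timestamp_format: str | None = None  # None ⇒ ISO-8601
    epoch_length: int = 60

    @classmethod
    def from_file(cls, path) -> "EpochDialect":
        """Load a dialect from a YAML or JSON mapping of these fields."""
        import json

        import yaml

        text = open(path).read()
        data = (
            json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        ) or {}
        return cls(**data)


def log10_floor(x, floor: float = 0.01):
    """log10 with a positive floor: ``log10(max(x, floor))``.

    Device zeros are common in nocturnal irradiance; the floor (default
    0.01 μW/cm², below the lowest hygiene threshold of 0.1) keeps the log
    transform defined without disturbing values in the analysed range.
    """
    if not floor > 0:
        raise ParameterError("log10 floor must be > 0")
    return np.log10(np.maximum(np.asarray(x, dtype=float), floor))


def read_epoch_series(
    path,
    dialect: EpochDialect | None = None,
    participant_id: str | None = None,
    events_path=None,
) -> EpochSeries:
    """Read a delimited epoch file into a validated :class:`EpochSeries`.

    Rows with unparseable channel values become masked epochs.  Gaps in the
    timestamp grid are filled with masked filler epochs so the spacing stays
    uniform at ``dialect.epoch_length``.

    Raises
    ------
    FormatError
        Missing required column, empty file, unparseable timestamp.
    IntegrityError
        Duplicated or non-monotonic timestamps, off-grid timestamps.
    """
    dialect = dialect or EpochDialect()
    try:
        df = pd.read_csv(
            path, sep=dialect.delimiter, decimal=dialect.decimal, dtype=str,
            skipinitialspace=True,
        )
    except pd.errors.EmptyDataError:
        raise FormatError(f"empty epoch file: {path}") from None
    if df.empty:
        raise FormatError(f"epoch file has a header but no rows: {path}")

    required = [dialect.timestamp_col] + [dialect.columns[c] for c in dialect.columns]
    for col in required:
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r} in {path}")

    ts = pd.to_datetime(
        df[dialect.timestamp_col], format=dialect.timestamp_format, errors="coerce"
    )
    if ts.isna().any():
        bad = df[dialect.timestamp_col][ts.isna()].iloc[0]
        raise FormatError(f"unparseable timestamp {bad!r} in {path}")
    tvals = ts.to_numpy()
    if len(tvals) > 1 and not (np.diff(tvals) > np.timedelta64(0, "s")).all():
        raise IntegrityError(f"timestamps not strictly increasing in {path}")

    step = np.timedelta64(dialect.epoch_length, "s")
    offsets = (tvals - tvals[0]) / step
    idx = np.rint(offsets).astype(int)
    if not np.allclose(offsets, idx):
        raise IntegrityError(
            f"timestamps in {path} do not align to a {dialect.epoch_length}-s grid"
        )

    def parse_floats(strings):
        # Python float() is correctly rounded (pandas' fast parser is not),
        # which the exact write/read round-trip contract relies on
        out = np.empty(len(strings))
        for i, v in enumerate(strings):
            try:
                if dialect.decimal != ".":
                    v = v.replace(dialect.decimal, ".")
                out[i] = float(v)
            except (TypeError, ValueError):
                out[i] = np.nan
        return out

    n = idx[-1] + 1
    channels = {}
    row_valid = np.ones(len(df), dtype=bool)
    if dialect.mask_col and dialect.mask_col in df.columns:
        flagged = parse_floats(df[dialect.mask_col].to_numpy())
        row_valid &= ~(np.nan_to_num(flagged) != 0)
    for canon, col in dialect.columns.items():
        vals = parse_floats(df[col].to_numpy())
        row_valid &= np.isfinite(vals)
        full = np.full(n, np.nan)
        full[idx] = vals
        channels[canon] = full
    valid = np.zeros(n, dtype=bool)
    valid[idx] = row_valid
    for name in NONNEGATIVE_CHANNELS:
        if name in channels:
            neg = valid & (channels[name] < 0)
            valid &= ~neg  # negative physical values are masked, not rejected

    events = []
    if events_path is not None:
        ev = pd.read_csv(events_path, dtype=str)
        if ev.shape[1] < 2:
            raise FormatError(f"events file {events_path} needs (timestamp, label) columns")
        for _, row in ev.iterrows():
            t = pd.to_datetime(row.iloc[0], errors="coerce")
            if pd.isna(t):
                raise FormatError(f"unparseable event timestamp {row.iloc[0]!r}")
            events.append((pd.Timestamp(t), str(row.iloc[1])))

    pid = participant_id or str(path)
    return EpochSeries(
        participant_id=pid,
        start_time=pd.Timestamp(tvals[0]),
        channels=channels,
        valid=valid,
        epoch_length=dialect.epoch_length,
        events=events,
    )


def write_epoch_series(series: EpochSeries, path) -> None:
    """Serialize to canonical CSV (ISO-8601 timestamps, ``masked`` flag column)."""
    df = pd.DataFrame({"timestamp": series.times.strftime("%Y-%m-%dT%H:%M:%S")})
    for name, arr in series.channels.items():
        df[name] = arr
    df["masked"] = (~series.valid).astype(int)
    # %.17g guarantees exact float64 round-tripping
    df.to_csv(path, index=False, float_format="%.17g")


def write_events(events: Sequence[tuple[pd.Timestamp, str]], path) -> None:
    df = pd.DataFrame(
        {
            "timestamp": [pd.Timestamp(t).strftime("%Y-%m-%dT%H:%M:%S") for t, _ in events],
            "label": [lab for _, lab in events],
        }
    )
    df.to_csv(path, index=False)


def bin_daily_profile(
    series: EpochSeries,
    channel: str,
    transform: str = "raw",
    log_floor: float = 0.01,
    per_day_first: bool = False,
) -> DailyProfile:
    """Average a channel into the 48 clock-aligned 30-min bins.

    Default is pool-then-mean: all unmasked epochs of all recorded days whose
    clock time falls in bin ``b`` are pooled and averaged together, which is
    robust to partial days.  ``per_day_first=True`` instead averages within
    each calendar day first and then across days.
    """
    x = series.channel(channel)
    if transform == "log10":
        x = log10_floor(x, log_floor)
    elif transform != "raw":
        raise ParameterError(f"unknown transform {transform!r}")
    valid = series.valid
    if not valid.any():
        raise InsufficientDataError(
            f"series {series.participant_id!r} has no unmasked epochs"
        )
    minutes = np.mod((series.hours_elapsed * 60.0).round().astype(np.int64), 1440)
    bins = minutes // BIN_MINUTES

    values = np.full(N_BINS, np.nan)
    if per_day_first:
        day_idx = (series.hours_elapsed // 24.0).astype(int)
        frame = pd.DataFrame(
            {"day": day_idx[valid], "bin": bins[valid], "x": x[valid]}
        )
        per_day = frame.groupby(["day", "bin"])["x"].mean().reset_index()
        mean_by_bin = per_day.groupby("bin")["x"].mean()
        values[mean_by_bin.index.to_numpy()] = mean_by_bin.to_numpy()
        n_contrib = np.bincount(bins[valid], minlength=N_BINS)
    else:
        n_contrib = np.bincount(bins[valid], minlength=N_BINS)
        sums = np.bincount(bins[valid], weights=x[valid], minlength=N_BINS)
        nz = n_contrib > 0
        values[nz] = sums[nz] / n_contrib[nz]
    return DailyProfile(values=values, n_contrib=n_contrib, channel=channel, transform=transform)
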