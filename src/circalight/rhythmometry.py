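"""Parametric (cosinor) and non-parametric circadian rhythm indices.

The single-component cosinor fits ``y(t) = M + A·cos(2πt/τ − φ)`` by ordinary
least squares in its linearised form ``M + β·cos(ωt) + γ·sin(ωt)``; MESOR is
M, amplitude A = √(β²+γ²), and the acrophase is reported as the local clock
time at which the fitted curve peaks (hh.fraction in [0, 24)), matching how
actigraphy reports print phases.  A zero-amplitude F-test with (2, n−3)
degrees of freedom compares the rhythm model against the intercept-only model.

Non-parametric indices follow the classical rest–activity conventions:
inter-daily stability (IS) and intra-daily variability (IV) on hourly means,
M10/L5 by exhaustive sliding-window search over the wrap-around average daily
profile at epoch resolution, relative amplitude RA = (M10−L5)/(M10+L5), and a
circadian function index CFI combining IS, inverted-normalised IV and RA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import InsufficientDataError, ParameterError, UndefinedIndexError
from .io import EpochSeries

_EPS = 1e-12


@dataclass
class CosinorFit:
    """Summary of a fixed-period single-component cosinor fit."""

    mesor: float
    amplitude: float
    acrophase: float  # clock time of fitted peak, hours in [0, 24)
    period: float  # hours
    f_stat: float
    p_zero_amplitude: float
    residual_sd: float
    n_used: int


@dataclass
class NonparamIndices:
    """Non-parametric rest–activity summary for one channel."""

    is_: float  # inter-daily stability, [0, 1]
    iv: float  # intra-daily variability, [0, 4] on hourly data
    m10: float  # mean of the 10 most-active consecutive hours
    m10_onset: float  # clock hours
    l5: float  # mean of the 5 least-active consecutive hours
    l5_onset: float  # clock hours
    ra: float  # relative amplitude
    cfi: float  # circadian function index


def cosinor_from_arrays(t_hours, y, period: float = 24.0) -> CosinorFit:
    """Cosinor fit on explicit (time in hours, value) arrays.

    ``t_hours`` is measured from local midnight so the acrophase comes out
    directly as a clock time.  Requires ≥ 4 points spanning more than half a
    period.  A constant input returns amplitude 0 with p = 1 by convention.
    """
    t = np.asarray(t_hours, dtype=float)
    y = np.asarray(y, dtype=float)
    if period <= 0:
        raise ParameterError("period must be positive")
    n = len(y)
    if n < 4 or len(t) != n:
        raise InsufficientDataError(f"cosinor needs ≥ 4 matched points, got {n}")
    if t.max() - t.min() <= period / 2:
        raise InsufficientDataError("cosinor needs data spanning more than half a period")

    omega = 2.0 * np.pi / period
    X = np.column_stack([np.ones(n), np.cos(omega * t), np.sin(omega * t)])
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    mesor, beta, gamma = coef
    amplitude = float(np.hypot(beta, gamma))
    # fitted curve = M + A·cos(ωt − φ) with φ = atan2(γ, β); peak at t = φ/ω
    acrophase = float(np.mod(np.arctan2(gamma, beta) / omega, period))

    resid = y - X @ coef
    sse1 = float(resid @ resid)
    sse0 = float(np.sum((y - y.mean()) ** 2))
    df2 = n - 3
    scale = max(sse0, 1.0)
    if sse1 <= _EPS * scale:  # (near-)perfect fit
        if amplitude <= _EPS * max(abs(mesor), 1.0):
            f_stat, p = 0.0, 1.0  # constant input: no rhythm, by convention
        else:
            f_stat, p = np.inf, 0.0
    else:
        f_stat = ((sse0 - sse1) / 2.0) / (sse1 / df2)
        f_stat = max(float(f_stat), 0.0)
        p = float(stats.f.sf(f_stat, 2, df2))
    residual_sd = float(np.sqrt(sse1 / df2)) if df2 > 0 else float("nan")
    return CosinorFit(
        mesor=float(mesor),
        amplitude=amplitude,
        acrophase=acrophase,
        period=float(period),
        f_stat=float(f_stat),
        p_zero_amplitude=float(p),
        residual_sd=residual_sd,
        n_used=n,
    )


def fit_cosinor(series: EpochSeries, channel: str, period: float = 24.0) -> CosinorFit:
    """Cosinor fit of one channel of an :class:`EpochSeries` (unmasked epochs only)."""
    y = series.channel(channel)[series.valid]
    t = series.hours_elapsed[series.valid]
    return cosinor_from_arrays(t, y, period=period)


def _hourly_means(series: EpochSeries, channel: str):
    """Sequential hourly means over the recording, with each hour's clock class.

    Hours without any unmasked epoch are dropped; IV differences then span the
    gap, which is the standard pragmatic treatment for short masked stretches.
    """
    x = series.channel(channel)
    valid = series.valid
    hour_idx = np.floor(series.hours_elapsed).astype(np.int64)
    hour_idx -= hour_idx[0]
    counts = np.bincount(hour_idx[valid])
    sums = np.bincount(hour_idx[valid], weights=x[valid])
    present = counts > 0
    means = sums[present] / counts[present]
    first_clock_hour = int(np.floor(series.hours_elapsed[0])) % 24
    clock = (np.flatnonzero(present) + first_clock_hour) % 24
    return means, clock


def _mean_daily_curve(series: EpochSeries, channel: str) -> np.ndarray:
    """Average daily profile at epoch resolution (NaN at uncovered positions)."""
    per_day = int(round(86400 / series.epoch_length))
    pos = np.mod(
        np.rint(series.hours_elapsed * 3600 / series.epoch_length).astype(np.int64),
        per_day,
    )
    x = series.channel(channel)
    valid = series.valid
    counts = np.bincount(pos[valid], minlength=per_day)
    sums = np.bincount(pos[valid], weights=x[valid], minlength=per_day)
    curve = np.full(per_day, np.nan)
    nz = counts > 0
    curve[nz] = sums[nz] / counts[nz]
    return curve


def _window_extreme(curve: np.ndarray, window: int, mode: str):
    """Best wrap-around window mean (exhaustive; ties → earliest clock onset)."""
    n = len(curve)
    filled = np.nan_to_num(curve, nan=0.0)
    counts = np.isfinite(curve).astype(float)
    csum = np.concatenate([filled, filled]).cumsum()
    ccnt = np.concatenate([counts, counts]).cumsum()
    best_val, best_start = None, None
    for start in range(n):
        s = csum[start + window - 1] - (csum[start - 1] if start > 0 else 0.0)
        c = ccnt[start + window - 1] - (ccnt[start - 1] if start > 0 else 0.0)
        if c == 0:
            continue
        m = s / c
        better = (
            best_val is None
            or (mode == "max" and m > best_val + 1e-15)
            or (mode == "min" and m < best_val - 1e-15)
        )
        if better:
            best_val, best_start = m, start
    if best_val is None:
        raise InsufficientDataError("no covered window in the daily profile")
    return float(best_val), int(best_start)


def nonparametric_indices(
    series: EpochSeries, channel: str, basis: str = "hourly"
) -> NonparamIndices:
    """IS, IV, M10/L5 (+onsets), RA and CFI for one channel.

    IS/IV are computed on hourly means by default (``basis="hourly"``, the
    classical convention); ``basis="epoch"`` uses raw epochs with clock-epoch
    classes instead.  M10/L5 always use a sliding window at epoch resolution
    over the wrap-around mean daily profile.

    Raises
    ------
    UndefinedIndexError
        If the series has zero variance on the chosen basis.
    """
    if series.n_epochs * series.epoch_length < 24 * 3600:
        raise InsufficientDataError("non-parametric indices need ≥ 24 h of data")
    if basis == "hourly":
        xs, clock_class = _hourly_means(series, channel)
        p_classes = 24
    elif basis == "epoch":
        xs = series.channel(channel)[series.valid]
        per_day = int(round(86400 / series.epoch_length))
        clock_class = np.mod(
            np.rint(series.hours_elapsed * 3600 / series.epoch_length).astype(np.int64),
            per_day,
        )[series.valid]
        p_classes = per_day
    else:
        raise ParameterError(f"unknown basis {basis!r}")

    N = len(xs)
    xbar = xs.mean()
    ss_total = float(np.sum((xs - xbar) ** 2))
    if ss_total <= 0:
        raise UndefinedIndexError("IS/IV undefined: zero variance")

    class_means = np.zeros(p_classes)
    for h in range(p_classes):
        sel = clock_class == h
        if sel.any():
            class_means[h] = xs[sel].mean()
        else:
            class_means[h] = xbar  # empty class contributes nothing to IS
    is_ = float(N * np.sum((class_means - xbar) ** 2) / (p_classes * ss_total))
    diffs = np.diff(xs)
    iv = float(N * np.sum(diffs**2) / ((N - 1) * ss_total))

    curve = _mean_daily_curve(series, channel)
    per_hour = int(round(3600 / series.epoch_length))
    m10, m10_start = _window_extreme(curve, 10 * per_hour, "max")
    l5, l5_start = _window_extreme(curve, 5 * per_hour, "min")
    m10_onset = m10_start * series.epoch_length / 3600.0
    l5_onset = l5_start * series.epoch_length / 3600.0

    ra = 0.0 if (m10 + l5) == 0 else float((m10 - l5) / (m10 + l5))
    iv_term = float(np.clip((2.0 - iv) / 2.0, 0.0, 1.0))
    cfi = float((np.clip(is_, 0, 1) + iv_term + np.clip(ra, 0, 1)) / 3.0)
    return NonparamIndices(
        is_=is_, iv=iv, m10=m10, m10_onset=m10_onset,
        l5=l5, l5_onset=l5_onset, ra=ra, cfi=cfi,
    )
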