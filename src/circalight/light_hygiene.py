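"""Blue-light hygiene: recommendation-anchored reference curve, NEI/DDI indices.

Consensus light-hygiene recommendations are phrased in melanopic equivalent
daylight illuminance (mEDI): at least 250 lx mEDI during daytime, at most
10 lx mEDI in the pre-bed hours, and below 1 lx mEDI during sleep.  For the
standard illuminant D65, 1 lx mEDI corresponds to 1.3262 mW/m² of melanopic
irradiance, i.e. 0.13262 μW/cm², which converts the three anchors to
≈33, ≈1.33 and ≈0.13 μW/cm² (the sleep anchor is conventionally printed as
0.1 μW/cm² and the reference curve uses that printed value).

The reference curve R(t) is a continuous 24-h template built from those
anchors: a daytime half-sine arc scaled to cross the 33 μW/cm² daytime target
at 09:00 and 17:00 (peak ≈52.93 μW/cm² at 13:00), an evening cosine ramp
from the 1.33 pre-bed ceiling at 20:00 down to the 0.1 sleep plateau at
23:00, the plateau until 05:00, and a morning ramp back to the day arc.  The
day arc is clipped from below at the pre-bed ceiling so the curve stays
continuous and never drops below the sleep plateau.

Two scalar indices integrate a participant's 48-bin mean blue-light profile
against R(t):

* ``DDI_bl`` — daytime deficit: area *below* the curve over 06:00–20:00;
* ``NEI_bl`` — nocturnal excess: area *above* the curve over 20:00–05:00;

both in μW/cm²·h, by rectangle quadrature over the 30-min bins with R
evaluated at bin midpoints.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .exceptions import ParameterError, UnitError
from .io import BIN_MINUTES, N_BINS, DailyProfile, EpochSeries, bin_daily_profile

#: melanopic irradiance (μW/cm²) per lx of melanopic EDI under D65
MEDI_TO_IRRADIANCE_UW_CM2 = 0.13262

#: NEI/DDI clock windows, half-open, hours
DAY_WINDOW = (6.0, 20.0)
NIGHT_WINDOW = (20.0, 5.0)  # wraps midnight


def medi_to_irradiance(medi):
    """Convert melanopic EDI (lx) to melanopic irradiance (μW/cm²)."""
    medi = np.asarray(medi, dtype=float)
    if np.any(medi < 0):
        raise ParameterError("mEDI must be non-negative")
    out = medi * MEDI_TO_IRRADIANCE_UW_CM2
    return float(out) if out.ndim == 0 else out


def irradiance_to_medi(irr):
    """Inverse of :func:`medi_to_irradiance`."""
    irr = np.asarray(irr, dtype=float)
    if np.any(irr < 0):
        raise ParameterError("irradiance must be non-negative")
    out = irr / MEDI_TO_IRRADIANCE_UW_CM2
    return float(out) if out.ndim == 0 else out


@dataclass
class ReferenceCurve:
    """Recommendation-anchored 24-h blue-light reference template.

    All anchors and breakpoints are configurable; the default shape is the
    package's explicit reconstruction of a "natural gradual changes" template
    (see module docstring).  ``shape="plateau"`` is a named alternative whose
    day segment sits flat at the daytime target.
    """

    day_target: float = 33.0  # μW/cm², crossed at day_anchor_hour
    prebed_ceiling: float = 1.33  # μW/cm²
    sleep_ceiling: float = 0.1  # μW/cm²
    day_window: tuple[float, float] = DAY_WINDOW  # [start, end) clock hours
    day_anchor_hour: float = 9.0  # day arc crosses day_target here (and mirrored)
    prebed_ramp_end: float = 23.0  # sleep plateau starts here
    sleep_end: float = 5.0  # morning ramp starts here
    shape: str = "half_sine"  # {"half_sine", "plateau"}

    def __post_init__(self) -> None:
        if not (self.day_target >= self.prebed_ceiling >= self.sleep_ceiling > 0):
            raise ParameterError(
                "anchors must satisfy day_target ≥ prebed_ceiling ≥ sleep_ceiling > 0"
            )
        d0, d1 = self.day_window
        if not (0 <= d0 < d1 <= 24):
            raise ParameterError("day_window must be an increasing pair within [0, 24]")
        if not (d0 < self.day_anchor_hour < d1):
            raise ParameterError("day_anchor_hour must lie inside the day window")
        if self.shape not in ("half_sine", "plateau"):
            raise ParameterError(f"unknown shape {self.shape!r}")
        if not (d1 < self.prebed_ramp_end <= 24):
            raise ParameterError("prebed ramp must follow the day window")
        if not (0 < self.sleep_end <= d0):
            raise ParameterError("sleep plateau must end before the day window")

    @property
    def peak(self) -> float:
        """Scale of the daytime half-sine arc (its 13:00 maximum by default)."""
        d0, d1 = self.day_window
        frac = (self.day_anchor_hour - d0) / (d1 - d0)
        return self.day_target / math.sin(math.pi * frac)

    def _day_value(self, t: np.ndarray) -> np.ndarray:
        d0, d1 = self.day_window
        if self.shape == "plateau":
            return np.full_like(t, self.day_target)
        arc = self.peak * np.sin(np.pi * (t - d0) / (d1 - d0))
        # clip from below so the arc meets the pre-bed ceiling continuously
        return np.maximum(arc, self.prebed_ceiling)

    def value(self, t) -> np.ndarray | float:
        """Evaluate R(t) at clock hours ``t`` (vectorized, t taken mod 24)."""
        t = np.mod(np.asarray(t, dtype=float), 24.0)
        scalar = t.ndim == 0
        t = np.atleast_1d(t)
        out = np.empty_like(t)
        d0, d1 = self.day_window

        day = (t >= d0) & (t < d1)
        out[day] = self._day_value(t[day])

        ramp = (t >= d1) & (t < self.prebed_ramp_end)
        if ramp.any():
            start_val = float(self._day_value(np.array([d1 - 1e-9]))[0])
            frac = (t[ramp] - d1) / (self.prebed_ramp_end - d1)
            out[ramp] = self.sleep_ceiling + (start_val - self.sleep_ceiling) * (
                1 + np.cos(np.pi * frac)
            ) / 2.0

        plateau = (t >= self.prebed_ramp_end) | (t < self.sleep_end)
        out[plateau] = self.sleep_ceiling

        morning = (t >= self.sleep_end) & (t < d0)
        if morning.any():
            end_val = float(self._day_value(np.array([d0]))[0])
            frac = (t[morning] - self.sleep_end) / (d0 - self.sleep_end)
            out[morning] = self.sleep_ceiling + (end_val - self.sleep_ceiling) * (
                1 - np.cos(np.pi * frac)
            ) / 2.0
        return float(out[0]) if scalar else out

    @property
    def anchors(self) -> dict[str, float]:
        return {
            "day_target": self.day_target,
            "prebed_ceiling": self.prebed_ceiling,
            "sleep_ceiling": self.sleep_ceiling,
        }


def build_reference_curve(preset: str = "half_sine", **overrides) -> ReferenceCurve:
    """Build a reference curve from a named preset plus overrides.

    Presets: ``"half_sine"`` (default reconstruction) and ``"plateau"``
    (flat 33 μW/cm² day segment).
    """
    if preset not in ("half_sine", "plateau"):
        raise ParameterError(f"unknown preset {preset!r}")
    return ReferenceCurve(shape=preset, **overrides)


@dataclass
class LightIndices:
    """DDI/NEI pair for one participant."""

    ddi_bl: float  # μW/cm²·h, ≥ 0
    nei_bl: float  # μW/cm²·h, ≥ 0
    mode: str = "mean_profile"  # {"mean_profile", "per_day_mean"}
    ddi_missing_bins: list[int] = field(default_factory=list)
    nei_missing_bins: list[int] = field(default_factory=list)


def _window_bins(start: float, end: float) -> np.ndarray:
    """Indices of 30-min bins whose midpoints fall in the (possibly wrapping) window."""
    mids = DailyProfile.bin_midpoints_hours()
    if start <= end:
        return np.flatnonzero((mids >= start) & (mids < end))
    return np.flatnonzero((mids >= start) | (mids < end))


def _area(profile: DailyProfile, ref: ReferenceCurve, window, sign: int) -> tuple[float, list[int]]:
    if profile.transform != "raw":
        raise UnitError(
            "NEI/DDI require a raw-irradiance profile; got transform="
            f"{profile.transform!r}"
        )
    bins = _window_bins(*window)
    mids = DailyProfile.bin_midpoints_hours()[bins]
    rvals = np.asarray(ref.value(mids))
    vals = profile.values[bins]
    present = profile.n_contrib[bins] > 0
    diff = sign * (vals[present] - rvals[present])
    area = float(np.sum(np.maximum(diff, 0.0)) * (BIN_MINUTES / 60.0))
    missing = [int(b) for b in bins[~present]]
    return area, missing


def compute_nei(profile: DailyProfile, ref: ReferenceCurve) -> float:
    """Nocturnal excess index: area above R(t) over 20:00–05:00, μW/cm²·h.

    Missing bins contribute 0 (they are listed by :func:`light_indices`).
    """
    area, _ = _area(profile, ref, NIGHT_WINDOW, sign=+1)
    return area


def compute_ddi(profile: DailyProfile, ref: ReferenceCurve) -> float:
    """Daytime deficit index: area below R(t) over 06:00–20:00, μW/cm²·h."""
    area, _ = _area(profile, ref, DAY_WINDOW, sign=-1)
    return area


def light_indices(
    profile: DailyProfile, ref: ReferenceCurve, mode: str = "mean_profile"
) -> LightIndices:
    """Compute both indices with their missing-bin reports."""
    nei, nei_missing = _area(profile, ref, NIGHT_WINDOW, sign=+1)
    ddi, ddi_missing = _area(profile, ref, DAY_WINDOW, sign=-1)
    return LightIndices(
        ddi_bl=ddi,
        nei_bl=nei,
        mode=mode,
        ddi_missing_bins=ddi_missing,
        nei_missing_bins=nei_missing,
    )


def light_indices_for_series(
    series: EpochSeries,
    ref: ReferenceCurve,
    mode: str = "mean_profile",
    channel: str = "blue",
) -> LightIndices:
    """Indices for a whole recording.

    ``mean_profile`` (default) pools all days into one 48-bin profile first;
    ``per_day_mean`` computes the indices on each calendar day's own profile
    and averages them across days.
    """
    if mode == "mean_profile":
        profile = bin_daily_profile(series, channel, transform="raw")
        return light_indices(profile, ref, mode=mode)
    if mode != "per_day_mean":
        raise ParameterError(f"unknown mode {mode!r}")

    day_idx = (series.hours_elapsed // 24.0).astype(int)
    minutes = np.mod((series.hours_elapsed * 60.0).round().astype(np.int64), 1440)
    bins = minutes // BIN_MINUTES
    x = series.channel(channel)
    valid = series.valid
    ddis, neis = [], []
    ddi_missing, nei_missing = set(), set()
    for d in np.unique(day_idx):
        sel = valid & (day_idx == d)
        if not sel.any():
            continue
        n_contrib = np.bincount(bins[sel], minlength=N_BINS)
        sums = np.bincount(bins[sel], weights=x[sel], minlength=N_BINS)
        values = np.full(N_BINS, np.nan)
        nz = n_contrib > 0
        values[nz] = sums[nz] / n_contrib[nz]
        prof = DailyProfile(values=values, n_contrib=n_contrib, channel=channel)
        li = light_indices(prof, ref, mode="per_day_mean")
        ddis.append(li.ddi_bl)
        neis.append(li.nei_bl)
        ddi_missing.update(li.ddi_missing_bins)
        nei_missing.update(li.nei_missing_bins)
    return LightIndices(
        ddi_bl=float(np.mean(ddis)),
        nei_bl=float(np.mean(neis)),
        mode="per_day_mean",
        ddi_missing_bins=sorted(ddi_missing),
        nei_missing_bins=sorted(nei_missing),
    )
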