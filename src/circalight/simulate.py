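"""Synthetic cohort generator: 7-day, 1-min actigraphy with planted structure.

The generator emulates the data structure of a week-long Arctic actigraphy
study at the spring equinox: a diurnal activity rhythm gated by each
participant's sleep interval, a nocturnal-peaking wrist-temperature cosinor,
a daylight blue-light envelope controlled by photoperiod (latitude ~66.9° N),
and evening indoor light.  Its defaults are anchored to the printed cohort
statistics of that study population (wrist-temperature MESOR ≈ 31.99 °C,
bedtime ≈ 22:35, waketime ≈ 06:51, blue-light MESOR ≈ 10 μW/cm²); the
distributional forms (Gaussian noise, lognormal evening light) are simulator
choices, not measured properties.

Planted effects provide ground truth for recovery tests:

* evening blue-light excess proportional to (BMI − 25) with a raised-cosine
  clock weight peaking at 23:30 (optionally restricted to MTNR1B G-allele
  carriers), so the r-chart acrophase and the NEI–BMI association are known;
* a wrist-temperature MESOR slope on BMI in G-carriers;
* leptin tied to BMI and realized WASO, cortisol to realized DDI and the
  blue-light M10 onset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .exceptions import ParameterError
from .io import EpochSeries, ParticipantMeta
from .light_hygiene import ReferenceCurve, light_indices_for_series
from .rhythmometry import nonparametric_indices
from .sleep import mean_sleep_parameters, sleep_summary

#: simulated recordings start at local midnight of this calendar date
START_DATE = "2022-03-21"


@dataclass
class Photoperiod:
    """Sunrise/sunset in local clock hours, with polar sentinels."""

    sunrise: float
    sunset: float
    kind: str  # {"normal", "polar_day", "polar_night"}

    @property
    def day_length(self) -> float:
        return self.sunset - self.sunrise


def photoperiod(latitude: float, day_of_year: int) -> Photoperiod:
    """Day length from the standard solar-declination formula (−0.833° horizon).

    Returns a full-day sentinel (sunrise 0, sunset 24) above the polar circle
    in summer and a no-day sentinel (zero length) in winter.
    """
    if abs(latitude) > 90:
        raise ParameterError("latitude must lie in [-90, 90]")
    decl = -23.44 * math.cos(2 * math.pi * (day_of_year + 10) / 365.2422)
    phi = math.radians(latitude)
    delta = math.radians(decl)
    h0 = math.radians(-0.833)
    cos_h = (math.sin(h0) - math.sin(phi) * math.sin(delta)) / (
        math.cos(phi) * math.cos(delta)
    )
    if cos_h < -1:
        return Photoperiod(0.0, 24.0, "polar_day")
    if cos_h > 1:
        return Photoperiod(12.0, 12.0, "polar_night")
    half = math.degrees(math.acos(cos_h)) / 15.0
    return Photoperiod(12.0 - half, 12.0 + half, "normal")


@dataclass
class SimConfig:
    """All knobs of the synthetic cohort.  Same config + seed ⇒ bit-identical output."""

    n_participants: int = 40
    seed: int = 0
    latitude: float = 66.9
    day_of_year: int = 80  # spring equinox
    epoch_length: int = 60
    days: int = 7

    # activity model (PIM counts)
    activity_wake_mean: float = 4200.0
    activity_wake_amp_frac: float = 0.2  # diurnal modulation of wake activity
    activity_acrophase: float = 14.75  # clock hours
    activity_noise_sd: float = 400.0
    activity_hourly_sigma: float = 0.5  # lognormal hour-to-hour wake-level modulation
    activity_sleep_mean: float = 20.0
    activity_sleep_sd: float = 15.0
    waso_activity: float = 3000.0  # counts during a nocturnal wake bout

    # wrist temperature model (°C)
    wt_mesor: float = 31.99
    wt_amplitude: float = 1.4
    wt_acrophase: float = 2.75  # 02:45
    wt_noise_sd: float = 0.3

    # sleep model (clock hours / rates)
    bedtime_mean: float = 22.583  # 22:35
    waketime_mean: float = 6.85  # 06:51
    sleep_between_sd: float = 0.9  # between-subject sd of bed/wake times
    sleep_night_jitter_sd: float = 0.25  # within-subject nightly jitter
    waso_bouts_per_night: float = 4.0
    waso_bout_minutes: float = 12.0

    # light model (μW/cm² blue irradiance)
    blue_day_peak_median: float = 25.0  # median midday peak reaching the wrist
    blue_day_peak_sigma: float = 0.4  # lognormal sigma between subjects
    blue_noise_sigma: float = 0.5  # multiplicative epoch noise (lognormal)
    evening_log_mu: float = math.log(0.6)  # indoor evening level, lognormal
    evening_log_sigma: float = 0.6
    dark_level: float = 0.002  # residual sensor reading during sleep
    lux_per_blue: float = 7.54  # crude broadband illuminance per blue unit

    # planted effects
    beta_nei_bmi: float = 0.08  # μW/cm² evening excess per BMI unit (at weight peak)
    effect_peak_hour: float = 23.5
    effect_halfwidth: float = 2.5  # hours, raised-cosine support
    restrict_to_g_carriers: bool = False
    beta_wt_bmi_g: float = -0.05  # °C per BMI unit, G-carriers only

    # hormone models
    leptin_base: float = 10.0
    leptin_slope_bmi: float = 1.0
    leptin_slope_waso: float = 0.05  # per WASO minute above 50
    leptin_noise_sd: float = 4.0
    cortisol_base: float = 300.0
    cortisol_slope_ddi: float = 0.3  # per μW/cm²·h above 330
    cortisol_slope_m10onset: float = -20.0  # per hour of blue M10 onset after 08:00
    cortisol_noise_sd: float = 60.0

    # cohort composition
    bmi_mean: float = 24.2
    bmi_sd: float = 4.6
    female_frac: float = 0.82
    native_frac: float = 0.39
    age_mean: float = 36.0
    age_sd: float = 14.0
    g_carrier_freq: float = 0.44  # carrier frequency of the MTNR1B G allele

    # analysis parameters used for realized WASO/DDI inside the generator
    cole_scale: float = 1000.0
    onset_rule: int = 5

    def validate(self) -> None:
        for name in (
            "activity_noise_sd", "activity_sleep_sd", "wt_noise_sd",
            "sleep_between_sd", "sleep_night_jitter_sd", "leptin_noise_sd",
            "cortisol_noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be ≥ 0")
        for name in ("female_frac", "native_frac", "g_carrier_freq"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ParameterError(f"{name} must lie in [0, 1]")
        if self.n_participants < 0:
            raise ParameterError("n_participants must be ≥ 0")
        if self.days < 1 or self.epoch_length <= 0:
            raise ParameterError("days ≥ 1 and epoch_length > 0 required")


@dataclass
class PlantedTruth:
    """Ground truth stored alongside the cohort for recovery tests."""

    beta_nei_bmi: float
    effect_peak_hour: float
    restrict_to_g_carriers: bool
    beta_wt_bmi_g: float
    excess_level: dict[str, float] = field(default_factory=dict)  # per participant
    wt_mesor: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class Cohort:
    participants: list[tuple[EpochSeries, ParticipantMeta]]
    truth: PlantedTruth

    def __len__(self) -> int:
        return len(self.participants)

    def meta_frame(self) -> pd.DataFrame:
        rows = []
        for _, m in self.participants:
            rows.append(
                {
                    "participant_id": m.participant_id,
                    "bmi": m.bmi,
                    "leptin": m.leptin,
                    "cortisol": m.cortisol,
                    "sex": m.sex,
                    "age": m.age,
                    "population": m.population,
                    "genotype": m.genotype,
                    "g_carrier": m.g_carrier,
                }
            )
        return pd.DataFrame(rows)


def _raised_cosine_weight(clock_hours: np.ndarray, peak: float, halfwidth: float) -> np.ndarray:
    delta = np.mod(clock_hours - peak + 12.0, 24.0) - 12.0
    w = np.where(np.abs(delta) <= halfwidth,
                 0.5 * (1.0 + np.cos(np.pi * delta / halfwidth)), 0.0)
    return w


def simulate_participant(
    meta: ParticipantMeta, config: SimConfig, rng: np.random.Generator
) -> EpochSeries:
    """Generate one participant's multichannel series with diary events."""
    config.validate()
    per_day = int(round(86400 / config.epoch_length))
    n = config.days * per_day
    step_h = config.epoch_length / 3600.0
    t_abs = np.arange(n) * step_h  # hours since local midnight, day 0
    clock = np.mod(t_abs, 24.0)

    pp = photoperiod(config.latitude, config.day_of_year)

    # --- individual sleep schedule -------------------------------------------------
    bed_p = config.bedtime_mean + rng.normal() * config.sleep_between_sd
    wake_p = config.waketime_mean + rng.normal() * config.sleep_between_sd
    asleep = np.zeros(n, dtype=bool)
    events: list[tuple[pd.Timestamp, str]] = []
    start = pd.Timestamp(f"{START_DATE} 00:00:00")

    wake0 = wake_p + rng.normal() * config.sleep_night_jitter_sd
    asleep[t_abs < wake0] = True
    events.append((start + pd.Timedelta(hours=float(wake0)), "waketime"))
    night_bounds = []
    for i in range(config.days):
        bed_i = 24.0 * i + bed_p + rng.normal() * config.sleep_night_jitter_sd
        wake_i = 24.0 * (i + 1) + wake_p + rng.normal() * config.sleep_night_jitter_sd
        asleep[(t_abs >= bed_i) & (t_abs < wake_i)] = True
        night_bounds.append((bed_i, min(wake_i, n * step_h)))
        if bed_i < n * step_h:
            events.append((start + pd.Timedelta(hours=float(bed_i)), "bedtime"))
        if wake_i < n * step_h:
            events.append((start + pd.Timedelta(hours=float(wake_i)), "waketime"))
    awake = ~asleep

    # nocturnal wake bouts (WASO): activity spikes inside each night
    in_bout = np.zeros(n, dtype=bool)
    for bed_i, wake_i in night_bounds:
        span = wake_i - bed_i
        if span <= 1.0:
            continue
        k = rng.poisson(config.waso_bouts_per_night)
        for _ in range(k):
            s = bed_i + 0.5 + rng.uniform() * (span - 1.0)
            length_h = max(1.0, rng.exponential(config.waso_bout_minutes)) / 60.0
            in_bout[(t_abs >= s) & (t_abs < s + length_h)] = True
    in_bout &= asleep

    # --- activity ------------------------------------------------------------------
    diurnal = 1.0 + config.activity_wake_amp_frac * np.cos(
        2 * np.pi * (clock - config.activity_acrophase) / 24.0
    )
    # hour-to-hour modulation fragments the wake rhythm (errands, desk work...)
    hour_idx = np.floor(t_abs).astype(int)
    hourly_factor = np.exp(
        rng.normal(0.0, 1.0, hour_idx[-1] + 1) * config.activity_hourly_sigma
    )[hour_idx]
    act = np.empty(n)
    act[awake] = config.activity_wake_mean * diurnal[awake] * hourly_factor[awake] + rng.normal(
        0.0, 1.0, awake.sum()
    ) * config.activity_noise_sd
    act[asleep] = np.abs(
        config.activity_sleep_mean
        + rng.normal(0.0, 1.0, asleep.sum()) * config.activity_sleep_sd
    )
    act[in_bout] = config.waso_activity + np.abs(
        rng.normal(0.0, 1.0, in_bout.sum()) * config.activity_noise_sd
    )
    act = np.clip(act, 0.0, None)

    # --- wrist temperature -----------------------------------------------------------
    wt_mesor = config.wt_mesor
    if meta.g_carrier and meta.bmi is not None:
        wt_mesor = wt_mesor + config.beta_wt_bmi_g * (meta.bmi - 25.0)
    wt = (
        wt_mesor
        + config.wt_amplitude * np.cos(2 * np.pi * (clock - config.wt_acrophase) / 24.0)
        + rng.normal(0.0, 1.0, n) * config.wt_noise_sd
    )

    # --- blue light ------------------------------------------------------------------
    if pp.kind == "polar_night":
        env = np.zeros(n)
    elif pp.kind == "polar_day":
        env = 0.5 * (1.0 + np.cos(2 * np.pi * (clock - 12.0) / 24.0))
    else:
        env = np.sin(np.pi * (clock - pp.sunrise) / pp.day_length)
        env[(clock < pp.sunrise) | (clock > pp.sunset)] = 0.0
        env = np.clip(env, 0.0, None)

    peak_p = config.blue_day_peak_median * math.exp(
        rng.normal() * config.blue_day_peak_sigma
    )
    evening_p = math.exp(config.evening_log_mu + rng.normal() * config.evening_log_sigma)
    noise1 = np.exp(rng.normal(0.0, 1.0, n) * config.blue_noise_sigma)
    noise2 = np.exp(rng.normal(0.0, 1.0, n) * config.blue_noise_sigma)
    blue = np.zeros(n)
    blue[awake] = (
        peak_p * env[awake] * noise1[awake]
        + evening_p * (1.0 - env[awake]) * noise2[awake]
    )
    blue[asleep] = config.dark_level * noise1[asleep]

    # planted evening excess covarying with BMI
    affected = (not config.restrict_to_g_carriers) or bool(meta.g_carrier)
    if affected and meta.bmi is not None and config.beta_nei_bmi != 0.0:
        w = _raised_cosine_weight(clock, config.effect_peak_hour, config.effect_halfwidth)
        blue = blue + config.beta_nei_bmi * (meta.bmi - 25.0) * w
    blue = np.clip(blue, 0.0, None)
    lux = blue * config.lux_per_blue

    return EpochSeries(
        participant_id=meta.participant_id,
        start_time=pd.Timestamp(f"{START_DATE} 00:00:00"),
        channels={"activity_pim": act, "wrist_temp": wt, "lux": lux, "blue": blue},
        valid=np.ones(n, dtype=bool),
        epoch_length=config.epoch_length,
        events=events,
    )


def simulate_cohort(config: SimConfig, ref: ReferenceCurve | None = None) -> Cohort:
    """Draw participant metadata, simulate recordings, attach hormones and truth.

    Hormone values are linear models on each participant's *realized* WASO
    (from the scored recording) and DDI / blue-light M10 onset (from the
    light-hygiene and rhythmometry modules), plus Gaussian noise.
    """
    config.validate()
    ref = ref or ReferenceCurve()
    ss = np.random.SeedSequence(config.seed)
    meta_seed, *child_seeds = ss.spawn(config.n_participants + 1)
    meta_rng = np.random.default_rng(meta_seed)

    truth = PlantedTruth(
        beta_nei_bmi=config.beta_nei_bmi,
        effect_peak_hour=config.effect_peak_hour,
        restrict_to_g_carriers=config.restrict_to_g_carriers,
        beta_wt_bmi_g=config.beta_wt_bmi_g,
    )
    participants: list[tuple[EpochSeries, ParticipantMeta]] = []
    for i in range(config.n_participants):
        pid = f"P{i + 1:03d}"
        bmi = float(np.clip(meta_rng.normal(config.bmi_mean, config.bmi_sd), 16.0, 42.0))
        sex = "female" if meta_rng.uniform() < config.female_frac else "male"
        age = float(np.clip(meta_rng.normal(config.age_mean, config.age_sd), 12.0, 59.0))
        population = "native" if meta_rng.uniform() < config.native_frac else "non_native"
        if meta_rng.uniform() < config.g_carrier_freq:
            genotype = "GG" if meta_rng.uniform() < 0.15 else "CG"
        else:
            genotype = "CC"
        meta = ParticipantMeta(
            participant_id=pid, bmi=bmi, sex=sex, age=age,
            population=population, genotype=genotype,
        )
        rng = np.random.default_rng(child_seeds[i])
        series = simulate_participant(meta, config, rng)

        nights = sleep_summary(
            series, scale=config.cole_scale, onset_rule=config.onset_rule
        )
        sleep_means = mean_sleep_parameters(nights)
        waso = sleep_means.get("waso", 50.0)
        li = light_indices_for_series(series, ref)
        np_blue = nonparametric_indices(series, "blue")

        meta.leptin = float(
            max(
                0.1,
                config.leptin_base
                + config.leptin_slope_bmi * (bmi - 25.0)
                + config.leptin_slope_waso * (waso - 50.0)
                + meta_rng.normal() * config.leptin_noise_sd,
            )
        )
        meta.cortisol = float(
            max(
                1.0,
                config.cortisol_base
                + config.cortisol_slope_ddi * (li.ddi_bl - 330.0)
                + config.cortisol_slope_m10onset * (np_blue.m10_onset - 8.0)
                + meta_rng.normal() * config.cortisol_noise_sd,
            )
        )

        affected = (not config.restrict_to_g_carriers) or bool(meta.g_carrier)
        truth.excess_level[pid] = (
            config.beta_nei_bmi * (bmi - 25.0) if affected else 0.0
        )
        truth.wt_mesor[pid] = config.wt_mesor + (
            config.beta_wt_bmi_g * (bmi - 25.0) if meta.g_carrier else 0.0
        )
        participants.append((series, meta))
    return Cohort(participants=participants, truth=truth)
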