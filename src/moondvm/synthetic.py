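"""Synthetic study generator: environment fields, GLMM-structured densities,
sampling schedules, and rendered shadowgraph frames.

Every downstream stage of the pipeline is testable against ground truth
produced here. Two generation modes exist:

* **density mode** — gamma bin densities drawn directly from the log-link
  mixed model (the published coefficient tables are the default generating
  truth), consumed by the statistics module for exact parameter-recovery
  tests;
* **individual mode** — Poisson placement of individual organisms from the
  bin densities (or from a calibrated depth distribution), rendered as dark
  silhouettes in bright collimated-light frames matching the imager optics
  (43 × 52 mm field, 10 cm path, 21 µm pixels, 2.4 frames/s at a 5 m/min
  descent), exercising the full segmentation → assembly → fit chain with
  the extra dispersion real counting introduces.

The default study layout mirrors the field campaign: four late-summer 2022
dates at a clear temperate lake (two near new moon, two near full moon),
one daylight profile per date plus a half-hourly night series, a 16.7 m
water column in 10 cm bins, and stratified temperature / deep
chlorophyll-a / deeper phycoerythrin / well-oxygenated water.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date as date_cls
from datetime import datetime, timedelta, timezone

import numpy as np
import pandas as pd
from scipy import optimize as sp_optimize
from scipy import stats as sp_stats
from skimage.draw import ellipse as draw_ellipse
from skimage.draw import line as draw_line

from . import glmm
from .assembly import SIZE_CLASS_RANGES, SIZE_CLASSES
from .imaging import Frame
from .lightfield import (
    LightProfile,
    SkyModelParams,
    attenuate_profile,
    lunar_state,
    make_bin_edges,
    solar_altitude,
    surface_illuminance,
)

__all__ = [
    "STUDY_LAT",
    "STUDY_LON",
    "SAMPLING_DATES",
    "MOON_CONDITIONS",
    "DAYNIGHT_COEFFICIENTS",
    "NIGHT_COEFFICIENTS",
    "DAYNIGHT_RANDOM_VARIANCES",
    "NIGHT_RANDOM_VARIANCES",
    "Optics",
    "EnvironmentConfig",
    "EnvironmentProfile",
    "ProfileSchedule",
    "GeneratorConfig",
    "make_environment",
    "schedule_profiles",
    "make_night_design",
    "make_daynight_design",
    "simulate_bin_densities",
    "place_individuals",
    "truncated_normal_params",
    "make_calibrated_individuals",
    "render_profile_frames",
]

# Field site (clear temperate lake, virtually no light pollution)
STUDY_LAT = 53.1430
STUDY_LON = 13.0281

#: 2022 campaign dates: two near new moon, two near full moon.
SAMPLING_DATES = (
    date_cls(2022, 8, 25),
    date_cls(2022, 9, 13),
    date_cls(2022, 9, 29),
    date_cls(2022, 10, 12),
)
MOON_CONDITIONS = {
    date_cls(2022, 8, 25): "new",
    date_cls(2022, 9, 13): "full",
    date_cls(2022, 9, 29): "new",
    date_cls(2022, 10, 12): "full",
}

# ---------------------------------------------------------------------------
# Published coefficient tables (generating truth for recovery tests)
# ---------------------------------------------------------------------------

#: Day-night design (raw lux), per taxon; term order matches glmm.DAYNIGHT_TERMS.
DAYNIGHT_COEFFICIENTS: dict[str, dict[str, float]] = {
    "cladoceran": {
        "intercept": 1.55,
        "lx": -3.98e-6,
        "size_medium": -3.31e-3,
        "size_large": -3.74e-3,
        "lx:size_medium": -1.80e-6,
        "lx:size_large": -5.52e-6,
    },
    "copepod": {
        "intercept": 1.75,
        "lx": -7.42e-6,
        "size_medium": -3.90e-3,
        "size_large": -1.70e-3,
        "lx:size_medium": -4.50e-6,
        "lx:size_large": -8.61e-6,
    },
}

#: (var_date, var_profile) reported alongside each day-night model.
DAYNIGHT_RANDOM_VARIANCES = {"cladoceran": (0.11, 0.03), "copepod": (0.01, 0.01)}

#: Night design (z-scored covariates), per taxon; order matches glmm.NIGHT_TERMS.
NIGHT_COEFFICIENTS: dict[str, dict[str, float]] = {
    "cladoceran": {
        "intercept": 1.58,
        "size_medium": -0.03,
        "size_large": -0.09,
        "lx": -0.03,
        "temp": 0.10,
        "chl": 0.10,
        "lx:size_medium": -0.01,
        "lx:size_large": 0.05,
        "temp:size_medium": 0.19,
        "temp:size_large": 0.43,
        "lx:temp": 0.12,
        "chl:size_medium": -0.04,
        "chl:size_large": -0.08,
        "lx:chl": -0.03,
        "lx:temp:size_medium": -0.08,
        "lx:temp:size_large": -0.24,
        "lx:chl:size_medium": 0.01,
        "lx:chl:size_large": 0.07,
    },
    "copepod": {
        "intercept": 1.71,
        "size_medium": -0.01,
        "size_large": -0.01,
        "lx": -0.02,
        "temp": -0.04,
        "chl": 0.17,
        "lx:size_medium": -0.00,
        "lx:size_large": 0.05,
        "temp:size_medium": -0.03,
        "temp:size_large": 0.17,
        "lx:temp": 0.11,
        "chl:size_medium": 0.06,
        "chl:size_large": 0.12,
        "lx:chl": -0.02,
        "lx:temp:size_medium": -0.09,
        "lx:temp:size_large": -0.15,
        "lx:chl:size_medium": -0.07,
        "lx:chl:size_large": -0.03,
    },
}

NIGHT_RANDOM_VARIANCES = {"cladoceran": (0.04, 0.02), "copepod": (0.00, 0.01)}


# ---------------------------------------------------------------------------
# Optics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Optics:
    """Imager geometry and descent kinematics."""

    frame_height_mm: float = 43.0
    frame_breadth_mm: float = 52.0
    path_mm: float = 100.0
    pixel_pitch_mm: float = 0.021
    frame_rate_hz: float = 2.4
    descent_m_per_min: float = 5.0

    @property
    def descent_per_frame_m(self) -> float:
        """Depth advanced between frames: (5 m/min)/(2.4 s^-1) = 34.72 mm."""
        return self.descent_m_per_min / 60.0 / self.frame_rate_hz

    @property
    def frame_height_m(self) -> float:
        return self.frame_height_mm / 1000.0

    def frame_shape(self, scale_factor: int = 1) -> tuple[int, int]:
        rows = int(round(self.frame_height_mm / self.pixel_pitch_mm)) // scale_factor
        cols = int(round(self.frame_breadth_mm / self.pixel_pitch_mm)) // scale_factor
        return rows, cols

    def bin_volume_L(self, bin_height_m: float = 0.1) -> float:
        """Water volume of a fully covered depth bin (0.52 L at 10 cm)."""
        return (self.frame_breadth_mm / 1000.0) * (self.path_mm / 1000.0) * bin_height_m * 1000.0


# ---------------------------------------------------------------------------
# Environment fields
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EnvironmentConfig:
    """Closed-form curves for a late-summer stratified clear lake.

    Temperature is a logistic thermocline; chlorophyll-a a baseline plus a
    Gaussian deep maximum; phycoerythrin a Gaussian centred deeper than the
    chlorophyll maximum (toxic cyanobacteria sit below the edible
    phytoplankton here); oxygen declines smoothly but stays above
    3 mg/L everywhere. Seeded noise perturbs the curve parameters, not the
    values, so the qualitative structure (monotone temperature, peak
    ordering) survives any seed.
    """

    surface_temp_C: float = 20.0
    bottom_temp_C: float = 8.0
    thermocline_depth_m: float = 6.0
    thermocline_width_m: float = 1.5
    chl_baseline_ugL: float = 2.0
    chl_peak_ugL: float = 4.0
    chl_peak_depth_m: float = 8.0
    chl_peak_width_m: float = 2.0
    pe_baseline: float = 0.5
    pe_peak: float = 3.0
    pe_peak_depth_m: float = 10.5
    pe_peak_width_m: float = 2.0
    oxygen_surface_mgL: float = 10.0
    oxygen_bottom_mgL: float = 6.0
    parameter_jitter: float = 0.05   # relative SD applied to curve parameters
    lake_depth_m: float = 16.7
    grid_step_m: float = 0.5

    def depth_grid(self) -> np.ndarray:
        g = np.arange(0.0, self.lake_depth_m - 1e-9, self.grid_step_m)
        return np.append(g, self.lake_depth_m)


@dataclass(frozen=True)
class EnvironmentProfile:
    """Depth-resolved temperature / chl-a / phycoerythrin / oxygen."""

    depth_grid: np.ndarray
    temperature: np.ndarray
    chl_a: np.ndarray
    phycoerythrin: np.ndarray
    oxygen: np.ndarray

    def interp(self, field_name: str, depths: np.ndarray) -> np.ndarray:
        return np.interp(depths, self.depth_grid, getattr(self, field_name))


def make_environment(
    config: EnvironmentConfig | None = None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> EnvironmentProfile:
    """One realization of the environmental depth fields."""
    cfg = config or EnvironmentConfig()
    if rng is None:
        rng = np.random.default_rng(seed)
    j = cfg.parameter_jitter

    def jitter(x: float, scale: float | None = None) -> float:
        return x * (1.0 + j * rng.standard_normal()) if scale is None else x + scale * rng.standard_normal()

    z = cfg.depth_grid()
    t_surf = jitter(cfg.surface_temp_C)
    t_bot = min(jitter(cfg.bottom_temp_C), t_surf - 1.0)
    zc = jitter(cfg.thermocline_depth_m)
    if not (0.0 < zc < cfg.lake_depth_m):
        raise ValueError(f"thermocline depth {zc:.2f} m outside the water column")
    w = max(jitter(cfg.thermocline_width_m), 0.2)
    temperature = t_bot + (t_surf - t_bot) / (1.0 + np.exp((z - zc) / w))

    chl_depth = jitter(cfg.chl_peak_depth_m)
    pe_depth = jitter(cfg.pe_peak_depth_m)
    if pe_depth <= chl_depth:  # enforce the deeper-phycoerythrin structure
        pe_depth = chl_depth + max(cfg.pe_peak_depth_m - cfg.chl_peak_depth_m, 0.5)
    chl = cfg.chl_baseline_ugL + jitter(cfg.chl_peak_ugL) * np.exp(
        -((z - chl_depth) ** 2) / (2.0 * cfg.chl_peak_width_m**2)
    )
    pe = cfg.pe_baseline + jitter(cfg.pe_peak) * np.exp(
        -((z - pe_depth) ** 2) / (2.0 * cfg.pe_peak_width_m**2)
    )
    oxygen = np.maximum(
        cfg.oxygen_bottom_mgL
        + (jitter(cfg.oxygen_surface_mgL) - cfg.oxygen_bottom_mgL)
        / (1.0 + np.exp((z - zc) / max(w, 0.2))),
        3.0,
    )
    return EnvironmentProfile(
        depth_grid=z, temperature=temperature, chl_a=chl, phycoerythrin=pe, oxygen=oxygen
    )


# ---------------------------------------------------------------------------
# Sampling schedule
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProfileSchedule:
    """Profile times for one sampling date."""

    date: date_cls
    profile_times: tuple[datetime, ...]
    labels: tuple[str, ...]          # "day" or "night-series"
    moon_condition: str              # "new" | "full"
    warning: str | None = None

    def __post_init__(self) -> None:
        times = self.profile_times
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("profile times must be strictly increasing")
        if self.labels.count("day") != 1:
            raise ValueError("exactly one day profile per date")


def _sunset_utc(day: date_cls, lat: float, lon: float) -> datetime:
    """Evening instant the sun's geometric altitude crosses 0 (minute scan + bisection)."""
    t = datetime(day.year, day.month, day.day, 12, 0, tzinfo=timezone.utc)
    prev = solar_altitude(t, lat, lon)
    for minute in range(1, 12 * 60):
        t2 = t + timedelta(minutes=1)
        alt = solar_altitude(t2, lat, lon)
        if prev >= 0.0 > alt:
            lo, hi = t, t2
            for _ in range(20):
                mid = lo + (hi - lo) / 2
                if solar_altitude(mid, lat, lon) >= 0:
                    lo = mid
                else:
                    hi = mid
            return lo + (hi - lo) / 2
        t, prev = t2, alt
    raise ValueError(f"no sunset found on {day} at ({lat}, {lon})")


def _solar_depression_time(day: date_cls, lat: float, lon: float, depression_deg: float) -> datetime:
    """Evening instant the sun reaches the given depression below the horizon."""
    t = _sunset_utc(day, lat, lon)
    while solar_altitude(t, lat, lon) > -depression_deg:
        t += timedelta(minutes=1)
    return t


def schedule_profiles(
    dates,
    lat: float = STUDY_LAT,
    lon: float = STUDY_LON,
    moon_conditions: dict | None = None,
    cadence_min: float = 30.0,
    night_hours_new: float = 5.0,
    moon_altitude_stop_deg: float = 50.0,
    day_profile_utc_hour: float = 15.0,
) -> list[ProfileSchedule]:
    """Sampling schedule: one day profile plus a half-hourly night series.

    The day profile is at ~16:00 CET (15:00 UTC); the night series starts
    30 min before sunset and runs half-hourly for ``night_hours_new`` hours
    on new-moon dates, or until the moon reaches 50° altitude on full-moon
    dates (falling back to 5.5 h with a warning if it never does).
    """
    moon_conditions = moon_conditions or MOON_CONDITIONS
    schedules = []
    for day in dates:
        condition = moon_conditions.get(day, "new")
        day_time = datetime(day.year, day.month, day.day, tzinfo=timezone.utc) + timedelta(
            hours=day_profile_utc_hour
        )
        start = _sunset_utc(day, lat, lon) - timedelta(minutes=30)
        step = timedelta(minutes=cadence_min)
        times, warning = [day_time], None
        # the night window is counted from sunset, so the series spans
        # [sunset - 30 min, sunset + night_hours]: e.g. 12 half-hourly profiles
        if condition == "new":
            n_steps = int(round((night_hours_new * 60.0 + 30.0) / cadence_min))
            times += [start + i * step for i in range(n_steps + 1)]
        else:
            max_steps = int(round((5.5 * 60.0 + 30.0) / cadence_min))
            i, stopped = 0, False
            while i <= max_steps:
                t = start + i * step
                if lunar_state(t, lat, lon).lunar_altitude >= moon_altitude_stop_deg:
                    stopped = True
                    break
                times.append(t)
                i += 1
            if not stopped:
                warning = (
                    f"moon never reached {moon_altitude_stop_deg} deg on {day}; "
                    "night series capped at 5.5 h"
                )
        labels = ("day",) + ("night-series",) * (len(times) - 1)
        schedules.append(
            ProfileSchedule(
                date=day,
                profile_times=tuple(times),
                labels=labels,
                moon_condition=condition,
                warning=warning,
            )
        )
    return schedules


# ---------------------------------------------------------------------------
# Design tables (density mode)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneratorConfig:
    """Defaults of the density-mode generator (the study conditions)."""

    taxon: str = "cladoceran"
    design: str = "night"
    sigma_date: float = 0.2        # random-intercept SD, sqrt of the reported 0.04
    sigma_profile: float = 0.14    # sqrt of the reported 0.02
    gamma_shape: float = 2.0
    lake_depth_m: float = 16.7
    bin_height_m: float = 0.1
    kd_per_m: float = 0.25
    day_lux_cap: float = 10_000.0  # keeps raw-lux day-night slopes exercisable
    optics: Optics = field(default_factory=Optics)
    environment: EnvironmentConfig = field(default_factory=EnvironmentConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gamma_shape <= 0:
            raise ValueError("gamma_shape must be positive")
        n_bins = self.lake_depth_m / self.bin_height_m
        if abs(n_bins - round(n_bins)) > 1e-9:
            raise ValueError("bin_height must divide lake_depth exactly")

    @property
    def n_bins(self) -> int:
        return int(round(self.lake_depth_m / self.bin_height_m))

    def beta(self) -> dict[str, float]:
        table = NIGHT_COEFFICIENTS if self.design == "night" else DAYNIGHT_COEFFICIENTS
        return dict(table[self.taxon])


def _profile_covariate_rows(
    pid: str,
    day: date_cls,
    t: datetime,
    env: EnvironmentProfile,
    light: LightProfile,
    n_bins: int,
    bin_height: float,
) -> list[dict]:
    mids = (np.arange(n_bins) + 0.5) * bin_height
    temp = env.interp("temperature", mids)
    chl = env.interp("chl_a", mids)
    lx = light.illuminance_lx
    rows = []
    for b in range(n_bins):
        for cls in SIZE_CLASSES:
            rows.append(
                {
                    "date": day.isoformat(),
                    "profile_id": pid,
                    "time": t,
                    "bin_index": b,
                    "bin_mid_depth": mids[b],
                    "size_class": cls,
                    "illuminance_lx": lx[b],
                    "temperature_C": temp[b],
                    "chl_a_ugL": chl[b],
                }
            )
    return rows


def make_night_design(
    config: GeneratorConfig | None = None,
    n_profiles_per_date: tuple[int, ...] = (13, 14, 13, 14),
    dates=SAMPLING_DATES,
    lat: float = STUDY_LAT,
    lon: float = STUDY_LON,
    seed: int | None = None,
    return_artifacts: bool = False,
):
    """Covariate table for the night model: 54 profiles × 167 bins × 3 classes.

    Night profiles run half-hourly from the end of civil twilight of each
    date; surface illuminance comes from the sky model at the actual lunar
    geometry of the date, attenuated into 10 cm bins, so new-moon dates are
    dark throughout and full-moon dates brighten as the moon climbs.

    With ``return_artifacts`` the per-date environments and per-profile
    light profiles are returned alongside the table.
    """
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    edges = make_bin_edges(cfg.lake_depth_m, cfg.bin_height_m)
    rows: list[dict] = []
    envs: dict[str, EnvironmentProfile] = {}
    lights: dict[str, LightProfile] = {}
    for day, n_prof in zip(dates, n_profiles_per_date):
        env = make_environment(cfg.environment, rng=rng)
        envs[day.isoformat()] = env
        start = _solar_depression_time(day, lat, lon, 6.0)
        for i in range(n_prof):
            t = start + timedelta(minutes=30 * i)
            sky = lunar_state(t, lat, lon)
            surface = surface_illuminance(sky, SkyModelParams())
            light = attenuate_profile(surface, cfg.kd_per_m, edges)
            pid = f"{day.isoformat()}_n{i:02d}"
            lights[pid] = light
            rows += _profile_covariate_rows(pid, day, t, env, light, cfg.n_bins, cfg.bin_height_m)
    table = pd.DataFrame(rows)
    if return_artifacts:
        return table, envs, lights
    return table


def make_daynight_design(
    config: GeneratorConfig | None = None,
    n_profiles_per_date: tuple[int, ...] = (17, 18, 17, 18),
    dates=SAMPLING_DATES,
    lat: float = STUDY_LAT,
    lon: float = STUDY_LON,
    seed: int | None = None,
    return_artifacts: bool = False,
):
    """Covariate table for the day-night model: 70 profiles × 167 bins × 3 classes.

    Each date contributes one daylight profile (~16:00 CET) and a series
    from 30 min before sunset; lux stays on its raw scale, with daytime
    surface values capped so the day-night contrast remains numerically
    exercisable against the small printed per-lx slopes.
    """
    cfg = config or GeneratorConfig(design="daynight")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    edges = make_bin_edges(cfg.lake_depth_m, cfg.bin_height_m)
    rows: list[dict] = []
    envs: dict[str, EnvironmentProfile] = {}
    lights: dict[str, LightProfile] = {}
    for day, n_prof in zip(dates, n_profiles_per_date):
        env = make_environment(cfg.environment, rng=rng)
        envs[day.isoformat()] = env
        day_time = datetime(day.year, day.month, day.day, 15, 0, tzinfo=timezone.utc)
        start = _sunset_utc(day, lat, lon) - timedelta(minutes=30)
        times = [day_time] + [start + timedelta(minutes=30 * i) for i in range(n_prof - 1)]
        for i, t in enumerate(times):
            sky = lunar_state(t, lat, lon)
            surface = min(surface_illuminance(sky, SkyModelParams()), cfg.day_lux_cap)
            light = attenuate_profile(surface, cfg.kd_per_m, edges)
            pid = f"{day.isoformat()}_p{i:02d}"
            lights[pid] = light
            rows += _profile_covariate_rows(pid, day, t, env, light, cfg.n_bins, cfg.bin_height_m)
    table = pd.DataFrame(rows)
    if return_artifacts:
        return table, envs, lights
    return table


def simulate_bin_densities(
    design_table: pd.DataFrame,
    beta: dict[str, float] | pd.Series,
    sigma_date: float,
    sigma_profile: float,
    gamma_shape: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    spec: glmm.GlmmSpec | None = None,
) -> pd.DataFrame:
    """Draw gamma bin densities from the log-link mixed model.

    eta = X beta + u_date + u_profile with u ~ Normal(0, sigma^2);
    density ~ Gamma(shape, mean = exp(eta)). The returned table is the
    design table with a strictly positive ``density`` column appended.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    spec = spec or glmm.GlmmSpec(design="night")
    X, _ = glmm.design_matrix(design_table, spec)
    b = pd.Series(beta).reindex(list(spec.terms))
    if b.isna().any():
        missing = list(b.index[b.isna()])
        raise ValueError(f"beta is missing terms {missing}")
    eta = X @ b.to_numpy()
    date_lv, date_idx = np.unique(design_table["date"].to_numpy(), return_inverse=True)
    prof_lv, prof_idx = np.unique(design_table["profile_id"].to_numpy(), return_inverse=True)
    eta = eta + rng.normal(0.0, sigma_date, len(date_lv))[date_idx]
    eta = eta + rng.normal(0.0, sigma_profile, len(prof_lv))[prof_idx]
    if not np.all(np.isfinite(eta)):
        bad = int(np.flatnonzero(~np.isfinite(eta))[0])
        raise ValueError(f"non-finite linear predictor at design row {bad}")
    out = design_table.copy()
    out["density"] = rng.gamma(gamma_shape, np.exp(eta) / gamma_shape)
    return out


# ---------------------------------------------------------------------------
# Individual mode
# ---------------------------------------------------------------------------

INDIVIDUAL_COLUMNS = (
    "profile_id",
    "taxon",
    "depth_m",
    "esd_true_mm",
    "lateral_mm",
    "axis_ratio",
    "antenna",
    "size_class",
)


def _draw_shape(taxon: str, rng: np.random.Generator) -> tuple[float, bool]:
    if taxon == "copepod":
        return float(rng.uniform(2.2, 3.0)), True
    return float(rng.uniform(1.2, 1.8)), False


def place_individuals(
    bin_densities: pd.DataFrame,
    optics: Optics | None = None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    bin_height_m: float = 0.1,
) -> pd.DataFrame:
    """Poisson placement of countable organisms from bin densities.

    Per table row, count ~ Poisson(density × fully covered bin volume);
    depths are uniform within the bin, ESDs uniform within the row's
    taxon/size-class range, lateral offsets uniform across the frame
    breadth.
    """
    optics = optics or Optics()
    if rng is None:
        rng = np.random.default_rng(seed)
    vol = optics.bin_volume_L(bin_height_m)
    rows = []
    for rec in bin_densities.itertuples(index=False):
        n = rng.poisson(rec.density * vol)
        if n == 0:
            continue
        lo, hi = SIZE_CLASS_RANGES[rec.taxon][rec.size_class]
        z0 = rec.bin_index * bin_height_m
        for _ in range(n):
            ratio, antenna = _draw_shape(rec.taxon, rng)
            rows.append(
                {
                    "profile_id": rec.profile_id,
                    "taxon": rec.taxon,
                    "depth_m": z0 + rng.uniform(0.0, bin_height_m),
                    "esd_true_mm": rng.uniform(lo, hi),
                    "lateral_mm": rng.uniform(0.0, optics.frame_breadth_mm),
                    "axis_ratio": ratio,
                    "antenna": antenna,
                    "size_class": rec.size_class,
                }
            )
    return pd.DataFrame(rows, columns=list(INDIVIDUAL_COLUMNS))


def truncated_normal_params(
    mean: float, sd: float, lower: float, upper: float
) -> tuple[float, float]:
    """(loc, scale) of a normal whose [lower, upper] truncation has the
    requested mean and SD."""

    def residual(p):
        loc, log_scale = p
        scale = math.exp(log_scale)
        a, b = (lower - loc) / scale, (upper - loc) / scale
        m, v = sp_stats.truncnorm.stats(a, b, loc=loc, scale=scale, moments="mv")
        return [m - mean, math.sqrt(v) - sd]

    sol = sp_optimize.fsolve(residual, [mean, math.log(sd)], full_output=True)
    p, info, ok, msg = sol
    if ok != 1:
        raise RuntimeError(f"truncated-normal calibration failed: {msg}")
    return float(p[0]), float(math.exp(p[1]))


def make_calibrated_individuals(
    profile_ids,
    mean_depth_m: float,
    sd_depth_m: float,
    expected_per_profile: float = 400.0,
    taxon: str = "cladoceran",
    size_classes: tuple[str, ...] = ("medium", "large"),
    lake_depth_m: float = 16.7,
    optics: Optics | None = None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Individuals whose depth distribution is a calibrated truncated normal.

    The underlying normal is solved so that the [0, lake_depth] truncation
    itself has the requested mean and SD — the generating condition for
    end-to-end recovery of a reported mean depth.
    """
    optics = optics or Optics()
    if rng is None:
        rng = np.random.default_rng(seed)
    loc, scale = truncated_normal_params(mean_depth_m, sd_depth_m, 0.0, lake_depth_m)
    a, b = (0.0 - loc) / scale, (lake_depth_m - loc) / scale
    rows = []
    for pid in profile_ids:
        n = rng.poisson(expected_per_profile)
        depths = sp_stats.truncnorm.rvs(a, b, loc=loc, scale=scale, size=n, random_state=rng)
        for d in depths:
            cls = size_classes[rng.integers(len(size_classes))]
            lo, hi = SIZE_CLASS_RANGES[taxon][cls]
            ratio, antenna = _draw_shape(taxon, rng)
            rows.append(
                {
                    "profile_id": pid,
                    "taxon": taxon,
                    "depth_m": float(d),
                    "esd_true_mm": rng.uniform(lo, hi),
                    "lateral_mm": rng.uniform(0.0, optics.frame_breadth_mm),
                    "axis_ratio": ratio,
                    "antenna": antenna,
                    "size_class": cls,
                }
            )
    return pd.DataFrame(rows, columns=list(INDIVIDUAL_COLUMNS))


# ---------------------------------------------------------------------------
# Frame rendering
# ---------------------------------------------------------------------------

def _silhouette_axes_mm(esd_mm: float, ratio: float) -> tuple[float, float]:
    """Major/minor ellipse diameters whose prolate-spheroid ESD is esd_mm."""
    major = esd_mm * ratio ** (2.0 / 3.0)
    minor = esd_mm * ratio ** (-1.0 / 3.0)
    return major, minor


def render_profile_frames(
    individuals: pd.DataFrame,
    optics: Optics | None = None,
    lake_depth_m: float = 16.7,
    *,
    profile_id: str | None = None,
    scale_factor: int = 1,
    illumination_gradient: float = 0.2,
    noise_sd: float = 2.0,
    background_level: float = 200.0,
    silhouette_level: float = 40.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> list[Frame]:
    """Render a profile's descending frame sequence with dark silhouettes.

    Frame k spans [k·Δ, k·Δ + 0.043 m] with Δ the per-frame descent
    (34.72 mm), so consecutive frames overlap by ~8.3 mm. The background is
    bright with a smooth multiplicative illumination gradient plus Gaussian
    noise; each in-span individual is an ellipse (plus thin antenna strokes
    for copepods) whose prolate-spheroid ESD equals its true ESD. A frame's
    recorded depth is its top edge; row 0 is the shallowest row.
    """
    optics = optics or Optics()
    if scale_factor not in (1, 2, 4, 8):
        raise ValueError("scale_factor must be one of 1, 2, 4, 8")
    if rng is None:
        rng = np.random.default_rng(seed)
    if len(individuals) and individuals["depth_m"].max() > lake_depth_m:
        deepest = individuals["depth_m"].max()
        raise ValueError(f"individual at {deepest:.2f} m deeper than profile bottom {lake_depth_m} m")
    if profile_id is None:
        profile_id = str(individuals["profile_id"].iloc[0]) if len(individuals) else "profile"

    rows_px, cols_px = optics.frame_shape(scale_factor)
    pitch = optics.pixel_pitch_mm * scale_factor
    height_m = rows_px * pitch / 1000.0
    delta = optics.descent_per_frame_m
    n_frames = max(int(math.ceil((lake_depth_m - height_m) / delta)) + 1, 1)

    # smooth multiplicative illumination field, fixed across the profile
    col_ramp = 1.0 + illumination_gradient * (np.linspace(0, 1, cols_px) - 0.5)
    row_ramp = 1.0 + 0.25 * illumination_gradient * (np.linspace(0, 1, rows_px) - 0.5)
    illumination = background_level * np.outer(row_ramp, col_ramp)

    depths = individuals["depth_m"].to_numpy(dtype=float) if len(individuals) else np.array([])
    frames = []
    for k in range(n_frames):
        top = k * delta
        img = illumination.copy()
        if noise_sd > 0:
            img = img + rng.normal(0.0, noise_sd, img.shape)
        if len(individuals):
            in_span = (depths >= top) & (depths < top + height_m)
            for rec in individuals.loc[in_span].itertuples(index=False):
                _draw_individual(img, rec, top, pitch, silhouette_level, rng)
        pixels = np.clip(img, 0, 255).astype(np.uint8)
        frames.append(
            Frame(
                pixels=pixels,
                pixel_pitch_mm=pitch,
                top_depth_m=top,
                profile_id=profile_id,
                frame_index=k,
            )
        )
    return frames


def _draw_individual(img: np.ndarray, rec, top_m: float, pitch_mm: float,
                     level: float, rng: np.random.Generator) -> None:
    row_c = (rec.depth_m - top_m) * 1000.0 / pitch_mm
    col_c = rec.lateral_mm / pitch_mm
    major_mm, minor_mm = _silhouette_axes_mm(rec.esd_true_mm, rec.axis_ratio)
    semi_major = max(major_mm / 2.0 / pitch_mm, 0.6)
    semi_minor = max(minor_mm / 2.0 / pitch_mm, 0.6)
    angle = rng.uniform(0.0, math.pi)
    rr, cc = draw_ellipse(
        row_c, col_c, semi_minor, semi_major, shape=img.shape, rotation=angle
    )
    img[rr, cc] = level
    if rec.antenna:
        # two thin strokes from the anterior pole, splayed off the body axis
        tip_r = row_c + semi_major * math.sin(-angle)
        tip_c = col_c + semi_major * math.cos(-angle)
        length = 1.4 * semi_major
        for sign in (-1.0, 1.0):
            theta = -angle + sign * math.radians(30.0)
            end_r = int(round(tip_r + length * math.sin(theta)))
            end_c = int(round(tip_c + length * math.cos(theta)))
            rr, cc = draw_line(int(round(tip_r)), int(round(tip_c)), end_r, end_c)
            ok = (rr >= 0) & (rr < img.shape[0]) & (cc >= 0) & (cc < img.shape[1])
            img[rr[ok], cc[ok]] = level
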