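"""Sky geometry and the underwater light field.

This module models everything between celestial mechanics and the lux value a
zooplankter experiences in a 10 cm depth bin:

* low-precision solar and lunar ephemerides (truncated Meeus series, good to
  roughly half a degree of altitude and ~1% of lunar illuminated fraction);
* twilight phase classification from solar altitude;
* a simplified surface-illuminance model: a piecewise daylight/twilight curve
  for the Sun, a Krisciunas–Schaefer-style brightness law for the Moon
  (phase-angle magnitude term, airmass extinction, inverse-square distance),
  a fixed starlight baseline, and a multiplicative cloud-transmission factor
  per okta;
* Beer–Lambert attenuation into half-open 10 cm depth bins with a scotopic
  floor (values below 0.001 lx are treated as zero);
* photometric/radiometric conversions through the CIE 1931 photopic
  luminosity function V(λ).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import datetime, timezone

import numpy as np

__all__ = [
    "SkyState",
    "LightProfile",
    "SkyModelParams",
    "julian_date",
    "solar_altitude",
    "solar_position",
    "classify_twilight",
    "lunar_state",
    "surface_illuminance",
    "attenuate_profile",
    "make_bin_edges",
    "photopic_sensitivity",
    "lux_to_irradiance",
    "irradiance_to_photon_flux",
    "lux_to_photon_flux",
]

DEG = math.pi / 180.0

# Physical constants (SI)
_PLANCK = 6.62607015e-34      # J s
_LIGHTSPEED = 2.99792458e8    # m/s
_AVOGADRO = 6.02214076e23     # 1/mol
_AU_KM = 149_597_870.7
_MEAN_LUNAR_DISTANCE_KM = 385_000.56
_EARTH_RADIUS_KM = 6378.14

# Luminous efficacy of monochromatic 555 nm radiation, lm/W
_KCD_MAX = 683.0


# ---------------------------------------------------------------------------
# Time and validation helpers
# ---------------------------------------------------------------------------

def _as_utc(t: datetime) -> datetime:
    if not isinstance(t, datetime):
        raise TypeError(f"expected a datetime, got {type(t).__name__}")
    if t.tzinfo is None:
        return t.replace(tzinfo=timezone.utc)
    return t.astimezone(timezone.utc)


def julian_date(t: datetime) -> float:
    """Julian date (UT) of a datetime; naive datetimes are taken as UTC."""
    t = _as_utc(t)
    y, m = t.year, t.month
    day = (
        t.day
        + (t.hour + (t.minute + (t.second + t.microsecond / 1e6) / 60.0) / 60.0) / 24.0
    )
    if m <= 2:
        y -= 1
        m += 12
    a = y // 100
    b = 2 - a + a // 4
    return math.floor(365.25 * (y + 4716)) + math.floor(30.6001 * (m + 1)) + day + b - 1524.5


def _check_latlon(lat: float, lon: float) -> None:
    if not (-90.0 <= lat <= 90.0):
        raise ValueError(f"latitude {lat} outside [-90, 90]")
    if not (-360.0 <= lon <= 360.0):
        raise ValueError(f"longitude {lon} outside [-360, 360]")


def _gmst_deg(jd: float) -> float:
    # Meeus eq. 12.4, mean sidereal time at Greenwich, degrees
    t = (jd - 2451545.0) / 36525.0
    gmst = (
        280.46061837
        + 360.98564736629 * (jd - 2451545.0)
        + 0.000387933 * t * t
        - t * t * t / 38710000.0
    )
    return gmst % 360.0


def _obliquity_deg(t: float) -> float:
    return 23.439291 - 0.0130042 * t - 1.64e-7 * t * t


def _altitude_deg(ra_deg: float, dec_deg: float, jd: float, lat: float, lon: float) -> float:
    h = (_gmst_deg(jd) + lon - ra_deg) % 360.0  # hour angle, degrees (east-positive lon)
    sin_alt = (
        math.sin(lat * DEG) * math.sin(dec_deg * DEG)
        + math.cos(lat * DEG) * math.cos(dec_deg * DEG) * math.cos(h * DEG)
    )
    return math.degrees(math.asin(max(-1.0, min(1.0, sin_alt))))


# ---------------------------------------------------------------------------
# Solar ephemeris (Meeus low precision, ch. 25)
# ---------------------------------------------------------------------------

def _solar_ecliptic(t: float) -> tuple[float, float]:
    """True ecliptic longitude (deg) and distance (AU) of the Sun."""
    l0 = 280.46646 + 36000.76983 * t + 0.0003032 * t * t
    m = 357.52911 + 35999.05029 * t - 0.0001537 * t * t
    mr = m * DEG
    c = (
        (1.914602 - 0.004817 * t - 0.000014 * t * t) * math.sin(mr)
        + (0.019993 - 0.000101 * t) * math.sin(2 * mr)
        + 0.000289 * math.sin(3 * mr)
    )
    true_lon = (l0 + c) % 360.0
    ecc = 0.016708634 - 0.000042037 * t - 0.0000001267 * t * t
    nu = (m + c) * DEG
    r_au = 1.000001018 * (1 - ecc * ecc) / (1 + ecc * math.cos(nu))
    return true_lon, r_au


def solar_position(time: datetime, lat: float, lon: float) -> tuple[float, float, float]:
    """Geometric solar (altitude_deg, ecliptic_longitude_deg, distance_au)."""
    _check_latlon(lat, lon)
    jd = julian_date(time)
    t = (jd - 2451545.0) / 36525.0
    lam, r_au = _solar_ecliptic(t)
    eps = _obliquity_deg(t) * DEG
    lam_r = lam * DEG
    ra = math.degrees(math.atan2(math.cos(eps) * math.sin(lam_r), math.cos(lam_r))) % 360.0
    dec = math.degrees(math.asin(math.sin(eps) * math.sin(lam_r)))
    return _altitude_deg(ra, dec, jd, lat, lon), lam, r_au


def solar_altitude(time: datetime, lat: float, lon: float) -> float:
    """Geometric altitude of the Sun in degrees (no refraction), in [-90, 90]."""
    return solar_position(time, lat, lon)[0]


TWILIGHT_PHASES = ("day", "civil", "nautical", "astronomical", "night")


def classify_twilight(solar_altitude_deg: float) -> str:
    """Map a solar altitude to {day, civil, nautical, astronomical, night}.

    Boundaries are assigned to the darker phase: day [0, 90], civil
    (-6, 0), nautical (-12, -6], astronomical (-18, -12], night [-90, -18].
    """
    h = float(solar_altitude_deg)
    if not (-90.0 <= h <= 90.0):
        raise ValueError(f"solar altitude {h} outside [-90, 90]")
    if h >= 0.0:
        return "day"
    if h > -6.0:
        return "civil"
    if h > -12.0:
        return "nautical"
    if h > -18.0:
        return "astronomical"
    return "night"


# ---------------------------------------------------------------------------
# Lunar ephemeris (truncated Meeus ch. 47 series)
# ---------------------------------------------------------------------------

# Largest periodic terms of the lunar longitude (deg) and distance (km) series,
# keyed by multiples of (D, M, M', F).
_LUNAR_LON_TERMS = [
    # (d, m, mp, f, sin_coeff_deg, cos_coeff_km)
    (0, 0, 1, 0, 6.288774, -20905.355),
    (2, 0, -1, 0, 1.274027, -3699.111),
    (2, 0, 0, 0, 0.658314, -2955.968),
    (0, 0, 2, 0, 0.213618, -569.925),
    (0, 1, 0, 0, -0.185116, 48.888),
    (0, 0, 0, 2, -0.114332, -3.149),
    (2, 0, -2, 0, 0.058793, 246.158),
    (2, -1, -1, 0, 0.057066, -152.138),
    (2, 0, 1, 0, 0.053322, -170.733),
    (2, -1, 0, 0, 0.045758, -204.586),
    (0, 1, -1, 0, -0.040923, -129.620),
    (1, 0, 0, 0, -0.034720, 108.743),
    (0, 1, 1, 0, -0.030383, 104.755),
    (2, 0, 0, -2, 0.015327, 10.321),
    (0, 0, 1, 2, -0.012528, 0.0),
    (0, 0, 1, -2, 0.010980, 79.661),
    (4, 0, -1, 0, 0.010675, -34.782),
    (0, 0, 3, 0, 0.010034, -23.210),
    (4, 0, -2, 0, 0.008548, -21.636),
    (2, 1, -1, 0, -0.007888, 24.208),
    (2, 1, 0, 0, -0.006766, 30.824),
    (1, 0, -1, 0, -0.005163, -8.379),
    (1, 1, 0, 0, 0.004987, -16.675),
    (2, -1, 1, 0, 0.004036, -12.831),
    (2, 0, 2, 0, 0.003994, -10.445),
    (4, 0, 0, 0, 0.003861, -11.650),
    (2, 0, -3, 0, 0.003665, 14.403),
]

_LUNAR_LAT_TERMS = [
    # (d, m, mp, f, sin_coeff_deg)
    (0, 0, 0, 1, 5.128122),
    (0, 0, 1, 1, 0.280602),
    (0, 0, 1, -1, 0.277693),
    (2, 0, 0, -1, 0.173237),
    (2, 0, -1, 1, 0.055413),
    (2, 0, -1, -1, 0.046271),
    (2, 0, 0, 1, 0.032573),
    (0, 0, 2, 1, 0.017198),
    (2, 0, 1, -1, 0.009266),
    (0, 0, 2, -1, 0.008822),
    (2, -1, 0, -1, 0.008216),
    (2, 0, -2, -1, 0.004324),
    (2, 0, 1, 1, 0.004200),
]


def _lunar_ecliptic(t: float) -> tuple[float, float, float]:
    """Geocentric lunar (longitude_deg, latitude_deg, distance_km)."""
    lp = 218.3164477 + 481267.88123421 * t - 0.0015786 * t * t
    d = 297.8501921 + 445267.1114034 * t - 0.0018819 * t * t
    m = 357.5291092 + 35999.0502909 * t - 0.0001536 * t * t
    mp = 134.9633964 + 477198.8675055 * t + 0.0087414 * t * t
    f = 93.2720950 + 483202.0175233 * t - 0.0036539 * t * t
    # eccentricity correction for terms involving the solar anomaly M
    e = 1.0 - 0.002516 * t - 0.0000074 * t * t

    lon = lp
    dist = 385000.56
    for dd, mm, mmp, ff, s_coeff, c_coeff in _LUNAR_LON_TERMS:
        arg = (dd * d + mm * m + mmp * mp + ff * f) * DEG
        scale = e ** abs(mm)
        lon += scale * s_coeff * math.sin(arg)
        dist += scale * c_coeff * math.cos(arg)
    lat = 0.0
    for dd, mm, mmp, ff, s_coeff in _LUNAR_LAT_TERMS:
        arg = (dd * d + mm * m + mmp * mp + ff * f) * DEG
        lat += (e ** abs(mm)) * s_coeff * math.sin(arg)
    return lon % 360.0, lat, dist


@dataclass(frozen=True)
class SkyState:
    """Solar/lunar geometry and sky condition at one instant and site."""

    time: datetime
    lat: float
    lon: float
    solar_altitude: float
    lunar_altitude: float
    lunar_phase_angle: float     # degrees; 0 = full moon, 180 = new moon
    illuminated_fraction: float  # (1 + cos phase_angle) / 2
    lunar_distance: float        # km, geocentric
    cloud_okta: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.cloud_okta <= 8):
            raise ValueError(f"cloud_okta {self.cloud_okta} outside 0..8")
        expected = (1.0 + math.cos(self.lunar_phase_angle * DEG)) / 2.0
        if abs(self.illuminated_fraction - expected) > 1e-9:
            raise ValueError("illuminated_fraction inconsistent with phase angle")


def lunar_state(
    time: datetime, lat: float, lon: float, cloud_okta: int = 0
) -> SkyState:
    """Solar and lunar geometry for one instant at a site.

    Uses a truncated Meeus series valid (here) for 1900–2100; the lunar
    altitude is corrected for topocentric parallax. Phase angle follows from
    the geocentric elongation and the Sun and Moon distances, and the
    illuminated fraction is (1 + cos i) / 2.
    """
    t_utc = _as_utc(time)
    if not (1900 <= t_utc.year <= 2100):
        raise ValueError(f"date {t_utc.date()} outside supported 1900-2100 window")
    _check_latlon(lat, lon)
    jd = julian_date(t_utc)
    t = (jd - 2451545.0) / 36525.0

    sun_alt, sun_lon, sun_r_au = solar_position(t_utc, lat, lon)
    moon_lon, moon_lat, moon_dist = _lunar_ecliptic(t)

    eps = _obliquity_deg(t) * DEG
    lam, beta = moon_lon * DEG, moon_lat * DEG
    ra = math.degrees(
        math.atan2(
            math.sin(lam) * math.cos(eps) - math.tan(beta) * math.sin(eps),
            math.cos(lam),
        )
    ) % 360.0
    dec = math.degrees(
        math.asin(
            math.sin(beta) * math.cos(eps) + math.cos(beta) * math.sin(eps) * math.sin(lam)
        )
    )
    alt_geo = _altitude_deg(ra, dec, jd, lat, lon)
    # first-order topocentric parallax correction (moon only; up to ~1 deg)
    parallax = math.degrees(math.asin(_EARTH_RADIUS_KM / moon_dist))
    alt_topo = alt_geo - parallax * math.cos(alt_geo * DEG)

    # phase angle from geocentric elongation (Meeus ch. 48)
    cos_psi = math.cos(beta) * math.cos((moon_lon - sun_lon) * DEG)
    psi = math.acos(max(-1.0, min(1.0, cos_psi)))
    sun_r_km = sun_r_au * _AU_KM
    phase = math.degrees(
        math.atan2(sun_r_km * math.sin(psi), moon_dist - sun_r_km * math.cos(psi))
    )
    frac = (1.0 + math.cos(phase * DEG)) / 2.0

    return SkyState(
        time=t_utc,
        lat=lat,
        lon=lon,
        solar_altitude=sun_alt,
        lunar_altitude=alt_topo,
        lunar_phase_angle=phase,
        illuminated_fraction=frac,
        lunar_distance=moon_dist,
        cloud_okta=cloud_okta,
    )


# ---------------------------------------------------------------------------
# Surface illuminance model
# ---------------------------------------------------------------------------

def _default_okta_transmission() -> tuple[float, ...]:
    # Kasten–Czeplak-flavoured transmission per okta; okta 0 = 1 by definition
    return (1.0, 0.96, 0.91, 0.85, 0.78, 0.69, 0.59, 0.46, 0.31)


@dataclass(frozen=True)
class SkyModelParams:
    """Tunables of the simplified surface-illuminance model.

    extinction_mag_per_airmass: atmospheric extinction applied to moonlight,
        magnitudes per airmass (0.25 ~ clear continental site).
    starlight_lx: moonless, sunless baseline (~1e-3 lx, integrated starlight
        plus airglow).
    okta_transmission: multiplicative cloud transmission, indexed by okta;
        must start at 1.0 and be non-increasing.
    daylight_lx: scale of the sin(altitude) daylight term.
    twilight_lx_at_horizon: illuminance when the sun sits on the horizon.
    twilight_decades_per_deg: log10-lux lost per degree of solar depression
        (chosen so the curve reaches ~1e-3 lx at -18 deg).
    """

    extinction_mag_per_airmass: float = 0.25
    starlight_lx: float = 0.001
    okta_transmission: tuple[float, ...] = field(default_factory=_default_okta_transmission)
    daylight_lx: float = 118_000.0
    twilight_lx_at_horizon: float = 500.0
    twilight_decades_per_deg: float = (math.log10(500.0) + 3.0) / 18.0

    def __post_init__(self) -> None:
        if self.extinction_mag_per_airmass is None or self.extinction_mag_per_airmass < 0:
            raise ValueError("extinction_mag_per_airmass must be a non-negative number")
        tr = tuple(self.okta_transmission)
        if len(tr) != 9 or abs(tr[0] - 1.0) > 1e-12 or any(
            b > a + 1e-12 for a, b in zip(tr, tr[1:])
        ):
            raise ValueError("okta_transmission must have 9 entries, start at 1.0, non-increasing")


def _airmass(altitude_deg: float) -> float:
    # Krisciunas & Schaefer (1991) optical pathlength approximation
    cos_z = math.sin(altitude_deg * DEG)
    return 1.0 / (cos_z + 0.025 * math.exp(-11.0 * cos_z))


def _solar_term_lx(h: float, p: SkyModelParams) -> float:
    if h >= 0.0:
        return p.twilight_lx_at_horizon + p.daylight_lx * math.sin(h * DEG)
    if h >= -18.0:
        return p.twilight_lx_at_horizon * 10.0 ** (p.twilight_decades_per_deg * h)
    return 0.0


def _lunar_term_lx(sky: SkyState, p: SkyModelParams) -> float:
    h = sky.lunar_altitude
    if h <= 0.0:
        return 0.0
    alpha = abs(sky.lunar_phase_angle)
    # apparent magnitude of the Moon vs phase angle (Krisciunas & Schaefer 1991)
    mag = -12.73 + 0.026 * alpha + 4.0e-9 * alpha ** 4
    # magnitude -14.18 delivers 1 lx outside the atmosphere
    e0 = 10.0 ** (-0.4 * (mag + 14.18))
    extinction = 10.0 ** (-0.4 * p.extinction_mag_per_airmass * _airmass(h))
    distance_sq = (_MEAN_LUNAR_DISTANCE_KM / sky.lunar_distance) ** 2
    return e0 * extinction * distance_sq * math.sin(h * DEG)


def surface_illuminance(sky: SkyState, params: SkyModelParams | None = None) -> float:
    """Total downwelling illuminance (lx) at the surface for one SkyState.

    Sum of a solar daylight/twilight term, a lunar term (phase-angle
    brightness law, airmass extinction, inverse-square distance, horizontal
    projection), and a starlight baseline, all scaled by the cloud
    transmission factor for the observed okta.
    """
    if params is None:
        params = SkyModelParams()
    total = (
        _solar_term_lx(sky.solar_altitude, params)
        + _lunar_term_lx(sky, params)
        + params.starlight_lx
    )
    return total * params.okta_transmission[sky.cloud_okta]


# ---------------------------------------------------------------------------
# Underwater attenuation
# ---------------------------------------------------------------------------

def make_bin_edges(max_depth_m: float, bin_height_m: float = 0.1) -> np.ndarray:
    """Half-open [z, z + bin) edges from the surface to max_depth."""
    n = math.ceil(round(max_depth_m / bin_height_m, 9))
    return np.round(np.arange(n + 1) * bin_height_m, 9)


@dataclass(frozen=True)
class LightProfile:
    """Per-depth-bin illuminance plus the surface and attenuation parameters."""

    bin_edges: np.ndarray       # metres, length n_bins + 1
    illuminance_lx: np.ndarray  # per bin, floored
    surface_lx: float
    kd_per_m: float
    wavelength_nm: float = 500.0
    floor_lx: float = 0.001

    @property
    def bin_mid_depth(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2.0

    @property
    def n_bins(self) -> int:
        return len(self.bin_edges) - 1


def attenuate_profile(
    surface_lx: float,
    kd_per_m: float,
    bin_edges: np.ndarray,
    floor_lx: float = 0.001,
    wavelength_nm: float = 500.0,
) -> LightProfile:
    """Beer–Lambert attenuation E(z) = E0 exp(-Kd z) at bin midpoints.

    Values below ``floor_lx`` are reported as exactly zero — the lowest
    scotopic sensitivity recorded in fish, below which light is treated as
    behaviourally irrelevant.
    """
    if surface_lx < 0:
        raise ValueError("surface_lx must be non-negative")
    if kd_per_m < 0:
        raise ValueError("kd_per_m must be non-negative")
    edges = np.asarray(bin_edges, dtype=float)
    if edges.ndim != 1 or len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin_edges must be a strictly increasing 1-D array")
    mids = (edges[:-1] + edges[1:]) / 2.0
    lx = surface_lx * np.exp(-kd_per_m * mids)
    lx = np.where(lx < floor_lx, 0.0, lx)
    return LightProfile(
        bin_edges=edges,
        illuminance_lx=lx,
        surface_lx=float(surface_lx),
        kd_per_m=float(kd_per_m),
        wavelength_nm=float(wavelength_nm),
        floor_lx=float(floor_lx),
    )


# ---------------------------------------------------------------------------
# Radiometric conversions (CIE 1931 2-deg photopic observer)
# ---------------------------------------------------------------------------

_CIE_WAVELENGTHS = np.arange(380, 785, 5)
_CIE_V = np.array([
    0.0000, 0.0001, 0.0001, 0.0002, 0.0004, 0.0006, 0.0012, 0.0022,
    0.0040, 0.0073, 0.0116, 0.0168, 0.0230, 0.0298, 0.0380, 0.0480,
    0.0600, 0.0739, 0.0910, 0.1126, 0.1390, 0.1693, 0.2080, 0.2586,
    0.3230, 0.4073, 0.5030, 0.6082, 0.7100, 0.7932, 0.8620, 0.9149,
    0.9540, 0.9803, 0.9950, 1.0000, 0.9950, 0.9786, 0.9520, 0.9154,
    0.8700, 0.8163, 0.7570, 0.6949, 0.6310, 0.5668, 0.5030, 0.4412,
    0.3810, 0.3210, 0.2650, 0.2170, 0.1750, 0.1382, 0.1070, 0.0816,
    0.0610, 0.0446, 0.0320, 0.0232, 0.0170, 0.0119, 0.0082, 0.0057,
    0.0041, 0.0029, 0.0021, 0.0015, 0.0010, 0.0007, 0.0005, 0.0004,
    0.00025, 0.0002, 0.0001, 0.0001, 0.0001, 0.0000, 0.0000, 0.0000,
    0.0000,
])


def photopic_sensitivity(wavelength_nm: float) -> float:
    """V(λ) of the CIE 1931 2° photopic observer, linearly interpolated."""
    w = float(wavelength_nm)
    if not (380.0 <= w <= 780.0):
        raise ValueError(f"wavelength {w} nm outside the 380-780 nm table")
    return float(np.interp(w, _CIE_WAVELENGTHS, _CIE_V))


def lux_to_irradiance(lux, wavelength_nm: float):
    """Monochromatic irradiance (W m^-2) equivalent of an illuminance.

    E = lux / (683 · V(λ)); the monochromatic approximation used for
    blue–green underwater spectra.
    """
    v = photopic_sensitivity(wavelength_nm)
    if v <= 0.0:
        raise ValueError(
            f"V({wavelength_nm} nm) = 0; illuminance carries no radiometric information there"
        )
    lux_arr = np.asarray(lux, dtype=float)
    if np.any(lux_arr < 0):
        raise ValueError("lux must be non-negative")
    out = lux_arr / (_KCD_MAX * v)
    return float(out) if np.isscalar(lux) else out


def irradiance_to_lux(w_m2, wavelength_nm: float):
    """Inverse of :func:`lux_to_irradiance` at the same wavelength."""
    v = photopic_sensitivity(wavelength_nm)
    arr = np.asarray(w_m2, dtype=float)
    out = arr * _KCD_MAX * v
    return float(out) if np.isscalar(w_m2) else out


def irradiance_to_photon_flux(w_m2, wavelength_nm: float):
    """Photon flux (µmol photons m^-2 s^-1) of monochromatic irradiance.

    flux = E · λ / (h c N_A), i.e. ≈ E[W m^-2] × λ[nm] × 0.008359 µmol.
    """
    w = float(wavelength_nm)
    if not (0.0 < w):
        raise ValueError("wavelength must be positive")
    arr = np.asarray(w_m2, dtype=float)
    if np.any(arr < 0):
        raise ValueError("irradiance must be non-negative")
    lam_m = w * 1e-9
    mol_per_joule = lam_m / (_PLANCK * _LIGHTSPEED * _AVOGADRO)
    out = arr * mol_per_joule * 1e6
    return float(out) if np.isscalar(w_m2) else out


def lux_to_photon_flux(lux, wavelength_nm: float):
    """Illuminance straight to photon flux at one nominal wavelength."""
    return irradiance_to_photon_flux(lux_to_irradiance(lux, wavelength_nm), wavelength_nm)
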