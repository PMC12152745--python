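"""Temporal and directional screening of profile time series.

Holds the season windows (boreal spring Feb 20 – Jun 1, boreal fall
Aug 1 – Nov 25), the night-only exclusion with standard refraction-corrected
sunrise/sunset (solar elevation below −0.833°), night labeling by local
sunset date, the seasonal direction filter that removes ground directions
inconsistent with broad-front migration, nightly thinning to the scan
closest to 3 h after sunset (peak migration, and past dusk bat emergence),
and season completeness rules.

Solar geometry follows the NOAA solar-position equations (fractional-year
Fourier series for declination and the equation of time); sunset and sunrise
instants are located by root-finding the elevation crossing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date, datetime, timedelta, timezone
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .vpts import StationConfig


class ScreeningError(ValueError):
    pass


#: Standard refraction-corrected horizon for sunrise/sunset, degrees.
SUN_HORIZON_DEG = -0.833


# ---------------------------------------------------------------------------
# Solar geometry (NOAA equations)
# ---------------------------------------------------------------------------

def solar_elevation(time: datetime | pd.Timestamp, latitude: float, longitude: float) -> float:
    """Apparent solar elevation angle (degrees) at a UTC instant.

    NOAA general solar-position equations: accurate to a few hundredths of a
    degree at study latitudes, amply sufficient for a ±0.833° horizon test.
    """
    t = pd.Timestamp(time)
    if t.tzinfo is None:
        t = t.tz_localize("UTC")
    t = t.tz_convert("UTC")
    doy = t.dayofyear
    hour = t.hour + t.minute / 60.0 + t.second / 3600.0 + t.microsecond / 3.6e9
    # fractional year, radians
    gamma = 2.0 * math.pi / 365.0 * (doy - 1 + (hour - 12) / 24.0)
    eqtime = 229.18 * (
        0.000075
        + 0.001868 * math.cos(gamma)
        - 0.032077 * math.sin(gamma)
        - 0.014615 * math.cos(2 * gamma)
        - 0.040849 * math.sin(2 * gamma)
    )  # minutes
    decl = (
        0.006918
        - 0.399912 * math.cos(gamma)
        + 0.070257 * math.sin(gamma)
        - 0.006758 * math.cos(2 * gamma)
        + 0.000907 * math.sin(2 * gamma)
        - 0.002697 * math.cos(3 * gamma)
        + 0.00148 * math.sin(3 * gamma)
    )  # radians
    time_offset = eqtime + 4.0 * longitude  # minutes (UTC reference)
    tst = hour * 60.0 + time_offset        # true solar time, minutes
    ha = math.radians(tst / 4.0 - 180.0)   # hour angle
    lat = math.radians(latitude)
    cos_zen = math.sin(lat) * math.sin(decl) + math.cos(lat) * math.cos(decl) * math.cos(ha)
    cos_zen = min(1.0, max(-1.0, cos_zen))
    return 90.0 - math.degrees(math.acos(cos_zen))


def is_night(time: datetime | pd.Timestamp, latitude: float, longitude: float) -> bool:
    """True iff the sun is below the standard −0.833° horizon."""
    return solar_elevation(time, latitude, longitude) < SUN_HORIZON_DEG


def _solar_noon_utc(day: date, longitude: float) -> pd.Timestamp:
    """Approximate local solar noon (UTC) on a calendar day."""
    return pd.Timestamp(
        datetime(day.year, day.month, day.day, 12, 0, tzinfo=timezone.utc)
    ) - pd.Timedelta(hours=longitude / 15.0)


def _elevation_crossing(t0: pd.Timestamp, t1: pd.Timestamp, lat: float, lon: float) -> pd.Timestamp:
    f = lambda s: solar_elevation(t0 + pd.Timedelta(seconds=s), lat, lon) - SUN_HORIZON_DEG
    span = (t1 - t0).total_seconds()
    sec = brentq(f, 0.0, span, xtol=0.5)
    return (t0 + pd.Timedelta(seconds=sec)).round("s")


def sunset_time(day: date, latitude: float, longitude: float) -> pd.Timestamp:
    """UTC instant of sunset on a station's local calendar day."""
    noon = _solar_noon_utc(day, longitude)
    return _elevation_crossing(noon, noon + pd.Timedelta(hours=11), latitude, longitude)


def sunrise_time(day: date, latitude: float, longitude: float) -> pd.Timestamp:
    """UTC instant of sunrise on a station's local calendar day."""
    noon = _solar_noon_utc(day, longitude)
    return _elevation_crossing(noon - pd.Timedelta(hours=11), noon, latitude, longitude)


# ---------------------------------------------------------------------------
# Seasons
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SeasonWindows:
    """Migration-period windows (month, day), boundaries inclusive."""

    spring_start: tuple[int, int] = (2, 20)
    spring_end: tuple[int, int] = (6, 1)
    fall_start: tuple[int, int] = (8, 1)
    fall_end: tuple[int, int] = (11, 25)

    def bounds(self, season: str, year: int) -> tuple[date, date]:
        if season == "spring":
            return (date(year, *self.spring_start), date(year, *self.spring_end))
        if season == "fall":
            return (date(year, *self.fall_start), date(year, *self.fall_end))
        raise ScreeningError(f"unknown season {season!r}")

    def n_nights(self, season: str, year: int) -> int:
        lo, hi = self.bounds(season, year)
        return (hi - lo).days + 1


def season_of(day: date, windows: SeasonWindows = SeasonWindows()) -> str:
    """'spring', 'fall' or 'none' for a calendar date (boundaries inclusive)."""
    for season in ("spring", "fall"):
        lo, hi = windows.bounds(season, day.year)
        if lo <= day <= hi:
            return season
    return "none"


# ---------------------------------------------------------------------------
# Night keys
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NightKey:
    """A station-night: the local calendar date of sunset, with the UTC
    sunset and next-morning sunrise instants."""

    station_id: str
    night_date: date
    sunset: pd.Timestamp
    sunrise: pd.Timestamp

    def __post_init__(self) -> None:
        if not self.sunset < self.sunrise:
            raise ScreeningError("sunset must precede the following sunrise")


def night_key_for_date(night_date: date, station: StationConfig) -> NightKey:
    """NightKey whose night starts at the given local date's sunset."""
    sunset = sunset_time(night_date, station.latitude, station.longitude)
    sunrise = sunrise_time(night_date + timedelta(days=1), station.latitude, station.longitude)
    return NightKey(station.station_id, night_date, sunset, sunrise)


def assign_night(time: datetime | pd.Timestamp, station: StationConfig) -> NightKey:
    """Night of a nocturnal instant: local date of the most recent sunset."""
    t = pd.Timestamp(time)
    if t.tzinfo is None:
        t = t.tz_localize("UTC")
    if not is_night(t, station.latitude, station.longitude):
        raise ScreeningError(f"{t} is not nocturnal at station {station.station_id}")
    local_date = (t + pd.Timedelta(hours=station.utc_offset_hours)).date()
    for candidate in (local_date, local_date - timedelta(days=1)):
        key = night_key_for_date(candidate, station)
        if key.sunset <= t < key.sunrise:
            return key
    raise ScreeningError(f"could not locate the night containing {t}")


# ---------------------------------------------------------------------------
# Direction filter
# ---------------------------------------------------------------------------

def direction_filter(partitioned: pd.DataFrame, season: str) -> pd.DataFrame:
    """Remove bins whose ground direction is inconsistent with the season.

    Spring removes southbound tracks strictly inside (90°, 270°); fall
    removes northbound tracks strictly below 90° or strictly above 270°.
    Exactly 90° and 270° are retained in both seasons. Bins with missing
    track pass through with ``direction_unfiltered = True``.
    """
    if season not in ("spring", "fall"):
        raise ScreeningError(f"direction filter needs season 'spring' or 'fall', got {season!r}")
    out = partitioned.copy()
    track = out["track"].to_numpy(dtype=float)
    if season == "spring":
        remove = (track > 90.0) & (track < 270.0)
    else:
        remove = (track < 90.0) | (track > 270.0)
    remove &= ~np.isnan(track)
    out = out.loc[~remove].copy()
    out["direction_unfiltered"] = np.isnan(out["track"].to_numpy(dtype=float))
    return out


# ---------------------------------------------------------------------------
# Nightly thinning and completeness
# ---------------------------------------------------------------------------

def thin_to_reference(
    scans: pd.DataFrame, night: NightKey, offset: pd.Timedelta = pd.Timedelta(hours=3)
) -> pd.Series:
    """The one scan of a night closest to sunset + offset (ties → earlier).

    ``scans`` must carry a ``datetime`` column; the selected row is returned.
    """
    if scans.empty:
        raise ScreeningError(f"no scans in night {night.night_date}")
    target = night.sunset + offset
    dist = (pd.to_datetime(scans["datetime"], utc=True) - target).abs()
    # stable argmin over (distance, datetime): equidistant pair -> earlier scan
    order = scans.assign(_dist=dist).sort_values(["_dist", "datetime"], kind="mergesort")
    return order.iloc[0].drop("_dist")


@dataclass(frozen=True)
class CompletenessReport:
    fraction_nights_with_data: float
    longest_continuous_run_days: int
    n_volumes: int
    passes_mt_total: bool      # >= 75% of window nights have usable data
    passes_mtr_cv: bool        # > 14 consecutive nights of data
    near_complete: bool        # > 3000 volumes in the season


def completeness(
    nights_with_data: Iterable[date],
    season: str,
    year: int,
    n_volumes: int = 0,
    windows: SeasonWindows = SeasonWindows(),
) -> CompletenessReport:
    """Season completeness against the reporting thresholds: 75% of nights
    for seasonal MT totals, more than two weeks of continuous data for
    MTR mean/CV, and the >3000-volume near-complete rule."""
    lo, hi = windows.bounds(season, year)
    window_nights = [lo + timedelta(days=i) for i in range((hi - lo).days + 1)]
    have = set(nights_with_data)
    present = [d in have for d in window_nights]
    fraction = sum(present) / len(present)
    longest = run = 0
    for p in present:
        run = run + 1 if p else 0
        longest = max(longest, run)
    return CompletenessReport(
        fraction_nights_with_data=fraction,
        longest_continuous_run_days=longest,
        n_volumes=n_volumes,
        passes_mt_total=fraction >= 0.75,
        passes_mtr_cv=longest > 14,
        near_complete=n_volumes > 3000,
    )
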