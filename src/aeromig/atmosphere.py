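"""Atmospheric pairing and flow assistance.

Pressure-level reanalysis tables (3-hourly, 15 levels between 1000 and
600 hPa) are matched to radar altitude bins by linear interpolation in time
followed by altitude, using geopotential height as the vertical coordinate.
Flow assistance follows the equal-airspeed model: the wind benefit along a
preferred migratory direction for a bird that fully compensates crosswind at
a fixed airspeed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .vpts import ProfileTimeSeries, StationConfig

logger = logging.getLogger(__name__)

#: Variables carried through the pairing, with their table column names.
GRID_VARIABLES = ["u_wind", "v_wind", "temp", "shum", "omega", "tke"]

ATMO_COLUMNS = {
    "time": "time",
    "level_hPa": "level_hPa",
    "gph_m": "gph_m",
    "u": "u_wind",
    "v": "v_wind",
    "temp_K": "temp",
    "shum": "shum",
    "omega": "omega",
    "tke": "tke",
}


class AtmosphereError(ValueError):
    """Malformed atmospheric data or pairing failure."""


@dataclass(frozen=True)
class FlowParams:
    """Flow-assistance parameters: fixed bird airspeed (m s⁻¹, default 8)
    and the preferred migratory direction (compass degrees)."""

    airspeed: float = 8.0
    preferred_direction: float = 0.0

    def __post_init__(self) -> None:
        if not self.airspeed > 0:
            raise ValueError("airspeed must be positive")
        if not 0.0 <= self.preferred_direction < 360.0:
            raise ValueError("preferred_direction must lie in [0, 360)")


@dataclass
class AtmosphericGrid:
    """Pressure-level time series at one grid point.

    ``data`` has columns ``time, level_hPa, gph_m, u_wind, v_wind, temp,
    shum, omega, tke``; times strictly increasing, geopotential height
    strictly increasing as pressure decreases at each time.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data.copy()
        df["time"] = pd.to_datetime(df["time"], utc=True)
        for col in ["level_hPa", "gph_m", *GRID_VARIABLES]:
            if col in df.columns:
                df[col] = pd.to_numeric(df[col]).astype(float)
        df = df.sort_values(["time", "level_hPa"], ascending=[True, False], kind="mergesort")
        for t, grp in df.groupby("time"):
            gph = grp["gph_m"].to_numpy()
            if not np.all(np.diff(gph) > 0):
                raise AtmosphereError(
                    f"geopotential height not strictly increasing with decreasing pressure at {t}"
                )
        self.data = df.reset_index(drop=True)

    @property
    def times(self) -> pd.DatetimeIndex:
        return pd.DatetimeIndex(self.data["time"].unique())


def read_atmosphere(path: str | Path) -> AtmosphericGrid:
    """Read the per-grid-point atmosphere CSV
    (``time, level_hPa, gph_m, u, v, temp_K, shum, omega, tke``)."""
    raw = pd.read_csv(path)
    missing = [c for c in ATMO_COLUMNS if c not in raw.columns]
    if missing:
        raise AtmosphereError(f"{path}: missing column(s) {missing}")
    return AtmosphericGrid(raw.rename(columns=ATMO_COLUMNS)[list(ATMO_COLUMNS.values())])


def write_atmosphere(grid: AtmosphericGrid, path: str | Path) -> Path:
    inv = {v: k for k, v in ATMO_COLUMNS.items()}
    out = grid.data.rename(columns=inv)
    out["time"] = pd.to_datetime(out["time"], utc=True).dt.strftime("%Y-%m-%dT%H:%M:%SZ")
    out.to_csv(path, index=False, float_format="%.10g")
    return Path(path)


# ---------------------------------------------------------------------------
# Pairing: linear interpolation in time, then altitude
# ---------------------------------------------------------------------------

def pair_weather(series: ProfileTimeSeries, grid: AtmosphericGrid) -> pd.DataFrame:
    """Interpolate grid variables to every (timestamp, bin center) of a series.

    For each profile timestamp every variable (and the level geopotential
    heights) is linearly interpolated between the bracketing grid instants at
    each pressure level, then linearly interpolated in altitude from level
    heights to bin centers. Outside the level span values clamp to the
    nearest level; outside the grid's time span values are missing and a
    warning is logged.

    Returns a DataFrame keyed by (datetime, height) with the interpolated
    variables plus provenance columns ``time_lo``/``time_hi`` (the grid
    instants that fed each value).
    """
    times = grid.times
    tvals = np.asarray(times.view("int64"))
    # levels sorted by increasing gph within each time; pivot to (ntime, nlev)
    piv = {
        var: grid.data.pivot(index="time", columns="level_hPa", values=var)
        .sort_index()
        .to_numpy()
        for var in ["gph_m"] + GRID_VARIABLES
    }
    # pivot columns are ascending level_hPa; reverse to ascending height
    piv = {var: arr[:, ::-1] for var, arr in piv.items()}

    out_frames = []
    for ts, grp in series.data.groupby("datetime", sort=True):
        centers = grp["height"].to_numpy(dtype=float) + 50.0
        row = {"datetime": ts, "height": grp["height"].to_numpy(dtype=float)}
        t = ts.value
        if t < tvals[0] or t > tvals[-1]:
            logger.warning("profile timestamp %s outside atmospheric grid span", ts)
            for var in GRID_VARIABLES:
                row[var] = np.full(len(centers), np.nan)
            row["time_lo"] = pd.NaT
            row["time_hi"] = pd.NaT
        else:
            hi = int(np.searchsorted(tvals, t, side="left"))
            lo = max(hi - 1, 0) if tvals[hi] != t else hi
            if tvals[hi] == t:
                w = 0.0
                lo = hi
            else:
                w = (t - tvals[lo]) / (tvals[hi] - tvals[lo])
            gph_t = (1 - w) * piv["gph_m"][lo] + w * piv["gph_m"][hi]
            for var in GRID_VARIABLES:
                prof_t = (1 - w) * piv[var][lo] + w * piv[var][hi]
                # np.interp clamps outside [gph_t[0], gph_t[-1]]
                row[var] = np.interp(centers, gph_t, prof_t)
            row["time_lo"] = times[lo]
            row["time_hi"] = times[hi]
        out_frames.append(pd.DataFrame(row))
    if not out_frames:
        return pd.DataFrame(columns=["datetime", "height", *GRID_VARIABLES, "time_lo", "time_hi"])
    return pd.concat(out_frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Flow assistance (equal-airspeed model)
# ---------------------------------------------------------------------------

def tailwind_eq_airspeed(
    u_wind: float | np.ndarray,
    v_wind: float | np.ndarray,
    params: FlowParams,
) -> float | np.ndarray:
    """Flow assistance along the preferred direction at fixed airspeed.

    With t the wind component along the preferred direction and c the
    crosswind component, assistance = t + sqrt(a² − c²) − a for airspeed a:
    the ground-speed gain along the preferred track of a bird heading so as
    to exactly cancel the crosswind. When |c| > a full compensation is
    infeasible and the result is missing (NaN).
    """
    u = np.asarray(u_wind, dtype=float)
    v = np.asarray(v_wind, dtype=float)
    theta = np.deg2rad(params.preferred_direction)
    a = params.airspeed
    t = u * np.sin(theta) + v * np.cos(theta)
    c = u * np.cos(theta) - v * np.sin(theta)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        assist = np.where(np.abs(c) <= a, t + np.sqrt(np.maximum(a**2 - c**2, 0.0)) - a, np.nan)
    if np.isscalar(u_wind) and np.isscalar(v_wind):
        return float(assist)
    return assist


def preferred_direction(tracks_deg: Sequence[float], weights: Sequence[float]) -> float:
    """Reflectivity-weighted circular mean of track directions, in [0, 360).

    Used with bird reflectivity as weights to derive each station–season's
    preferred migratory direction from the observed ground directions.
    """
    tr = np.asarray(tracks_deg, dtype=float)
    w = np.asarray(weights, dtype=float)
    ok = ~(np.isnan(tr) | np.isnan(w)) & (w > 0)
    if not ok.any():
        raise AtmosphereError("no bins with positive bird reflectivity and defined track")
    rad = np.deg2rad(tr[ok])
    s = np.sum(w[ok] * np.sin(rad))
    c = np.sum(w[ok] * np.cos(rad))
    if s == 0 and c == 0:
        raise AtmosphereError("circular mean undefined (resultant vector is zero)")
    deg = float(np.rad2deg(np.arctan2(s, c)) % 360.0)
    return 0.0 if deg >= 360.0 else deg


def ground_level_value(
    paired: pd.DataFrame, variable: str, station: StationConfig
) -> pd.DataFrame:
    """Value of a paired variable at the bin whose center is closest to the
    station ground height, per timestamp (ties resolve to the lower bin)."""
    if paired.empty:
        raise AtmosphereError("no bins available for ground-level extraction")
    df = paired.copy()
    df["_dist"] = np.abs(df["height"] + 50.0 - station.antenna_height_m)
    # stable sort on (dist, height): equidistant pair -> lower bin first
    df = df.sort_values(["datetime", "_dist", "height"], kind="mergesort")
    out = df.groupby("datetime", sort=True).first().reset_index()
    return out[["datetime", variable]].rename(columns={variable: f"{variable}_ground"})


# ---------------------------------------------------------------------------
# Covariate screening and wind validation
# ---------------------------------------------------------------------------

def collinearity_screen(
    table: pd.DataFrame,
    priority: Sequence[str],
    threshold: float = 0.7,
) -> list[str]:
    """Drop the lower-priority member of each covariate pair with
    |Pearson r| > threshold; deterministic given the priority order.

    Constant columns (undefined r) are excluded from screening with a
    warning and do not appear in the retained list.
    """
    cols = [c for c in priority if c in table.columns]
    if len(cols) < 2 or len(table) < 3:
        raise AtmosphereError("need >= 2 covariates and >= 3 rows to screen")
    usable = []
    for c in cols:
        x = table[c].to_numpy(dtype=float)
        if np.nanstd(x) == 0:
            logger.warning("covariate %r is constant; excluded from screening", c)
            continue
        usable.append(c)
    retained: list[str] = []
    for c in usable:
        drop = False
        for kept in retained:
            sub = table[[kept, c]].dropna()
            r = np.corrcoef(sub[kept], sub[c])[0, 1]
            if abs(r) > threshold:
                drop = True
                break
        if not drop:
            retained.append(c)
    return retained


def wind_mad(series_a: pd.DataFrame, series_b: pd.DataFrame) -> float:
    """Mean absolute wind-speed difference between two matched records.

    Inputs carry ``time, height_m, speed_ms``; records are matched on
    (time, height_m) and the mean |Δspeed| over matches is returned — the
    statistic used to validate reanalysis winds against weather balloons.
    """
    merged = series_a.merge(series_b, on=["time", "height_m"], suffixes=("_a", "_b"))
    merged = merged.dropna(subset=["speed_ms_a", "speed_ms_b"])
    if merged.empty:
        raise AtmosphereError("no matched (time, height) records between the two series")
    return float(np.mean(np.abs(merged["speed_ms_a"] - merged["speed_ms_b"])))
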