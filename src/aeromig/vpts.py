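"""Vertical-profile time series: domain types, VPTS-CSV I/O, vertical integration.

A vertical profile is a per-timestamp stack of fixed-width (100 m) altitude
bins holding linear reflectivity eta (cm² km⁻³) and reflectivity-weighted
mean ground-velocity components u (eastward) and v (northward), both m s⁻¹.
Dividing eta by an assumed single-bird radar cross section converts it to an
animal density (birds km⁻³), which vertical integration turns into the two
workhorse quantities of radar aeroecology:

* VID — vertically integrated density, birds km⁻²
* MTR — migration traffic rate, birds km⁻¹ h⁻¹ (density × ground speed,
  integrated over altitude: the instantaneous flux across a 1 km transect)

All heights are meters above sea level; the altitude ceiling is 5000 m.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

#: Altitude bin width, meters.
BIN_WIDTH_M = 100.0
#: Bin width in km, the Δh of all vertical integrals.
DELTA_H_KM = BIN_WIDTH_M / 1000.0
#: Highest admissible bin lower bound, meters a.s.l.
MAX_HEIGHT_M = 4900.0

#: Columns of the VPTS-CSV dialect (one optional extra column `source`
#: is tolerated on read and ignored).
VPTS_COLUMNS = ["radar", "datetime", "height", "eta", "u", "v"]


class VptsError(ValueError):
    """Malformed vertical-profile data."""


@dataclass(frozen=True)
class StationConfig:
    """A radar station: identifier, coordinates and antenna height.

    ``utc_offset_hours`` is the civil time zone used to label nights by
    local sunset date (e.g. -5 for Colombia).
    """

    station_id: str
    latitude: float
    longitude: float
    antenna_height_m: float = 0.0
    utc_offset_hours: float = 0.0


@dataclass(frozen=True)
class RcsParams:
    """Radar cross section of a single bird, cm² (default 11)."""

    rcs: float = 11.0

    def __post_init__(self) -> None:
        if not self.rcs > 0:
            raise ValueError(f"rcs must be positive, got {self.rcs}")


@dataclass
class VerticalProfile:
    """One timestamp's stack of altitude bins.

    ``bins`` is a DataFrame with columns ``height`` (bin lower bound, m),
    ``eta``, ``u``, ``v``; missing velocity is NaN while eta may still be
    present.
    """

    station_id: str
    timestamp: pd.Timestamp
    bins: pd.DataFrame

    @property
    def heights(self) -> np.ndarray:
        return self.bins["height"].to_numpy(dtype=float)

    @property
    def centers(self) -> np.ndarray:
        """Bin centers (height_lo + 50 m), used for all height-indexed work."""
        return self.heights + BIN_WIDTH_M / 2.0


@dataclass
class ProfileTimeSeries:
    """Time-ordered vertical profiles of a single station.

    ``data`` is a long-format DataFrame with columns
    ``datetime, height, eta, u, v`` (plus any partition columns added
    downstream), sorted by (datetime, height).
    """

    station: StationConfig
    data: pd.DataFrame

    def __post_init__(self) -> None:
        self.data = validate_profile_table(self.data)

    def __len__(self) -> int:
        return self.data["datetime"].nunique()

    def profiles(self) -> Iterator[VerticalProfile]:
        for ts, grp in self.data.groupby("datetime", sort=True):
            yield VerticalProfile(self.station.station_id, ts, grp.reset_index(drop=True))

    def timestamps(self) -> pd.DatetimeIndex:
        return pd.DatetimeIndex(sorted(self.data["datetime"].unique()))


@dataclass(frozen=True)
class IntegratedScan:
    """Vertically integrated quantities of one profile."""

    timestamp: pd.Timestamp
    vid: float                 # birds km⁻²
    mtr: float                 # birds km⁻¹ h⁻¹; NaN when undefined
    mean_height: float         # m a.s.l., density-weighted bin centers; NaN if empty
    n_bins_used: int


def validate_profile_table(df: pd.DataFrame) -> pd.DataFrame:
    """Check invariants of a long-format profile table and return it sorted."""
    missing = [c for c in ("datetime", "height", "eta", "u", "v") if c not in df.columns]
    if missing:
        raise VptsError(f"profile table missing mandatory column(s): {missing}")
    df = df.copy()
    df["datetime"] = pd.to_datetime(df["datetime"], utc=True)
    for col in ("height", "eta", "u", "v"):
        df[col] = pd.to_numeric(df[col], errors="coerce").astype(float)

    h = df["height"].to_numpy(dtype=float)
    bad_height = ~np.isin(h, np.arange(0.0, MAX_HEIGHT_M + 1, BIN_WIDTH_M))
    if bad_height.any():
        rows = df.index[bad_height].tolist()[:5]
        raise VptsError(
            f"invalid bin lower bound(s) {sorted(set(h[bad_height]))[:5]} at rows {rows}; "
            f"heights must lie in 0..{MAX_HEIGHT_M:.0f} m in {BIN_WIDTH_M:.0f} m steps"
        )
    if (df["eta"].dropna() < 0).any():
        raise VptsError("negative reflectivity (eta) encountered")
    dup = df.duplicated(subset=["datetime", "height"], keep=False)
    if dup.any():
        key = df.loc[dup, ["datetime", "height"]].iloc[0]
        raise VptsError(
            f"duplicate (timestamp, height) pair: ({key['datetime']}, {key['height']:g})"
        )
    return df.sort_values(["datetime", "height"], kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# VPTS-CSV I/O
# ---------------------------------------------------------------------------

def read_vpts(path: str | Path, station: StationConfig) -> ProfileTimeSeries:
    """Read a VPTS-CSV file (columns ``radar,datetime,height,eta,u,v``).

    Empty fields are missing values (never coerced to zero). Malformed rows
    are reported with their 1-based line number in the file.
    """
    path = Path(path)
    try:
        raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    except OSError as exc:
        raise VptsError(f"cannot read {path}: {exc}") from exc
    missing = [c for c in VPTS_COLUMNS if c not in raw.columns]
    if missing:
        raise VptsError(f"{path}: missing mandatory column(s) {missing}")

    df = pd.DataFrame({"datetime": raw["datetime"], "height": raw["height"]})
    for col in ("eta", "u", "v"):
        df[col] = raw[col].replace("", np.nan)

    # per-row parse check with line numbers (header = line 1)
    for col in ("height", "eta", "u", "v"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna() & (df[col].astype(str).str.strip() != "")
        if bad.any():
            lines = (df.index[bad] + 2).tolist()[:5]
            raise VptsError(f"{path}: unparseable {col!r} value(s) at line(s) {lines}")
        df[col] = vals
    parsed_ts = pd.to_datetime(df["datetime"], errors="coerce", utc=True)
    if parsed_ts.isna().any():
        lines = (df.index[parsed_ts.isna()] + 2).tolist()[:5]
        raise VptsError(f"{path}: unparseable datetime at line(s) {lines}")
    df["datetime"] = parsed_ts
    return ProfileTimeSeries(station=station, data=df)


def write_vpts(series: ProfileTimeSeries, path: str | Path) -> Path:
    """Write the VPTS-CSV dialect; ``read_vpts(write_vpts(s))`` round-trips."""
    path = Path(path)
    out = series.data.copy()
    out.insert(0, "radar", series.station.station_id)
    out["datetime"] = out["datetime"].dt.strftime("%Y-%m-%dT%H:%M:%SZ")
    out["height"] = out["height"].map(lambda x: f"{x:.0f}")
    cols = VPTS_COLUMNS + [c for c in out.columns if c not in VPTS_COLUMNS]
    try:
        out[cols].to_csv(path, index=False, float_format="%.6g")
    except OSError as exc:
        raise VptsError(f"cannot write {path}: {exc}") from exc
    return path


# ---------------------------------------------------------------------------
# Vertical integration
# ---------------------------------------------------------------------------

def bin_density(eta_total: float | np.ndarray, rcs: RcsParams = RcsParams()) -> float | np.ndarray:
    """Animal density (birds km⁻³) from linear reflectivity: dens = eta / rcs."""
    eta = np.asarray(eta_total, dtype=float)
    if np.any(eta[~np.isnan(eta)] < 0):
        raise VptsError("negative reflectivity")
    dens = eta / rcs.rcs
    return float(dens) if np.isscalar(eta_total) else dens


MS_TO_KMH = 3.6


def integrate_profile(profile: VerticalProfile, rcs: RcsParams = RcsParams()) -> IntegratedScan:
    """Integrate one profile across altitude into VID, MTR and mean height.

    MTR is marked missing (NaN) whenever any bin with positive density lacks
    a velocity estimate — partial-bin traffic rates are never silently
    computed.
    """
    eta = profile.bins["eta"].to_numpy(dtype=float)
    u = profile.bins["u"].to_numpy(dtype=float)
    v = profile.bins["v"].to_numpy(dtype=float)
    dens = np.where(np.isnan(eta), 0.0, eta) / rcs.rcs

    vid = float(np.sum(dens) * DELTA_H_KM)
    centers = profile.centers
    if vid > 0:
        mean_height = float(np.sum(centers * dens) / np.sum(dens))
    else:
        mean_height = math.nan

    vel_ok = ~(np.isnan(u) | np.isnan(v))
    if np.any((dens > 0) & ~vel_ok):
        mtr = math.nan
    else:
        speed_kmh = np.sqrt(u[vel_ok] ** 2 + v[vel_ok] ** 2) * MS_TO_KMH
        mtr = float(np.sum(dens[vel_ok] * speed_kmh) * DELTA_H_KM)
    return IntegratedScan(
        timestamp=profile.timestamp,
        vid=vid,
        mtr=mtr,
        mean_height=mean_height,
        n_bins_used=int(np.sum(dens > 0)),
    )


def integrate_series(series: ProfileTimeSeries, rcs: RcsParams = RcsParams()) -> pd.DataFrame:
    """Integrate every profile; returns one row per timestamp."""
    rows = [integrate_profile(p, rcs) for p in series.profiles()]
    return pd.DataFrame(
        {
            "datetime": [r.timestamp for r in rows],
            "vid": [r.vid for r in rows],
            "mtr": [r.mtr for r in rows],
            "mean_height": [r.mean_height for r in rows],
            "n_bins_used": [r.n_bins_used for r in rows],
        }
    )


def normalized_density(profile: VerticalProfile, rcs: RcsParams = RcsParams()) -> pd.Series:
    """Per-bin dens/VID weights (km⁻¹); they integrate to 1 over altitude.

    Normalization removes nightly variation in abundance, isolating altitude
    selection.
    """
    eta = profile.bins["eta"].to_numpy(dtype=float)
    dens = np.where(np.isnan(eta), 0.0, eta) / rcs.rcs
    vid = np.sum(dens) * DELTA_H_KM
    if not vid > 0:
        raise VptsError("normalized_density undefined for an empty profile (VID = 0)")
    return pd.Series(dens / vid, index=profile.bins.index, name="norm_dens")
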