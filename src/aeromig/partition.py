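"""Bird–insect echo partitioning by airspeed.

Tropical radar echoes mix birds and insects. The partition model assumes
insects move approximately with the wind (airspeed a_i ≈ 1 m s⁻¹, oriented
downwind) while birds are self-propelled at a fixed airspeed a_b ≈ 8 m s⁻¹
with an unknown heading. The observed reflectivity-weighted mean velocity of
a bin is then the bird-fraction mixture

    V_obs = f · (V_wind + a_b·ĥ) + (1 − f) · (V_wind + a_i·ŵ)

with ĥ the unit heading vector and ŵ the downwind unit vector (dropped under
calm wind). Writing A = V_obs − V_wind and eliminating ĥ (|ĥ| = 1) yields a
scalar quadratic in f:

    f²(a_i² − a_b²) + 2 f a_i((A·ŵ) − a_i) + |A − a_i·ŵ|² = 0

which has exactly one root in [0, 1] whenever |A| ≤ a_b (the polynomial is
concave with g(0) ≥ 0 and g(1) = |A|² − a_b² ≤ 0). The bird fraction f
multiplies total reflectivity to give bird reflectivity; the recovered
heading vector gives heading and, adding the wind, track.

Compass convention throughout: bearings measured clockwise from north
(0° = N, 90° = E), i.e. bearing = atan2(u, v) in degrees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .atmosphere import GRID_VARIABLES
from .vpts import ProfileTimeSeries


class PartitionError(ValueError):
    pass


@dataclass(frozen=True)
class PartitionParams:
    """Fixed airspeeds of the two taxa and the calm-wind cutoff.

    Below ``calm_wind_eps`` the insect self-propulsion term is dropped
    (downwind direction undefined in calm air).
    """

    a_bird: float = 8.0
    a_insect: float = 1.0
    calm_wind_eps: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.a_insect < self.a_bird:
            raise ValueError("require 0 <= a_insect < a_bird")


@dataclass(frozen=True)
class PartitionResult:
    """Per-bin partition: bird fraction, bird air velocity, heading/track,
    bird reflectivity and the model residual (zero unless clamped)."""

    f_bird: float
    u_air: float
    v_air: float
    heading: float          # compass deg; NaN when f_bird = 0
    track: float            # compass deg of bird ground velocity; NaN when undefined
    airspeed_obs: float     # |V_obs − V_wind| of the mixture
    eta_bird: float
    residual: float


def heading_from_uv(u_air: float, v_air: float) -> float:
    """Compass bearing of an (east, north) vector: 0° = N, 90° = E."""
    if u_air == 0.0 and v_air == 0.0:
        raise PartitionError("heading undefined for zero vector")
    deg = float(np.rad2deg(np.arctan2(u_air, v_air)) % 360.0)
    return 0.0 if deg >= 360.0 else deg


def track_from_air(u_air: float, v_air: float, u_wind: float, v_wind: float) -> float:
    """Compass bearing of the bird ground-velocity vector (air + wind)."""
    ug, vg = u_air + u_wind, v_air + v_wind
    if ug == 0.0 and vg == 0.0:
        raise PartitionError("track undefined: bird ground velocity is zero")
    return heading_from_uv(ug, vg)


def _solve_f(
    au: np.ndarray,
    av: np.ndarray,
    wu: np.ndarray,
    wv: np.ndarray,
    calm: np.ndarray,
    params: PartitionParams,
) -> np.ndarray:
    """Vectorized bird-fraction solution. ``(au, av)`` is A = V_obs − V_wind,
    ``(wu, wv)`` the downwind unit vector (zeroed where ``calm``)."""
    ai, ab = params.a_insect, params.a_bird
    a_obs = np.hypot(au, av)

    # calm branch: A = f·a_b·ĥ  =>  f = |A|/a_b
    f_calm = np.minimum(a_obs / ab, 1.0)

    a_dot_w = au * wu + av * wv
    qa = ai**2 - ab**2                      # < 0
    qb = 2.0 * ai * (a_dot_w - ai)
    qc = (au - ai * wu) ** 2 + (av - ai * wv) ** 2
    disc = qb**2 - 4.0 * qa * qc            # >= qb² since qa<0, qc>=0
    sqrt_disc = np.sqrt(np.maximum(disc, 0.0))
    # concave parabola: upper root = (−qb − √disc)/(2qa) with 2qa < 0
    f_quad = (-qb - sqrt_disc) / (2.0 * qa)

    f = np.where(calm, f_calm, np.clip(f_quad, 0.0, 1.0))
    f = np.where(a_obs >= ab, 1.0, f)
    return f


def partition_arrays(
    u_obs: np.ndarray,
    v_obs: np.ndarray,
    u_wind: np.ndarray,
    v_wind: np.ndarray,
    eta_total: np.ndarray,
    params: PartitionParams = PartitionParams(),
) -> pd.DataFrame:
    """Partition many bins at once; NaN inputs yield NaN partitions.

    Returns columns ``f_bird, u_air, v_air, heading, track, airspeed_obs,
    eta_bird, residual``.
    """
    u_obs = np.asarray(u_obs, dtype=float)
    v_obs = np.asarray(v_obs, dtype=float)
    u_wind = np.asarray(u_wind, dtype=float)
    v_wind = np.asarray(v_wind, dtype=float)
    eta_total = np.asarray(eta_total, dtype=float)
    if np.any(eta_total[~np.isnan(eta_total)] < 0):
        raise PartitionError("negative eta_total")

    ok = ~(np.isnan(u_obs) | np.isnan(v_obs) | np.isnan(u_wind) | np.isnan(v_wind))
    au = np.where(ok, u_obs - u_wind, np.nan)
    av = np.where(ok, v_obs - v_wind, np.nan)
    wspd = np.hypot(u_wind, v_wind)
    calm = wspd < params.calm_wind_eps
    with np.errstate(invalid="ignore", divide="ignore"):
        wu = np.where(calm, 0.0, u_wind / wspd)
        wv = np.where(calm, 0.0, v_wind / wspd)

        f = np.where(ok, _solve_f(au, av, wu, wv, calm, params), np.nan)

        # heading vector: ĥ ∝ A − (1−f)·a_i·ŵ  (f > 0)
        ru = au - (1.0 - f) * params.a_insect * wu
        rv = av - (1.0 - f) * params.a_insect * wv
        rnorm = np.hypot(ru, rv)
        fpos = ok & (f > 0) & (rnorm > 0)
        hu = np.where(fpos, ru / np.where(rnorm > 0, rnorm, 1.0), np.nan)
        hv = np.where(fpos, rv / np.where(rnorm > 0, rnorm, 1.0), np.nan)
        u_air = np.where(fpos, params.a_bird * hu, np.nan)
        v_air = np.where(fpos, params.a_bird * hv, np.nan)

        residual = np.where(fpos, np.abs(rnorm - f * params.a_bird), rnorm)
        heading = np.where(fpos, np.rad2deg(np.arctan2(hu, hv)) % 360.0, np.nan)
        ug = u_air + u_wind
        vg = v_air + v_wind
        gnorm = np.hypot(ug, vg)
        track = np.where(fpos & (gnorm > 0), np.rad2deg(np.arctan2(ug, vg)) % 360.0, np.nan)

    return pd.DataFrame(
        {
            "f_bird": f,
            "u_air": u_air,
            "v_air": v_air,
            "heading": heading,
            "track": track,
            "airspeed_obs": np.hypot(au, av),
            "eta_bird": f * eta_total,
            "residual": residual,
        }
    )


def partition_bin(
    u_obs: float,
    v_obs: float,
    u_wind: float,
    v_wind: float,
    eta_total: float,
    params: PartitionParams = PartitionParams(),
) -> PartitionResult:
    """Partition a single bin's echo into bird and insect components."""
    df = partition_arrays(
        np.array([u_obs]), np.array([v_obs]),
        np.array([u_wind]), np.array([v_wind]),
        np.array([eta_total]), params,
    )
    row = df.iloc[0]
    return PartitionResult(
        f_bird=float(row["f_bird"]),
        u_air=float(row["u_air"]),
        v_air=float(row["v_air"]),
        heading=float(row["heading"]),
        track=float(row["track"]),
        airspeed_obs=float(row["airspeed_obs"]),
        eta_bird=float(row["eta_bird"]),
        residual=float(row["residual"]),
    )


def scalar_fallback_f(
    airspeed_obs: float | np.ndarray, params: PartitionParams = PartitionParams()
) -> float | np.ndarray:
    """Diagnostic-only scalar interpolation f = clip((|A| − a_i)/(a_b − a_i), 0, 1).

    Exact in the collinear case; ignores direction and is not the default.
    """
    f = np.clip(
        (np.asarray(airspeed_obs, dtype=float) - params.a_insect)
        / (params.a_bird - params.a_insect),
        0.0,
        1.0,
    )
    return float(f) if np.isscalar(airspeed_obs) else f


def partition_series(
    series: ProfileTimeSeries,
    paired_weather: pd.DataFrame,
    params: PartitionParams = PartitionParams(),
) -> pd.DataFrame:
    """Partition every bin of a series using its paired wind.

    Returns the series table with ``u_wind, v_wind`` (and the other paired
    variables) merged in and partition columns ``eta_bird, f_bird, heading,
    track, u_air, v_air, residual`` appended. Bins with missing velocity or
    wind yield missing partitions.
    """
    cols = ["datetime", "height"] + [c for c in GRID_VARIABLES if c in paired_weather.columns]
    merged = series.data.merge(paired_weather[cols], on=["datetime", "height"], how="left")
    if len(merged) != len(series.data):
        raise PartitionError("paired weather does not align one-to-one with the series bins")
    part = partition_arrays(
        merged["u"].to_numpy(),
        merged["v"].to_numpy(),
        merged["u_wind"].to_numpy(),
        merged["v_wind"].to_numpy(),
        merged["eta"].to_numpy(),
        params,
    )
    return pd.concat([merged, part], axis=1)


def bird_profile_table(partitioned: pd.DataFrame) -> pd.DataFrame:
    """Bird-only profile table for vertical integration: reflectivity is
    eta_bird and velocities are the bird ground-velocity components."""
    out = partitioned[["datetime", "height"]].copy()
    out["eta"] = partitioned["eta_bird"]
    out["u"] = partitioned["u_air"] + partitioned["u_wind"]
    out["v"] = partitioned["v_air"] + partitioned["v_wind"]
    # pure-insect bins carry no bird signal: zero reflectivity, no velocity needed
    zero = partitioned["f_bird"] == 0
    out.loc[zero, "eta"] = 0.0
    return out


def _compass_to_uv(bearing_deg: float, magnitude: float = 1.0) -> tuple[float, float]:
    """(east, north) components of a compass bearing."""
    rad = math.radians(bearing_deg)
    return magnitude * math.sin(rad), magnitude * math.cos(rad)
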