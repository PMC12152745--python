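"""Nightly aggregation and seasonal episodicity statistics.

Nightly migration traffic MT (birds km⁻¹) is the time integral of the
migration traffic rate over a night; the steadiness of a season is
quantified by the coefficient of variation of nightly MTR, bootstrap
confidence intervals, the percent of nights capturing 50/75/90% of total
seasonal passage (few nights = episodic, many = steady), the chronological
20–80% and 10–90% core spans, and the 50%-crossing peak date.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .screening import NightKey


class PhenologyError(ValueError):
    pass


@dataclass(frozen=True)
class NightlySummary:
    """One night's traffic: time-weighted mean MTR, time-integrated MT."""

    night: NightKey
    mean_mtr: float      # birds km⁻¹ h⁻¹; NaN iff no scan has MTR
    mt_night: float      # birds km⁻¹
    n_scans: int
    gap_flag: bool       # an intra-night gap in usable MTR exceeded max_gap


def nightly_summaries(
    scans: pd.DataFrame,
    nights: Sequence[NightKey],
    max_gap: pd.Timedelta = pd.Timedelta(hours=1),
) -> list[NightlySummary]:
    """Aggregate integrated scans into per-night traffic.

    ``scans`` carries ``datetime``, ``mtr`` and a ``night_date`` column
    keying each scan to a night. Each scan's MTR is weighted by its
    midpoint-to-midpoint interval clipped to [sunset, sunrise];
    mt_night = Σ MTR·Δt. ``gap_flag`` is set when consecutive usable scans
    are further apart than ``max_gap``.
    """
    by_date = {n.night_date: n for n in nights}
    out: list[NightlySummary] = []
    for nd, grp in scans.groupby("night_date", sort=True):
        night = by_date.get(nd)
        if night is None:
            raise PhenologyError(f"no NightKey provided for night {nd}")
        grp = grp.sort_values("datetime")
        ts = pd.to_datetime(grp["datetime"], utc=True).astype("int64").to_numpy() / 3.6e12
        mtr = grp["mtr"].to_numpy(dtype=float)
        lo = night.sunset.value / 3.6e12   # hours since epoch
        hi = night.sunrise.value / 3.6e12
        if len(ts) == 0:
            raise PhenologyError(f"empty night group {nd}")
        mids = (ts[:-1] + ts[1:]) / 2.0
        edges = np.clip(np.concatenate(([lo], mids, [hi])), lo, hi)
        dt_h = np.diff(edges)

        usable = ~np.isnan(mtr)
        if usable.any():
            mt_night = float(np.sum(mtr[usable] * dt_h[usable]))
            mean_mtr = float(np.sum(mtr[usable] * dt_h[usable]) / np.sum(dt_h[usable]))
            gaps = np.diff(ts[usable])
            gap_flag = bool(len(gaps) and np.max(gaps) > max_gap / pd.Timedelta(hours=1))
        else:
            mt_night = 0.0
            mean_mtr = float("nan")
            gap_flag = True
        out.append(
            NightlySummary(
                night=night, mean_mtr=mean_mtr, mt_night=mt_night,
                n_scans=len(grp), gap_flag=gap_flag,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Season statistics
# ---------------------------------------------------------------------------

def season_cv(values: Sequence[float]) -> float:
    """Coefficient of variation of nightly MTR: sample (n−1) sd / mean."""
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if len(x) < 2:
        raise PhenologyError("CV needs at least two nights with MTR")
    mean = float(np.mean(x))
    if mean == 0:
        raise PhenologyError("CV undefined: mean nightly MTR is zero")
    return float(np.std(x, ddof=1) / mean)


def bootstrap_stat(
    values: Sequence[float],
    statistic: str = "mean",
    n_rep: int = 10_000,
    level: float = 95.0,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float, float]:
    """Bootstrap a nightly statistic: resample nights with replacement and
    return (point estimate, lo, hi) at the percentile interval.

    Deterministic given the seed. 10 000 replicates by default.
    """
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if len(x) < 2:
        raise PhenologyError("bootstrap needs at least two nights")
    fn: Callable[[np.ndarray], np.ndarray]
    if statistic == "mean":
        fn = lambda m: np.mean(m, axis=1)
    elif statistic == "cv":
        fn = lambda m: np.std(m, axis=1, ddof=1) / np.mean(m, axis=1)
    else:
        raise PhenologyError(f"unknown statistic {statistic!r}")
    est = float(fn(x[None, :])[0])
    if np.ptp(x) == 0:
        return est, est, est
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = rng.integers(0, len(x), size=(n_rep, len(x)))
    reps = fn(x[idx])
    alpha = (100.0 - level) / 2.0
    lo, hi = np.percentile(reps, [alpha, 100.0 - alpha])
    return est, float(lo), float(hi)


def pct_nights(mt_values: Sequence[float], fraction: float) -> float:
    """Percent of nights capturing a fraction of total seasonal passage.

    Nights are sorted by traffic descending; returns 100·k/N for the minimal
    k whose cumulative traffic reaches fraction·total. N counts the nights
    with data in the season window.
    """
    x = np.asarray(mt_values, dtype=float)
    x = x[~np.isnan(x)]
    total = float(np.sum(x))
    if not total > 0:
        raise PhenologyError("pct_nights undefined: total traffic is zero")
    if not 0.0 < fraction <= 1.0:
        raise PhenologyError("fraction must be in (0, 1]")
    csum = np.cumsum(np.sort(x)[::-1])
    k = int(np.searchsorted(csum, fraction * total - 1e-9 * total) + 1)
    return 100.0 * k / len(x)


def _first_crossing(dates: np.ndarray, csum: np.ndarray, target: float) -> date:
    idx = int(np.searchsorted(csum, target - 1e-9 * csum[-1]))
    return dates[min(idx, len(dates) - 1)]


def core_span(
    night_dates: Sequence[date], mt_values: Sequence[float], lo: float, hi: float
) -> int:
    """Days between the chronological lo- and hi-fraction cumulative crossings
    (e.g. the 20–80% or 10–90% core of a season)."""
    if not lo < hi:
        raise PhenologyError("need lo < hi")
    d, x = _chronological(night_dates, mt_values)
    total = float(np.sum(x))
    if not total > 0:
        raise PhenologyError("core_span undefined: total traffic is zero")
    csum = np.cumsum(x)
    d_lo = _first_crossing(d, csum, lo * total)
    d_hi = _first_crossing(d, csum, hi * total)
    return (d_hi - d_lo).days


def peak_date(night_dates: Sequence[date], mt_values: Sequence[float]) -> date:
    """Seasonal peak: first night by which 50% of total passage has occurred."""
    d, x = _chronological(night_dates, mt_values)
    total = float(np.sum(x))
    if not total > 0:
        raise PhenologyError("peak_date undefined: total traffic is zero")
    return _first_crossing(d, np.cumsum(x), 0.5 * total)


def cumulative_curve(
    night_dates: Sequence[date], mt_values: Sequence[float]
) -> pd.DataFrame:
    """Chronological cumulative-passage staircase, ending at fraction 1.0."""
    d, x = _chronological(night_dates, mt_values)
    total = float(np.sum(x))
    if not total > 0:
        raise PhenologyError("cumulative curve undefined: total traffic is zero")
    return pd.DataFrame({"night_date": d, "cum_fraction": np.cumsum(x) / total})


def _chronological(
    night_dates: Sequence[date], mt_values: Sequence[float]
) -> tuple[np.ndarray, np.ndarray]:
    d = np.asarray(night_dates)
    x = np.asarray(mt_values, dtype=float)
    if len(d) != len(x):
        raise PhenologyError("dates and traffic values differ in length")
    ok = ~np.isnan(x)
    d, x = d[ok], x[ok]
    order = np.argsort(d, kind="mergesort")
    return d[order], x[order]


@dataclass(frozen=True)
class SeasonPhenology:
    """Season-level episodicity summary."""

    total_mt: float
    cv: float
    cv_ci: tuple[float, float]
    mean_mtr: float
    mean_ci: tuple[float, float]
    pct_nights: dict[float, float]
    core_spans: dict[tuple[float, float], int]
    peak: date
    n_nights: int

    def to_dict(self) -> dict:
        return {
            "total_mt": self.total_mt,
            "cv": self.cv,
            "cv_ci": list(self.cv_ci),
            "mean_mtr": self.mean_mtr,
            "mean_ci": list(self.mean_ci),
            "pct_nights": {f"{k:.2f}": v for k, v in self.pct_nights.items()},
            "core_spans": {f"{a:.2f}-{b:.2f}": v for (a, b), v in self.core_spans.items()},
            "peak_date": self.peak.isoformat(),
            "n_nights": self.n_nights,
        }


def season_phenology(
    nightlies: Sequence[NightlySummary],
    n_rep: int = 10_000,
    fractions: Sequence[float] = (0.50, 0.75, 0.90),
    spans: Sequence[tuple[float, float]] = ((0.20, 0.80), (0.10, 0.90)),
    seed: int = 0,
) -> SeasonPhenology:
    """All seasonal episodicity statistics from nightly summaries."""
    dates = [n.night.night_date for n in nightlies]
    mt = [n.mt_night for n in nightlies]
    mtr = [n.mean_mtr for n in nightlies]
    rng = np.random.default_rng(seed)
    mean_est, mean_lo, mean_hi = bootstrap_stat(mtr, "mean", n_rep=n_rep, seed=rng)
    cv_est, cv_lo, cv_hi = bootstrap_stat(mtr, "cv", n_rep=n_rep, seed=rng)
    return SeasonPhenology(
        total_mt=float(np.nansum(mt)),
        cv=cv_est,
        cv_ci=(cv_lo, cv_hi),
        mean_mtr=mean_est,
        mean_ci=(mean_lo, mean_hi),
        pct_nights={f: pct_nights(mt, f) for f in fractions},
        core_spans={(a, b): core_span(dates, mt, a, b) for a, b in spans},
        peak=peak_date(dates, mt),
        n_nights=len(nightlies),
    )
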