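"""Nocturnal flight-call rates and radar–acoustic pairing.

Migrating birds give short flight calls at night; calls per hour of
recording is an independent, ground-based index of migration intensity.
Rates are computed per night (summing counts and hours across a night's
recordings), fourth-root transformed for modeling, and paired with
radar-derived bird density on nights when both sensors were operating.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats


class AcousticsError(ValueError):
    pass


@dataclass(frozen=True)
class RecordingNight:
    """One night of acoustic recording: hours after removing outages and
    reviewed call counts per taxon."""

    night_date: date
    hours: float
    calls: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.hours > 0:
            raise AcousticsError(f"night {self.night_date}: hours must be positive")
        if any(c < 0 for c in self.calls.values()):
            raise AcousticsError(f"night {self.night_date}: negative call count")


def read_calls(path: str | Path) -> list[RecordingNight]:
    """Read the calls CSV (``night,taxon,calls,hours``), aggregating each
    night's recordings (counts per taxon summed, hours from the night total)."""
    df = pd.read_csv(path)
    missing = [c for c in ("night", "taxon", "calls", "hours") if c not in df.columns]
    if missing:
        raise AcousticsError(f"{path}: missing column(s) {missing}")
    out = []
    for night, grp in df.groupby("night", sort=True):
        hours = float(grp["hours"].iloc[0])
        calls = grp.groupby("taxon")["calls"].sum().astype(int).to_dict()
        out.append(RecordingNight(pd.Timestamp(night).date(), hours, calls))
    return out


def write_calls(nights: list[RecordingNight], path: str | Path) -> Path:
    rows = [
        {"night": n.night_date.isoformat(), "taxon": t, "calls": c, "hours": n.hours}
        for n in nights
        for t, c in sorted(n.calls.items())
    ]
    pd.DataFrame(rows, columns=["night", "taxon", "calls", "hours"]).to_csv(path, index=False)
    return Path(path)


def call_rate(rec: RecordingNight, taxon: str | None = None) -> float:
    """Calls per hour for one taxon, or the total over taxa (default)."""
    if taxon is None:
        count = sum(rec.calls.values())
    else:
        count = rec.calls.get(taxon, 0)
    return count / rec.hours


def transform_rate(rate: float | np.ndarray) -> float | np.ndarray:
    """Fourth-root transform of call rate (variance-stabilizing for counts)."""
    r = np.asarray(rate, dtype=float)
    if np.any(r < 0):
        raise AcousticsError("call rate cannot be negative")
    out = r ** 0.25
    return float(out) if np.isscalar(rate) else out


def pair_with_radar(
    recordings: list[RecordingNight],
    radar_nights: pd.DataFrame,
) -> pd.DataFrame:
    """Inner-join acoustic nights with radar nights on the night date.

    ``radar_nights`` carries ``night_date`` plus radar quantities (vid and
    any covariates). Returns one row per night when both sensors operated,
    with ``call_rate`` and ``call_rate_4rt`` columns added.
    """
    ac = pd.DataFrame(
        {
            "night_date": [r.night_date for r in recordings],
            "hours": [r.hours for r in recordings],
            "call_rate": [call_rate(r) for r in recordings],
        }
    )
    paired = ac.merge(radar_nights, on="night_date", how="inner")
    if paired.empty:
        import logging

        logging.getLogger(__name__).warning(
            "no concurrent radar and acoustic nights; paired table is empty"
        )
    else:
        paired["call_rate_4rt"] = transform_rate(paired["call_rate"].to_numpy())
    return paired


def correlate(paired: pd.DataFrame, transformed: bool = True) -> tuple[float, float]:
    """Pearson correlation (r, r²) between call rate and radar bird density.

    By default the fourth-root rate is used; ``transformed=False`` gives the
    raw-rate variant. Both are reported by the pipeline.
    """
    col = "call_rate_4rt" if transformed else "call_rate"
    sub = paired[[col, "vid"]].dropna()
    if len(sub) < 3:
        raise AcousticsError("need at least three paired nights")
    if np.ptp(sub[col]) == 0 or np.ptp(sub["vid"]) == 0:
        raise AcousticsError("correlation undefined for a constant series")
    r = float(stats.pearsonr(sub[col], sub["vid"]).statistic)
    return r, r * r
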