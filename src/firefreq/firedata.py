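"""FIRMS-style active-fire hotspot aggregation.

Turns MCD14DL-format hotspot CSVs (one row per detected ~1 km fire pixel)
into the monthly modelling table, keeping only the requested detection
type codes (0 = presumed vegetation fire, 1 = active volcano, 2 = other
static land source, 3 = offshore), and joins an already-monthly climate
table.  A synthetic fixture generator makes the stage testable without
downloads.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, DataFormatError

__all__ = [
    "FIRMS_COLUMNS",
    "FirmsData",
    "read_firms_csv",
    "aggregate_monthly",
    "merge_climate",
    "make_firms_fixture",
    "summary_statistics",
]

logger = logging.getLogger(__name__)

FIRMS_COLUMNS = [
    "latitude", "longitude", "brightness", "scan", "track", "acq_date",
    "acq_time", "satellite", "confidence", "version", "bright_t31", "frp",
    "daynight", "type",
]
MANDATORY_COLUMNS = ["latitude", "longitude", "brightness", "acq_date", "frp", "type"]
CLIMATE_COLUMNS = ["year", "month", "rainfall", "tmin", "tmax"]

#: Type codes: presumed vegetation fire / volcano / static land / offshore.
VEGETATION_FIRE = 0


@dataclass
class FirmsData:
    """Validated hotspot records plus exclusion bookkeeping."""

    records: pd.DataFrame
    n_malformed: int = 0

    def __len__(self) -> int:
        return len(self.records)


def read_firms_csv(path) -> FirmsData:
    """Read a FIRMS hotspot CSV, dropping (and counting) malformed rows.

    Rows with unparseable dates or out-of-range coordinates are excluded;
    unknown extra columns pass through untouched.
    """
    records = pd.read_csv(path)
    missing = [c for c in MANDATORY_COLUMNS if c not in records.columns]
    if missing:
        raise DataFormatError(f"FIRMS file {path} missing columns: {missing}")
    n_raw = len(records)
    dates = pd.to_datetime(records["acq_date"], errors="coerce")
    valid = (
        dates.notna()
        & records["latitude"].between(-90, 90)
        & records["longitude"].between(-180, 180)
        & (records["frp"] >= 0)
    )
    records = records.loc[valid].copy()
    records["acq_date"] = dates.loc[valid]
    n_malformed = n_raw - len(records)
    if n_malformed:
        logger.warning("%s: excluded %d malformed rows", path, n_malformed)
    return FirmsData(records=records.reset_index(drop=True), n_malformed=n_malformed)


def aggregate_monthly(
    data: FirmsData | pd.DataFrame,
    type_filter: set[int] | None = frozenset({VEGETATION_FIRE}),
) -> pd.DataFrame:
    """Count retained hotspots per calendar (year, month) with mean FRP and
    brightness.  ``type_filter=None`` keeps all types.  Months with no
    retained records are absent, not zero-filled."""
    records = data.records if isinstance(data, FirmsData) else data
    if records.empty:
        raise DataFormatError("no hotspot records to aggregate")
    if type_filter is not None:
        records = records[records["type"].isin(type_filter)]
    if records.empty:
        logger.warning("no records left after type filtering")
        return pd.DataFrame(
            columns=["year", "month", "fire_count", "mean_frp", "mean_brightness"]
        )
    dates = pd.to_datetime(records["acq_date"])
    grouped = (
        records.assign(year=dates.dt.year, month=dates.dt.month)
        .groupby(["year", "month"], as_index=False)
        .agg(
            fire_count=("acq_date", "size"),
            mean_frp=("frp", "mean"),
            mean_brightness=("brightness", "mean"),
        )
        .sort_values(["year", "month"], ignore_index=True)
    )
    return grouped


def merge_climate(fire_series: pd.DataFrame, climate_table: pd.DataFrame) -> pd.DataFrame:
    """Inner-join monthly fire counts with monthly climate on (year, month).

    Emits the modelling table ``time,year,month,max_temp,tmin,rainfall,
    fire_count`` with time = 1..n in chronological order.
    """
    for name, tab in (("fire series", fire_series), ("climate table", climate_table)):
        if tab.duplicated(["year", "month"]).any():
            raise DataFormatError(f"duplicate (year, month) keys in {name}")
    missing = [c for c in CLIMATE_COLUMNS if c not in climate_table.columns]
    if missing:
        raise DataFormatError(f"climate table missing columns: {missing}")
    merged = fire_series.merge(climate_table, on=["year", "month"], how="inner")
    merged = merged.sort_values(["year", "month"], ignore_index=True)
    if len(merged) < 24:
        logger.warning("join produced only %d rows (< 24 months)", len(merged))
    merged["time"] = np.arange(1, len(merged) + 1)
    merged = merged.rename(columns={"tmax": "max_temp"})
    return merged[["time", "year", "month", "max_temp", "tmin", "rainfall", "fire_count"]]


def make_firms_fixture(
    n_records: int,
    date_range: tuple[str, str],
    rng: np.random.Generator,
    path=None,
    type_probs: dict[int, float] | None = None,
) -> pd.DataFrame:
    """Generate a synthetic FIRMS-format table with realistic field ranges.

    Latitudes/longitudes cover a Kenya-like box; the default type mix is
    80/10/10 over codes {0, 2, 3}.  Deterministic under a fixed rng.
    """
    if n_records < 1:
        raise ConfigurationError(f"n_records must be >= 1, got {n_records}")
    type_probs = type_probs or {0: 0.8, 2: 0.1, 3: 0.1}
    codes = np.array(sorted(type_probs))
    probs = np.array([type_probs[c] for c in codes], dtype=float)
    probs = probs / probs.sum()

    start, end = pd.Timestamp(date_range[0]), pd.Timestamp(date_range[1])
    n_days = (end - start).days + 1
    dates = start + pd.to_timedelta(rng.integers(0, n_days, n_records), unit="D")
    frame = pd.DataFrame(
        {
            "latitude": rng.uniform(-5.0, 5.5, n_records).round(4),
            "longitude": rng.uniform(33.9, 41.9, n_records).round(4),
            "brightness": rng.uniform(300.0, 400.0, n_records).round(1),
            "scan": rng.uniform(1.0, 2.0, n_records).round(2),
            "track": rng.uniform(1.0, 1.5, n_records).round(2),
            "acq_date": dates.strftime("%Y-%m-%d"),
            "acq_time": [f"{h:02d}{mn:02d}" for h, mn in zip(
                rng.integers(0, 24, n_records), rng.integers(0, 60, n_records))],
            "satellite": rng.choice(["Terra", "Aqua"], n_records),
            "confidence": rng.integers(30, 101, n_records),
            "version": "6.3",
            "bright_t31": rng.uniform(280.0, 320.0, n_records).round(1),
            "frp": rng.gamma(2.0, 15.0, n_records).round(1),
            "daynight": rng.choice(["D", "N"], n_records),
            "type": rng.choice(codes, n_records, p=probs),
        },
        columns=FIRMS_COLUMNS,
    )
    if path is not None:
        frame.to_csv(path, index=False)
    return frame


def summary_statistics(table: pd.DataFrame, variables: list[str] | None = None) -> pd.DataFrame:
    """Min/max/median/mean/SD block per variable (descriptive summary)."""
    variables = variables or [
        c for c in ("fire_count", "max_temp", "tmin", "rainfall") if c in table
    ]
    rows = []
    for var in variables:
        col = table[var].astype(float)
        rows.append(
            {
                "variable": var,
                "minimum": col.min(),
                "maximum": col.max(),
                "median": col.median(),
                "mean": col.mean(),
                "sd": col.std(ddof=1),
            }
        )
    return pd.DataFrame(rows)
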