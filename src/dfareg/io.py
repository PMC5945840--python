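"""Dataset ingestion, seasonal splitting and tabular result output.

Input is delimited text (CSV/TSV) with a header row, an optional
ISO-8601 timestamp column, and one numeric column per site/series.
Seasonal splitting follows the meteorological calendar-month convention:
winter = December–February, spring = March–May, summer = June–August,
fall = September–November.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("dfareg")

__all__ = [
    "InputFormatError",
    "Dataset",
    "SEASON_OF_MONTH",
    "read_dataset",
    "split_by_season",
    "write_results",
]

SEASON_OF_MONTH = {
    12: "winter", 1: "winter", 2: "winter",
    3: "spring", 4: "spring", 5: "spring",
    6: "summer", 7: "summer", 8: "summer",
    9: "fall", 10: "fall", 11: "fall",
}

SEASONS = ("winter", "spring", "summer", "fall")


class InputFormatError(ValueError):
    """Malformed input file (ragged rows, bad timestamps, non-numeric data)."""


@dataclass
class Dataset:
    """Equal-length named numeric columns with optional timestamps."""

    data: pd.DataFrame
    timestamps: pd.DatetimeIndex | None = None
    provenance: str = ""

    def __post_init__(self):
        if self.timestamps is not None and len(self.timestamps) != len(self.data):
            raise InputFormatError("timestamps and data lengths differ")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def columns(self) -> list[str]:
        return list(self.data.columns)

    def column(self, name: str) -> np.ndarray:
        return self.data[name].to_numpy()


def read_dataset(
    path,
    timestamp_column: str | None = None,
    *,
    delimiter: str | None = None,
    interpolate: bool = False,
    max_gap: int = 6,
) -> Dataset:
    """Read a delimited text file into a :class:`Dataset`.

    Missing or non-numeric payload values are an error by default; with
    ``interpolate=True`` interior gaps of at most ``max_gap`` consecutive
    rows are filled linearly.  Timestamps, when named, must parse as
    ISO-8601 and be strictly increasing.
    """
    try:
        df = pd.read_csv(path, sep=delimiter, engine="python")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise InputFormatError(f"cannot parse {path}: {exc}") from exc
    if df.empty:
        raise InputFormatError(f"{path} contains no data rows")
    timestamps = None
    if timestamp_column is not None:
        if timestamp_column not in df.columns:
            raise InputFormatError(f"no column {timestamp_column!r} in {path}")
        try:
            timestamps = pd.DatetimeIndex(
                pd.to_datetime(df[timestamp_column], format="ISO8601")
            )
        except (ValueError, TypeError) as exc:
            raise InputFormatError(f"unparseable timestamps in {path}: {exc}") from exc
        if not timestamps.is_monotonic_increasing or timestamps.has_duplicates:
            raise InputFormatError(f"timestamps in {path} are not strictly increasing")
        df = df.drop(columns=[timestamp_column])
    payload = df.apply(pd.to_numeric, errors="coerce")
    bad = payload.isna()
    if bad.to_numpy().any():
        if not interpolate:
            row = int(bad.any(axis=1).idxmax())
            raise InputFormatError(
                f"non-numeric or missing value at data row {row} of {path} "
                "(interpolation is off)"
            )
        payload = payload.interpolate(method="linear", limit=max_gap, limit_area="inside")
        if payload.isna().to_numpy().any():
            row = int(payload.isna().any(axis=1).idxmax())
            raise InputFormatError(
                f"gap too long or at series edge near row {row} of {path}"
            )
    return Dataset(data=payload, timestamps=timestamps, provenance=str(path))


def split_by_season(ds: Dataset) -> dict[str, Dataset]:
    """Partition rows into the four meteorological seasons by calendar month.

    Rows keep their original order within each season; the four outputs
    together are a permutation of the input (nothing lost or duplicated).
    """
    if ds.timestamps is None:
        raise InputFormatError("seasonal split requires timestamps")
    months = ds.timestamps.month
    labels = np.array([SEASON_OF_MONTH[m] for m in months])
    out = {}
    for season in SEASONS:
        mask = labels == season
        out[season] = Dataset(
            data=ds.data.loc[mask].reset_index(drop=True),
            timestamps=ds.timestamps[mask],
            provenance=f"{ds.provenance}#{season}",
        )
    return out


def write_results(tables: dict[str, pd.DataFrame], prefix) -> list[str]:
    """Write one CSV per named per-scale table as ``{prefix}_{name}.csv``.

    The scale column comes first; floats are written with 12 significant
    digits so a round-trip read reproduces the values.
    """
    if not tables:
        logger.warning("no result tables to write for prefix %s", prefix)
        return []
    written = []
    for name, table in tables.items():
        cols = list(table.columns)
        if "scale" in cols:
            cols = ["scale"] + [c for c in cols if c != "scale"]
        path = f"{prefix}_{name}.csv"
        table[cols].to_csv(path, index=False, float_format="%.12g")
        written.append(path)
        logger.info("wrote %s (%d rows)", path, len(table))
    return written
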