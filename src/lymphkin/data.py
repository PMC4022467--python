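"""Dataset containers and CSV readers/writers.

Three long-format layouts are supported, mirroring the public
supplementary files of the source experiments:

* migration data: one row per (organ, time) with the percent of injected
  label recovered from that organ;
* cannulation data: one row per collection time with the thoracic-duct
  output rate in percent of transferred cells per hour;
* stimulated-node data: one row per (node, time) for the antigen-stimulated
  and control popliteal lymph nodes.

Time columns must carry an explicit unit in the header (``time_min`` or
``time_h``); values are converted to minutes on read, the package-internal
canonical unit.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .params import OBSERVABLE_ORGANS

__all__ = [
    "MigrationDataset",
    "CannulationDataset",
    "StimulatedNodeData",
    "DataError",
    "read_migration_csv",
    "read_cannulation_csv",
    "read_node_csv",
]

_TIME_COLUMNS = {"time_min": 1.0, "time_minutes": 1.0, "time_h": 60.0, "time_hours": 60.0}

NODES = ("stimulated", "control")


class DataError(ValueError):
    """Raised for malformed or invalid dataset files."""


def _time_minutes(df: pd.DataFrame, path: str | None = None) -> pd.Series:
    cols = [c for c in df.columns if c.lower() in _TIME_COLUMNS]
    if not cols:
        raise DataError(
            f"{path or 'data'}: no time column with a unit tag found "
            f"(expected one of {sorted(_TIME_COLUMNS)})"
        )
    col = cols[0]
    return pd.to_numeric(df[col], errors="raise") * _TIME_COLUMNS[col.lower()]


def _check_numeric(series: pd.Series, name: str, minimum: float = 0.0) -> np.ndarray:
    values = pd.to_numeric(series, errors="coerce")
    bad = values.isna()
    if bad.any():
        row = int(bad.idxmax()) + 2  # +2: header line + 1-based
        raise DataError(f"non-numeric value in column {name!r} at file row {row}")
    if (values < minimum).any():
        row = int((values < minimum).idxmax()) + 2
        raise DataError(f"column {name!r} below {minimum} at file row {row}")
    return values.to_numpy(dtype=float)


@dataclass
class MigrationDataset:
    """Long-format (organ, time, percent recovered) measurements."""

    frame: pd.DataFrame  # columns: organ, time_min, percent

    def __post_init__(self) -> None:
        df = self.frame.reset_index(drop=True)
        unknown = ~df["organ"].isin(OBSERVABLE_ORGANS)
        if unknown.any():
            row = int(unknown.idxmax())
            raise DataError(
                f"unknown organ label {df['organ'][row]!r} at data row {row + 1} "
                f"(expected one of {OBSERVABLE_ORGANS})"
            )
        if (df["percent"] < 0).any():
            raise DataError("percent values must be >= 0")
        if (df["time_min"] < 0).any():
            raise DataError("times must be >= 0")
        if df.duplicated(["organ", "time_min"]).any():
            dup = df[df.duplicated(["organ", "time_min"])].iloc[0]
            raise DataError(
                f"duplicate record for organ {dup['organ']!r} at t={dup['time_min']} min"
            )
        self.frame = df.sort_values(["organ", "time_min"]).reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def organs(self) -> list[str]:
        return sorted(self.frame["organ"].unique())

    def organ_series(self, organ: str) -> tuple[np.ndarray, np.ndarray]:
        sub = self.frame[self.frame["organ"] == organ]
        return sub["time_min"].to_numpy(float), sub["percent"].to_numpy(float)

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)


@dataclass
class CannulationDataset:
    """Thoracic-duct output rate time series (percent of bolus per hour)."""

    frame: pd.DataFrame  # columns: time_min, rate_pct_per_h

    def __post_init__(self) -> None:
        df = self.frame.reset_index(drop=True)
        if (df["rate_pct_per_h"] < 0).any():
            raise DataError("duct output rates must be >= 0")
        if (df["time_min"] < 0).any():
            raise DataError("times must be >= 0")
        if df["time_min"].duplicated().any():
            raise DataError("duplicate collection times")
        self.frame = df.sort_values("time_min").reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def times(self) -> np.ndarray:
        return self.frame["time_min"].to_numpy(float)

    @property
    def rates(self) -> np.ndarray:
        return self.frame["rate_pct_per_h"].to_numpy(float)

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)


@dataclass
class StimulatedNodeData:
    """Label content of the stimulated vs control popliteal lymph node."""

    frame: pd.DataFrame  # columns: node, time_min, percent

    def __post_init__(self) -> None:
        df = self.frame.reset_index(drop=True)
        unknown = ~df["node"].isin(NODES)
        if unknown.any():
            row = int(unknown.idxmax())
            raise DataError(
                f"unknown node label {df['node'][row]!r} at data row {row + 1} "
                f"(expected one of {NODES})"
            )
        if (df["percent"] < 0).any():
            raise DataError("percent values must be >= 0")
        self.frame = df.sort_values(["node", "time_min"]).reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    def node_series(self, node: str) -> tuple[np.ndarray, np.ndarray]:
        sub = self.frame[self.frame["node"] == node]
        return sub["time_min"].to_numpy(float), sub["percent"].to_numpy(float)

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)


def read_migration_csv(path: str | Path) -> MigrationDataset:
    """Read a long-format migration CSV (organ, time_min|time_h, percent)."""
    df = pd.read_csv(path)
    if "organ" not in df.columns or "percent" not in df.columns:
        raise DataError(f"{path}: required columns 'organ' and 'percent' not found")
    out = pd.DataFrame(
        {
            "organ": df["organ"].astype(str).str.strip().str.lower(),
            "time_min": _time_minutes(df, str(path)),
            "percent": _check_numeric(df["percent"], "percent"),
        }
    )
    return MigrationDataset(out)


def read_cannulation_csv(path: str | Path) -> CannulationDataset:
    """Read a cannulation CSV (time_min|time_h, rate_pct_per_h)."""
    df = pd.read_csv(path)
    if "rate_pct_per_h" not in df.columns:
        raise DataError(f"{path}: required column 'rate_pct_per_h' not found")
    out = pd.DataFrame(
        {
            "time_min": _time_minutes(df, str(path)),
            "rate_pct_per_h": _check_numeric(df["rate_pct_per_h"], "rate_pct_per_h"),
        }
    )
    return CannulationDataset(out)


def read_node_csv(path: str | Path) -> StimulatedNodeData:
    """Read a stimulated-node CSV (node, time_min|time_h, percent)."""
    df = pd.read_csv(path)
    if "node" not in df.columns or "percent" not in df.columns:
        raise DataError(f"{path}: required columns 'node' and 'percent' not found")
    out = pd.DataFrame(
        {
            "node": df["node"].astype(str).str.strip().str.lower(),
            "time_min": _time_minutes(df, str(path)),
            "percent": _check_numeric(df["percent"], "percent"),
        }
    )
    return StimulatedNodeData(out)
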