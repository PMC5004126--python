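"""Time-stamped sensor tables: container, CSV I/O and grid alignment.

The :class:`TimeTable` is the exchange object for every pipeline stage.  It
wraps a :class:`pandas.DataFrame` with a ``DatetimeIndex``; missing cells are
``NaN`` and exposed through :attr:`TimeTable.mask`.  A table may consist of
several contiguous segments (e.g. two monitoring seasons separated by a
winter hole); within a segment the sampling interval is constant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError

logger = logging.getLogger(__name__)

#: reserved name of the optional ground-truth label column
MODE_COLUMN = "_mode"


@dataclass
class TimeTable:
    """Uniformly sampled (per segment) multivariate series with missing cells.

    Parameters
    ----------
    frame
        DataFrame indexed by timestamps (strictly increasing); all columns
        numeric, ``NaN`` marking missing cells.  The reserved column
        ``_mode`` carries ground-truth mode labels when present.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        idx = self.frame.index
        if not isinstance(idx, pd.DatetimeIndex):
            raise InputError("TimeTable index must be a DatetimeIndex")
        if len(idx) == 0:
            raise InputError("TimeTable must contain at least one row")
        diffs = np.diff(idx.asi8)
        if np.any(diffs < 0):
            pos = int(np.argmax(diffs < 0)) + 1
            raise InputError(f"timestamps not monotone increasing at row {pos} ({idx[pos]})")
        if np.any(diffs == 0):
            pos = int(np.argmax(diffs == 0)) + 1
            raise InputError(f"duplicate timestamp at row {pos}: {idx[pos]}")

    # ------------------------------------------------------------------ views
    @property
    def timestamps(self) -> pd.DatetimeIndex:
        return self.frame.index

    @property
    def columns(self) -> list[str]:
        """Data column names (the ground-truth label column is excluded)."""
        return [c for c in self.frame.columns if c != MODE_COLUMN]

    @property
    def data(self) -> pd.DataFrame:
        return self.frame[self.columns]

    @property
    def mask(self) -> pd.DataFrame:
        """Boolean frame, ``True`` where a data cell is missing."""
        return self.data.isna()

    @property
    def mode_labels(self) -> pd.Series | None:
        if MODE_COLUMN in self.frame.columns:
            return self.frame[MODE_COLUMN]
        return None

    def __len__(self) -> int:
        return len(self.frame)

    # ------------------------------------------------------------------ grid
    @property
    def dt_minutes(self) -> float:
        """Modal sampling interval in minutes."""
        diffs = np.diff(self.timestamps.asi8)
        if len(diffs) == 0:
            raise InputError("cannot infer a sampling interval from a single row")
        vals, counts = np.unique(diffs, return_counts=True)
        return float(vals[np.argmax(counts)] / 60e9)

    def segments(self) -> list[slice]:
        """Contiguous runs sampled at the modal interval.

        A break is declared wherever the stamp-to-stamp step differs from
        the modal interval.
        """
        idx = self.timestamps.asi8
        if len(idx) == 1:
            return [slice(0, 1)]
        dt = int(round(self.dt_minutes * 60e9))
        breaks = np.where(np.diff(idx) != dt)[0] + 1
        bounds = [0, *breaks.tolist(), len(idx)]
        return [slice(a, b) for a, b in zip(bounds[:-1], bounds[1:])]


# ---------------------------------------------------------------------- I/O

def read_table(path, timestamp_column: str | int = 0, **read_csv_kwargs) -> TimeTable:
    """Read a CSV file into a :class:`TimeTable`.

    Unparseable numeric cells become missing; their count is logged.
    Non-monotone or duplicate timestamps raise :class:`InputError`.
    """
    raw = pd.read_csv(path, **read_csv_kwargs)
    if isinstance(timestamp_column, int):
        timestamp_column = raw.columns[timestamp_column]
    try:
        stamps = pd.to_datetime(raw[timestamp_column])
    except (ValueError, TypeError) as exc:
        raise InputError(f"cannot parse timestamps in column {timestamp_column!r}: {exc}")
    data = raw.drop(columns=[timestamp_column])
    n_bad = 0
    for col in data.columns:
        coerced = pd.to_numeric(data[col], errors="coerce")
        n_bad += int((coerced.isna() & data[col].notna()).sum())
        data[col] = coerced.astype(float)
    if n_bad:
        logger.warning("%d unparseable numeric cells set to missing", n_bad)
    data.index = pd.DatetimeIndex(stamps)
    data.index.name = "timestamp"
    return TimeTable(data)


def write_table(table: TimeTable, path) -> None:
    """Write a table as CSV: ISO 8601 timestamps first, empty cells for missing."""
    out = table.frame.copy()
    out.index.name = "timestamp"
    out.to_csv(path, date_format="%Y-%m-%dT%H:%M:%S", na_rep="")


# ----------------------------------------------------------------- alignment

_AGGREGATORS = ("mean", "last", "linear-interpolation")


@dataclass
class AlignmentPolicy:
    """How to place heterogeneous-cadence series on the analysis grid.

    Aggregation is over half-open intervals ``[t, t + dt)`` stamped at ``t``.
    """

    target_dt: float = 15.0           # minutes
    aggregator: str = "mean"
    max_fill_gap: float = 180.0       # minutes; interpolation span limit

    def __post_init__(self) -> None:
        if self.target_dt <= 0:
            raise ConfigurationError("target_dt must be positive")
        if self.max_fill_gap < 0:
            raise ConfigurationError("max_fill_gap must be non-negative")
        if self.aggregator not in _AGGREGATORS:
            raise ConfigurationError(
                f"aggregator must be one of {_AGGREGATORS}, got {self.aggregator!r}")


def align(table: TimeTable, policy: AlignmentPolicy | None = None) -> TimeTable:
    """Resample a table onto the uniform ``policy.target_dt`` grid.

    ``mean``/``last`` aggregate all source points inside each half-open
    interval; intervals without any source point stay missing.  With
    ``linear-interpolation`` each grid point takes the value of the chord
    between the bracketing non-missing source points, provided their span
    does not exceed ``max_fill_gap`` minutes.
    """
    if policy is None:
        policy = AlignmentPolicy()
    if len(table) == 0:
        raise InputError("cannot align an empty table")

    dt = pd.Timedelta(minutes=policy.target_dt)
    start = table.timestamps[0].floor(dt)
    end = table.timestamps[-1].floor(dt)
    grid = pd.date_range(start, end, freq=dt, name="timestamp")

    if policy.aggregator in ("mean", "last"):
        binned = table.frame.groupby(table.timestamps.floor(dt))
        agg = binned.mean() if policy.aggregator == "mean" else binned.last()
        out = agg.reindex(grid)
    else:
        out = pd.DataFrame(index=grid, columns=table.frame.columns, dtype=float)
        t_grid = grid.asi8.astype(float)
        max_gap_ns = policy.max_fill_gap * 60e9
        for col in table.frame.columns:
            series = table.frame[col]
            valid = series.notna().to_numpy()
            if not valid.any():
                continue
            t_src = table.timestamps.asi8[valid].astype(float)
            v_src = series.to_numpy()[valid]
            vals = np.interp(t_grid, t_src, v_src)
            # distance to bracketing source points
            right = np.searchsorted(t_src, t_grid, side="left")
            left = np.clip(right - 1, 0, len(t_src) - 1)
            right = np.clip(right, 0, len(t_src) - 1)
            exact = np.isin(t_grid, t_src)
            span = t_src[right] - t_src[left]
            ok = exact | ((t_grid >= t_src[0]) & (t_grid <= t_src[-1])
                          & (span <= max_gap_ns))
            vals[~ok] = np.nan
            out[col] = vals
    return TimeTable(out)
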