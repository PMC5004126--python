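"""Seasonal detrending: Fourier low-pass baseline + high-frequency residual.

Each series is split into a two-component model: a slowly varying baseline
(all spectral content with period >= the cutoff, default 50 days) and the
residual "~" series that carries fluctuations from below the monthly scale
down to the sampling interval.  Reactive variables (rain, discharge) get a
zero baseline, so their residual is the raw series itself.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError
from .timetable import MODE_COLUMN, TimeTable

DEFAULT_ZERO_BASELINE = frozenset({"rain", "q13", "q18"})


@dataclass
class DetrendConfig:
    cutoff_period: float = 50.0                    # days
    zero_baseline_variables: frozenset[str] = DEFAULT_ZERO_BASELINE
    gapfill: str = "linear"                        # or "mean"
    per_segment: bool = True

    def __post_init__(self) -> None:
        if self.cutoff_period <= 0:
            raise ConfigurationError("cutoff_period must be positive")
        if self.gapfill not in ("linear", "mean"):
            raise ConfigurationError(f"gapfill must be 'linear' or 'mean', got {self.gapfill!r}")
        self.zero_baseline_variables = frozenset(self.zero_baseline_variables)


@dataclass
class DetrendResult:
    """Baseline and residual tables; residual is masked where raw was missing."""

    baseline: TimeTable
    residual: TimeTable
    config: DetrendConfig

    def residual_series(self, variable: str) -> pd.Series:
        return self.residual.frame[variable]


def _gapfill(values: np.ndarray, method: str) -> np.ndarray:
    """Fill NaNs by linear interpolation (edge-extended) or the series mean."""
    out = values.astype(float).copy()
    bad = ~np.isfinite(out)
    if not bad.any():
        return out
    if bad.all():
        raise InputError("all-missing series")
    good = np.where(~bad)[0]
    if method == "mean":
        out[bad] = out[good].mean()
    else:
        out[bad] = np.interp(np.where(bad)[0], good, out[good])
    return out


def fourier_lowpass_baseline(values: np.ndarray, dt_minutes: float,
                             cutoff_period_days: float = 50.0,
                             gapfill: str = "linear") -> np.ndarray:
    """Brick-wall low-pass baseline in the frequency domain.

    Missing values are gap-filled before the transform, so the baseline is
    defined at every point.  All bins with period < cutoff are zeroed; DC
    and every bin with period >= cutoff (inclusive) are retained.  No taper
    is applied; callers should discount ~2 cutoff periods at each edge.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < 8:
        raise InputError(f"series too short to detrend (n={n})")
    filled = _gapfill(values, gapfill)
    duration_days = n * dt_minutes / (60 * 24)
    if duration_days < 2 * cutoff_period_days:
        warnings.warn(
            f"record ({duration_days:.1f} d) shorter than two cutoff periods "
            f"({cutoff_period_days} d); baseline degenerates toward the mean",
            stacklevel=2)
    # A record window is generally not periodic; the implied jump between the
    # last and first sample would leak across the whole spectrum (Gibbs
    # ringing).  Two standard counter-measures, both linear: the
    # least-squares line is removed first and assigned to the baseline (a
    # line is slower than any retained bin), and the remainder is
    # mirror-padded by one cutoff period per side so the lowest retained
    # frequency sees full context at the edges.
    t = np.arange(n, dtype=float)
    slope, intercept = np.polyfit(t, filled, 1)
    line = intercept + slope * t
    y = filled - line
    pad = min(n - 1, int(round(cutoff_period_days * 24 * 60 / dt_minutes)))
    if pad > 0:
        y = np.concatenate([y[pad - 1::-1], y, y[: -pad - 1: -1]])
    spec = np.fft.rfft(y)
    freqs = np.fft.rfftfreq(len(y), d=dt_minutes * 60.0)     # Hz
    cutoff_hz = 1.0 / (cutoff_period_days * 86400.0)
    spec[freqs > cutoff_hz * (1 + 1e-12)] = 0.0              # keep period >= cutoff
    smooth = np.fft.irfft(spec, n=len(y))
    if pad > 0:
        smooth = smooth[pad: pad + n]
    return line + smooth


def detrend_table(table: TimeTable, config: DetrendConfig | None = None) -> DetrendResult:
    """Split every data column of a table into baseline + residual.

    Zero-baseline variables pass through untouched (residual = raw).  With
    ``per_segment`` true each contiguous segment is transformed separately
    and the residuals concatenated afterwards.
    """
    config = config or DetrendConfig()
    unknown = config.zero_baseline_variables - set(table.columns)
    if unknown:
        raise ConfigurationError(
            f"zero_baseline_variables not in table: {sorted(unknown)}")

    dt = table.dt_minutes
    segs = table.segments() if config.per_segment else [slice(0, len(table))]
    baseline = pd.DataFrame(index=table.timestamps, dtype=float)
    residual = pd.DataFrame(index=table.timestamps, dtype=float)
    for col in table.columns:
        raw = table.frame[col].to_numpy(dtype=float)
        if col in config.zero_baseline_variables:
            base = np.zeros(len(raw))
        else:
            base = np.empty(len(raw))
            for seg in segs:
                base[seg] = fourier_lowpass_baseline(
                    raw[seg], dt, config.cutoff_period, config.gapfill)
        resid = raw - base                       # NaN where raw is missing
        baseline[col] = base
        residual[col] = resid
    if MODE_COLUMN in table.frame.columns:
        residual[MODE_COLUMN] = table.frame[MODE_COLUMN]
    return DetrendResult(baseline=TimeTable(baseline), residual=TimeTable(residual),
                         config=config)
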