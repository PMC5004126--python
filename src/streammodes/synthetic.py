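"""Synthetic multivariate sensor tables with mode-coupled structure.

The generator emulates a two-season, 15-minute, 14-variable monitoring
record: every variable is a seasonal baseline plus a high-frequency
residual.  The variable of interest ("NO3") draws its residual from a
Gaussian mixture whose active component follows a first-order Markov chain
(mode persistence); covariate residuals are AR(1) noise plus a per-mode
additive shift, so that mode-conditioned comparisons downstream recover a
known significance pattern.  Coupling is purely statistical — there is no
physical rainfall-runoff or nitrogen-cycle model here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal

from .errors import ConfigurationError
from .timetable import MODE_COLUMN, TimeTable

#: name of the variable of interest in the default roster
NITRATE = "NO3"

#: columns whose seasonal baseline is defined as zero downstream
ZERO_BASELINE = ("rain", "q13", "q18")


# ---------------------------------------------------------------------- specs

@dataclass(frozen=True)
class MixtureSpec:
    """Gaussian mixture of the nitrate residual plus mode persistence."""

    weights: tuple[float, ...] = (0.05, 0.89, 0.06)
    means: tuple[float, ...] = (-0.59, 0.0053, 0.46)
    sds: tuple[float, ...] = (0.23, 0.21, 0.26)
    self_transition: float = 0.99

    def __post_init__(self) -> None:
        if not (len(self.weights) == len(self.means) == len(self.sds)):
            raise ConfigurationError("weights, means and sds must have equal length")
        if abs(sum(self.weights) - 1.0) > 1e-12:
            raise ConfigurationError("mixture weights must sum to 1")
        if any(s <= 0 for s in self.sds):
            raise ConfigurationError("mixture sds must be positive")
        if not 0.0 <= self.self_transition < 1.0:
            raise ConfigurationError("self_transition must be in [0, 1)")

    @property
    def n_components(self) -> int:
        return len(self.weights)

    def sample(self, n: int, rng: np.random.Generator | int) -> np.ndarray:
        """Draw ``n`` i.i.d. values from the mixture (no mode persistence)."""
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        comp = rng.choice(self.n_components, size=n, p=np.asarray(self.weights))
        return rng.normal(np.asarray(self.means)[comp], np.asarray(self.sds)[comp])


@dataclass(frozen=True)
class SeasonalSpec:
    """Slow baseline: mean + linear trend + one sinusoid."""

    amplitude: float = 0.0        # variable units
    period: float = 365.0         # days
    phase: float = 0.0            # days
    trend: float = 0.0            # variable units per day
    mean_level: float = 0.0       # variable units

    def __post_init__(self) -> None:
        if self.period <= 0:
            raise ConfigurationError("seasonal period must be positive")

    def evaluate(self, t_days: np.ndarray) -> np.ndarray:
        return (self.mean_level + self.trend * t_days
                + self.amplitude * np.sin(2 * np.pi * (t_days - self.phase) / self.period))


@dataclass(frozen=True)
class VariableSpec:
    """One generated column.

    ``seasonal=None`` marks a zero-baseline variable (reactive-catchment
    convention for rain and discharge); such series are rectified at zero.
    ``mode_shifts`` adds a per-mode offset to the residual, one entry per
    mixture component.
    """

    name: str
    seasonal: SeasonalSpec | None = field(default_factory=SeasonalSpec)
    mode_shifts: tuple[float, ...] = (0.0, 0.0, 0.0)
    noise_sd: float = 1.0
    ar1_coeff: float = 0.0
    offset: float = 0.0           # additive level for zero-baseline variables

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ConfigurationError(f"{self.name}: noise_sd must be >= 0")
        if not 0.0 <= self.ar1_coeff < 1.0:
            raise ConfigurationError(f"{self.name}: ar1_coeff must be in [0, 1)")


@dataclass(frozen=True)
class GapSpec:
    """Independent per-cell missingness."""

    missing_fraction: float = 0.04
    seed: int | None = None       # None: derived from the generate() seed

    def __post_init__(self) -> None:
        if not 0.0 <= self.missing_fraction < 1.0:
            raise ConfigurationError("missing_fraction must be in [0, 1)")


# ----------------------------------------------------------------- defaults

#: season blocks matching the published record dimensions (15,475 + 16,721 rows)
DEFAULT_SEGMENT_ROWS = (15_475, 16_721)
DEFAULT_SEGMENT_STARTS = ("2013-03-05 12:45", "2014-04-27 00:00")
DT_MINUTES = 15.0


def default_segments(dt_minutes: float = DT_MINUTES) -> list[tuple[pd.Timestamp, pd.Timestamp]]:
    """Two season blocks as (start, end) instants on the 15-min grid."""
    out = []
    for start, rows in zip(DEFAULT_SEGMENT_STARTS, DEFAULT_SEGMENT_ROWS):
        t0 = pd.Timestamp(start)
        out.append((t0, t0 + pd.Timedelta(minutes=dt_minutes * (rows - 1))))
    return out


def default_variables(n_modes: int = 3) -> list[VariableSpec]:
    """The 14-column default roster with its mode-shift directionality.

    Low mode: shallower riparian groundwater (GW32), wetter soil, less
    solar radiation, lower conductivity, higher discharge.  Typical and
    high modes share the GW32 shift (their contrast is null by
    construction) and rain carries no shift at all.
    """
    z = (0.0,) * n_modes
    season = SeasonalSpec
    return [
        VariableSpec(NITRATE, season(amplitude=4.0, mean_level=14.0, phase=80.0)),
        VariableSpec("q13", seasonal=None, offset=10.0, mode_shifts=(4.0, 0.0, 0.0),
                     noise_sd=3.0, ar1_coeff=0.5),
        VariableSpec("q18", seasonal=None, offset=14.0, mode_shifts=(5.0, 0.0, 0.0),
                     noise_sd=4.0, ar1_coeff=0.5),
        VariableSpec("Wt13", season(amplitude=7.0, mean_level=10.0, phase=100.0),
                     mode_shifts=z, noise_sd=0.8, ar1_coeff=0.5),
        VariableSpec("Wt18", season(amplitude=7.0, mean_level=10.5, phase=100.0),
                     mode_shifts=z, noise_sd=0.8, ar1_coeff=0.5),
        VariableSpec("GW3", season(amplitude=0.25, mean_level=2.0, phase=140.0),
                     mode_shifts=z, noise_sd=0.08, ar1_coeff=0.5),
        VariableSpec("GW25", season(amplitude=0.25, mean_level=1.8, phase=140.0),
                     mode_shifts=z, noise_sd=0.08, ar1_coeff=0.5),
        VariableSpec("GW32", season(amplitude=0.30, mean_level=1.5, phase=140.0),
                     mode_shifts=(-0.15, 0.0, 0.0), noise_sd=0.10, ar1_coeff=0.5),
        VariableSpec("At47", season(amplitude=10.0, mean_level=12.0, phase=110.0),
                     mode_shifts=z, noise_sd=2.5, ar1_coeff=0.5),
        VariableSpec("St24", season(amplitude=8.0, mean_level=11.0, phase=120.0),
                     mode_shifts=z, noise_sd=1.0, ar1_coeff=0.5),
        VariableSpec("Smoist24", season(amplitude=0.05, mean_level=0.30, phase=300.0),
                     mode_shifts=(0.030, 0.0, 0.0), noise_sd=0.02, ar1_coeff=0.5),
        VariableSpec("Sol71", season(amplitude=120.0, mean_level=180.0, phase=100.0),
                     mode_shifts=(-80.0, 0.0, 0.0), noise_sd=60.0, ar1_coeff=0.5),
        VariableSpec("rain", seasonal=None, offset=0.0, mode_shifts=z,
                     noise_sd=0.5, ar1_coeff=0.3),
        VariableSpec("Con47", season(amplitude=40.0, mean_level=500.0, phase=20.0),
                     mode_shifts=(-40.0, 0.0, 0.0), noise_sd=30.0, ar1_coeff=0.5),
    ]


# ------------------------------------------------------------- mode dynamics

def stationary_transition(weights: Sequence[float], self_transition: float) -> np.ndarray:
    """Markov transition matrix with the given stationary distribution.

    Off-diagonal mass is distributed proportionally to the target weights:
    ``P[i, j] = c * w[j]`` for ``i != j`` with a single global rate ``c``,
    which makes the chain reversible with stationary distribution ``w``.
    ``c`` is set so the stationary expected self-transition probability
    equals ``self_transition``.
    """
    w = np.asarray(weights, dtype=float)
    if w.ndim != 1 or len(w) < 2:
        raise ConfigurationError("weights must be a vector of length >= 2")
    if abs(w.sum() - 1.0) > 1e-12 or np.any(w < 0):
        raise ConfigurationError("weights must be a probability vector")
    if not 0.0 <= self_transition < 1.0:
        raise ConfigurationError("self_transition must be in [0, 1)")
    c = (1.0 - self_transition) / (1.0 - float(w @ w))
    P = c * np.tile(w, (len(w), 1))
    np.fill_diagonal(P, 1.0 - c * (1.0 - w))
    if np.any(np.diag(P) < 0):
        raise ConfigurationError(
            f"self_transition={self_transition} incompatible with weights {w.tolist()}: "
            "a diagonal entry would be negative")
    return P


def _simulate_modes(P: np.ndarray, weights: np.ndarray, n: int,
                    rng: np.random.Generator) -> np.ndarray:
    """Sample a mode path: stationary start, then the Markov chain."""
    cum = np.cumsum(P, axis=1)
    u = rng.random(n)
    modes = np.empty(n, dtype=np.int64)
    modes[0] = np.searchsorted(np.cumsum(weights), u[0], side="right")
    for t in range(1, n):
        modes[t] = np.searchsorted(cum[modes[t - 1]], u[t], side="right")
    return modes


def _ar1(n: int, coeff: float, marginal_sd: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary AR(1) noise with the requested marginal SD."""
    if marginal_sd == 0:
        return np.zeros(n)
    eps = rng.normal(0.0, marginal_sd * np.sqrt(1.0 - coeff ** 2), size=n)
    x0 = rng.normal(0.0, marginal_sd)
    if coeff == 0.0:
        eps[0] = x0
        return eps
    out, _ = signal.lfilter([1.0], [1.0, -coeff], eps, zi=np.array([coeff * x0]))
    return out


# ---------------------------------------------------------------- generation

def generate(mixture: MixtureSpec | None = None,
             variables: Sequence[VariableSpec] | None = None,
             segments: Sequence[tuple] | None = None,
             gaps: GapSpec | None = None,
             seed: int = 0,
             dt_minutes: float = DT_MINUTES,
             nitrate_column: str = NITRATE,
             include_mode: bool = True) -> TimeTable:
    """Generate a mode-coupled multivariate sensor table.

    The hidden mode path drives the mixture component of the nitrate
    residual and the per-mode shifts of every covariate; the optional
    ``_mode`` column records it as ground truth.
    """
    mixture = mixture or MixtureSpec()
    variables = list(variables) if variables is not None else default_variables(mixture.n_components)
    segments = list(segments) if segments is not None else default_segments(dt_minutes)
    gaps = gaps or GapSpec()

    names = [v.name for v in variables]
    if len(set(names)) != len(names):
        raise ConfigurationError("duplicate variable names")
    if nitrate_column not in names:
        raise ConfigurationError(f"no variable named {nitrate_column!r} in the roster")
    for v in variables:
        if len(v.mode_shifts) != mixture.n_components:
            raise ConfigurationError(
                f"{v.name}: mode_shifts has {len(v.mode_shifts)} entries, "
                f"expected {mixture.n_components}")

    index_parts = []
    for start, end in segments:
        start, end = pd.Timestamp(start), pd.Timestamp(end)
        if end < start:
            raise ConfigurationError(f"zero-length or inverted segment ({start} .. {end})")
        index_parts.append(pd.date_range(start, end, freq=pd.Timedelta(minutes=dt_minutes)))
    for a, b in zip(index_parts[:-1], index_parts[1:]):
        if b[0] <= a[-1]:
            raise ConfigurationError("segments must be non-overlapping and ordered")
    index = index_parts[0].append(index_parts[1:]) if len(index_parts) > 1 else index_parts[0]
    index.name = "timestamp"
    n = len(index)

    rng = np.random.default_rng(seed)
    t_days = (index.asi8 - index.asi8[0]) / (24 * 3600 * 1e9)

    P = stationary_transition(mixture.weights, mixture.self_transition)
    weights = np.asarray(mixture.weights)
    # independent mode path per segment (seasons are separate records)
    modes = np.empty(n, dtype=np.int64)
    pos = 0
    for part in index_parts:
        modes[pos:pos + len(part)] = _simulate_modes(P, weights, len(part), rng)
        pos += len(part)

    frame = pd.DataFrame(index=index)
    for v in variables:
        baseline = v.seasonal.evaluate(t_days) if v.seasonal is not None else np.full(n, v.offset)
        if v.name == nitrate_column:
            resid = rng.normal(np.asarray(mixture.means)[modes],
                               np.asarray(mixture.sds)[modes])
        else:
            resid = np.asarray(v.mode_shifts)[modes] + _ar1(n, v.ar1_coeff, v.noise_sd, rng)
        series = baseline + resid
        if v.seasonal is None:
            series = np.maximum(series, 0.0)   # reactive variables are non-negative
        frame[v.name] = series

    gap_rng = np.random.default_rng(gaps.seed) if gaps.seed is not None else rng
    if gaps.missing_fraction > 0:
        mask = gap_rng.random((n, len(variables))) < gaps.missing_fraction
        arr = frame.to_numpy()
        arr[mask] = np.nan
        frame = pd.DataFrame(arr, index=index, columns=frame.columns)

    if include_mode:
        frame[MODE_COLUMN] = modes.astype(float)
    return TimeTable(frame)
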