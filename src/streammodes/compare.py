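"""Mode-conditioned comparison of environmental covariates.

Residual values of every covariate are grouped by the synchronous nitrate
mode label; group pairs are compared with Welch's unequal-variance t-test
under Bonferroni correction, and per-class distributional summaries
(quartiles, whiskers, Pareto density curves) are produced for plotting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .detrend import DetrendResult
from .errors import DegenerateSampleError, InputError
from .mixture import ClassAssignment
from .pde import PDECurve, pde_estimate

logger = logging.getLogger(__name__)


@dataclass
class TestResult:
    t_stat: float
    df: float
    p_raw: float
    p_corrected: float
    significant: bool

    def render(self, digits: int = 3) -> str:
        return f"{self.p_corrected:.{digits}g}" if self.significant else "n.s."


@dataclass
class ComparisonTable:
    """Welch/Bonferroni results per variable and class pair (Table-style)."""

    results: dict[str, dict[tuple[str, str], TestResult | None]]
    group_stats: dict[str, dict[str, dict]]       # variable -> class -> mean/sd/n
    alpha: float
    correction_m: int
    correction_scope: str

    def pairs(self) -> list[tuple[str, str]]:
        for per_var in self.results.values():
            return list(per_var.keys())
        return []

    def to_frame(self) -> pd.DataFrame:
        """Text table: one row per variable, 'n.s.' for non-significant cells."""
        cols = {}
        for pair in self.pairs():
            name = f"{pair[0]}-{pair[1]}"
            cols[name] = [
                "untestable" if self.results[v][pair] is None
                else self.results[v][pair].render()
                for v in self.results
            ]
        return pd.DataFrame(cols, index=list(self.results.keys()))

    def significant_pairs(self, variable: str) -> list[tuple[str, str]]:
        return [p for p, r in self.results[variable].items()
                if r is not None and r.significant]


@dataclass
class ClassSummary:
    """Boxplot-style numbers plus a class-wise PDE curve per class."""

    stats: dict[str, dict]                         # class -> summary dict
    curves: dict[str, PDECurve | None] = field(default_factory=dict)


# ------------------------------------------------------------------ grouping

def group_by_mode(assignment: ClassAssignment, residuals: DetrendResult,
                  variable: str) -> dict[str, np.ndarray]:
    """Partition a variable's residuals by the synchronous nitrate class.

    Points where the nitrate label is undefined (nitrate missing) or the
    covariate is missing are dropped.
    """
    if variable not in residuals.residual.columns:
        raise InputError(f"unknown variable {variable!r}")
    values = residuals.residual.frame[variable].to_numpy(dtype=float)
    labels = assignment.labels
    if len(labels) != len(values):
        raise InputError(
            f"assignment ({len(labels)} points) does not match the residual grid "
            f"({len(values)} points)")
    keep = (labels >= 0) & np.isfinite(values)
    return {name: values[keep & (labels == k)]
            for k, name in enumerate(assignment.class_names)}


# --------------------------------------------------------------- Welch t-test

def welch_test(sample_a, sample_b) -> TestResult:
    """Two-sided Welch t-test (unequal variances, Welch-Satterthwaite df).

    Returned with ``p_corrected = p_raw`` and no significance call; the
    Bonferroni step belongs to :func:`build_comparison`.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    for name, s in (("first", a), ("second", b)):
        if len(s) < 2:
            raise DegenerateSampleError(f"{name} sample has fewer than 2 points")
        if np.var(s, ddof=1) == 0:
            raise DegenerateSampleError(f"{name} sample has zero variance")
    va, vb = np.var(a, ddof=1) / len(a), np.var(b, ddof=1) / len(b)
    t = (np.mean(a) - np.mean(b)) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va ** 2 / (len(a) - 1) + vb ** 2 / (len(b) - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return TestResult(t_stat=float(t), df=float(df), p_raw=float(p),
                      p_corrected=float(p), significant=False)


def bonferroni(p_raw: float, m: int) -> float:
    return min(1.0, m * p_raw)


# ------------------------------------------------------------ the comparison

def build_comparison(groups: dict[str, dict[str, np.ndarray]], alpha: float = 0.01,
                     correction_scope: str = "global") -> ComparisonTable:
    """All pairwise class tests per variable with Bonferroni correction.

    ``groups`` maps variable -> class -> sample.  Scope "global" corrects by
    (number of class pairs) x (number of variables); "per-variable" by the
    number of class pairs only.  Pairs with an empty or degenerate class are
    marked untestable rather than raising.
    """
    if correction_scope not in ("global", "per-variable"):
        raise InputError(f"unknown correction scope {correction_scope!r}")
    if not groups:
        raise InputError("no variables to compare")
    class_names = list(next(iter(groups.values())).keys())
    if len(class_names) < 2:
        raise InputError("need at least 2 classes")
    pairs = [(a, b) for i, a in enumerate(class_names) for b in class_names[i + 1:]]
    m = len(pairs) * (len(groups) if correction_scope == "global" else 1)

    results: dict[str, dict[tuple[str, str], TestResult | None]] = {}
    group_stats: dict[str, dict[str, dict]] = {}
    for var, per_class in groups.items():
        results[var] = {}
        group_stats[var] = {
            cls: {"mean": float(np.mean(s)) if len(s) else np.nan,
                  "sd": float(np.std(s, ddof=1)) if len(s) > 1 else np.nan,
                  "n": int(len(s))}
            for cls, s in per_class.items()
        }
        for pair in pairs:
            a, b = per_class[pair[0]], per_class[pair[1]]
            try:
                res = welch_test(a, b)
            except DegenerateSampleError as exc:
                logger.warning("%s %s-%s untestable: %s", var, *pair, exc)
                results[var][pair] = None
                continue
            res.p_corrected = bonferroni(res.p_raw, m)
            res.significant = res.p_corrected < alpha
            results[var][pair] = res
    return ComparisonTable(results=results, group_stats=group_stats, alpha=alpha,
                           correction_m=m, correction_scope=correction_scope)


# ------------------------------------------------------------------ summaries

def class_summaries(groups: dict[str, np.ndarray],
                    with_pde: bool = True) -> ClassSummary:
    """Boxplot numbers (linear-interpolation quartiles, 1.5 IQR whiskers)
    and an optional class-wise PDE curve for one variable's class samples."""
    if not groups:
        raise InputError("no classes given")
    out: dict[str, dict] = {}
    curves: dict[str, PDECurve | None] = {}
    for cls, sample in groups.items():
        s = np.asarray(sample, dtype=float)
        s = s[np.isfinite(s)]
        if len(s) == 0:
            continue
        if len(s) < 2:
            out[cls] = {"mean": float(s.mean()), "n": 1}
            curves[cls] = None
            continue
        q1, med, q3 = np.quantile(s, [0.25, 0.5, 0.75])
        iqr = q3 - q1
        in_lo = s[s >= q1 - 1.5 * iqr]
        in_hi = s[s <= q3 + 1.5 * iqr]
        out[cls] = {
            "mean": float(s.mean()),
            "median": float(med),
            "q1": float(q1),
            "q3": float(q3),
            "whisker_low": float(in_lo.min()),
            "whisker_high": float(in_hi.max()),
            "n": int(len(s)),
        }
        if with_pde:
            try:
                curves[cls] = pde_estimate(s)
            except (DegenerateSampleError, InputError):
                curves[cls] = None
        else:
            curves[cls] = None
    return ClassSummary(stats=out, curves=curves)
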