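"""1-D Gaussian mixture modelling: EM fitting, AIC/BIC model selection,
Bayes posterior classification and goodness-of-fit checks.

The residual ("~") series is modelled as a weighted sum of K Gaussians.
``em_fit`` runs expectation-maximization, ``select_k`` scans a range of K
and picks the information-criterion minimum, ``classify`` assigns each
point to the maximum-posterior component, and ``goodness_of_fit`` reports
chi-square, Kolmogorov-Smirnov and quantile-quantile diagnostics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from scipy.special import logsumexp

from .errors import DegenerateSampleError, InputError

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------- types

@dataclass
class GMMFit:
    """Fitted 1-D Gaussian mixture, components sorted by mean ascending."""

    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    loglik: float
    n_iter: int
    converged: bool

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        if not (len(self.weights) == len(self.means) == len(self.sds)):
            raise InputError("weights, means and sds must have equal length")
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise InputError("mixture weights must sum to 1")
        if np.any(self.sds <= 0):
            raise InputError("component SDs must be positive")
        order = np.argsort(self.means)
        self.weights = self.weights[order]
        self.means = self.means[order]
        self.sds = self.sds[order]

    @property
    def K(self) -> int:
        return len(self.weights)

    @property
    def n_params(self) -> int:
        """Free parameters: K means, K SDs, K-1 independent weights."""
        return 3 * self.K - 1

    def pdf(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        comp = self.weights * stats.norm.pdf(x[..., None], self.means, self.sds)
        return comp.sum(axis=-1)

    def cdf(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        comp = self.weights * stats.norm.cdf(x[..., None], self.means, self.sds)
        return comp.sum(axis=-1)

    def logpdf(self, x) -> np.ndarray:
        x = np.atleast_1d(np.asarray(x, dtype=float))
        return logsumexp(_log_component_density(x, self.weights, self.means, self.sds),
                         axis=-1)

    def ppf(self, q) -> np.ndarray:
        """Mixture quantile function by bisection (tolerance 1e-10)."""
        q = np.atleast_1d(np.asarray(q, dtype=float))
        lo = float(np.min(self.means - 10 * self.sds))
        hi = float(np.max(self.means + 10 * self.sds))
        out = np.empty_like(q)
        for i, qi in enumerate(q):
            out[i] = optimize.brentq(lambda x: self.cdf(x) - qi, lo, hi, xtol=1e-10)
        return out

    def to_dict(self) -> dict:
        return {
            "K": self.K,
            "weights": self.weights.tolist(),
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "loglik": self.loglik,
            "n_iter": self.n_iter,
            "converged": self.converged,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GMMFit":
        return cls(weights=np.array(d["weights"]), means=np.array(d["means"]),
                   sds=np.array(d["sds"]), loglik=float(d.get("loglik", np.nan)),
                   n_iter=int(d.get("n_iter", 0)), converged=bool(d.get("converged", True)))


@dataclass
class ModelSelectionTable:
    """AIC/BIC over a range of component counts."""

    rows: list[dict]                  # each: K, loglik, n_params, AIC, BIC
    chosen_k: int
    criterion: str
    agree: bool | None = None         # AIC/BIC argmin agreement (criterion="both")
    fits: dict[int, GMMFit] = field(default_factory=dict, repr=False)

    @property
    def best_fit(self) -> GMMFit:
        return self.fits[self.chosen_k]


@dataclass
class ClassAssignment:
    """Per-point posterior probabilities and argmax labels."""

    posteriors: np.ndarray            # (n, K); rows sum to 1; NaN rows for masked x
    labels: np.ndarray                # (n,) int; -1 where x was non-finite
    boundaries: np.ndarray            # (K-1,) decision thresholds
    class_names: list[str]

    @property
    def proportions(self) -> np.ndarray:
        """Fraction of classified points per class."""
        valid = self.labels >= 0
        return np.bincount(self.labels[valid], minlength=self.posteriors.shape[1]) / valid.sum()


@dataclass
class GoFReport:
    chi2_stat: float
    chi2_df: int
    chi2_p: float
    ks_stat: float
    ks_p: float
    qq_pairs: np.ndarray              # (m, 2): empirical vs model quantiles
    warning: str = ("goodness-of-fit computed against a model fitted on the same "
                    "sample; p-values are optimistic")


# ------------------------------------------------------------------ EM fitting

def _log_component_density(x, weights, means, sds):
    # (n, K) array of log(w_k * phi(x; mu_k, sd_k))
    z = (x[:, None] - means[None, :]) / sds[None, :]
    return (np.log(weights)[None, :] - np.log(sds)[None, :]
            - 0.5 * np.log(2 * np.pi) - 0.5 * z * z)


def log_likelihood(x, weights, means, sds) -> float:
    return float(logsumexp(_log_component_density(x, weights, means, sds), axis=1).sum())


def _em_step_numpy(x, w, m, s):
    """One EM sweep: returns (w', m', s', loglik at the input parameters)."""
    log_dens = _log_component_density(x, w, m, s)
    amax = log_dens.max(axis=1)
    p = np.exp(log_dens - amax[:, None])
    tot = p.sum(axis=1)
    ll = float((np.log(tot) + amax).sum())
    resp = p / tot[:, None]
    nk = resp.sum(axis=0)
    mu = (resp * x[:, None]).sum(axis=0) / nk
    var = (resp * (x[:, None] - mu[None, :]) ** 2).sum(axis=0) / nk
    return nk / len(x), mu, np.sqrt(var), ll


try:  # optional numba acceleration; the numpy path is the reference
    from numba import njit

    @njit(fastmath=True, cache=False)
    def _em_step_jit(x, w, m, s):  # pragma: no cover - exercised via _em_step
        n = x.shape[0]
        K = w.shape[0]
        lw = np.log(w) - np.log(s) - 0.5 * np.log(2 * np.pi)
        nk = np.zeros(K)
        sx = np.zeros(K)
        sxx = np.zeros(K)
        ll = 0.0
        a = np.empty(K)
        for i in range(n):
            amax = -1e308
            for k in range(K):
                z = (x[i] - m[k]) / s[k]
                a[k] = lw[k] - 0.5 * z * z
                if a[k] > amax:
                    amax = a[k]
            tot = 0.0
            for k in range(K):
                a[k] = np.exp(a[k] - amax)
                tot += a[k]
            ll += np.log(tot) + amax
            for k in range(K):
                r = a[k] / tot
                nk[k] += r
                sx[k] += r * x[i]
                sxx[k] += r * (x[i] - m[k]) * (x[i] - m[k])
        mu = np.empty(K)
        var = np.empty(K)
        for k in range(K):
            mu[k] = sx[k] / nk[k]
            # shift sxx (second moment about the old mean) to the new mean
            var[k] = sxx[k] / nk[k] - (mu[k] - m[k]) * (mu[k] - m[k])
        return nk / n, mu, np.sqrt(var), ll

    def _em_step(x, w, m, s):
        return _em_step_jit(x, w, m, s)

except ImportError:  # pragma: no cover
    _em_step = _em_step_numpy


def _em_once(x, weights, means, sds, tol, max_iter, sd_floor, rng):
    """Run EM from one start; returns (weights, means, sds, ll, n_iter, converged).

    The log-likelihood is asserted non-decreasing at every iteration (up to
    float tolerance); a component whose SD hits the floor is re-spawned at a
    random data point, which resets the monotonicity baseline.
    """
    prev_ll = -np.inf
    ll = -np.inf
    converged = False
    it = 0
    n = len(x)
    for it in range(1, max_iter + 1):
        new_w, new_m, new_s, ll = _em_step(x, weights, means, sds)
        if np.isfinite(prev_ll):
            assert ll >= prev_ll - 1e-7 * max(1.0, abs(prev_ll)), \
                f"EM log-likelihood decreased: {prev_ll} -> {ll}"
        if np.isfinite(prev_ll) and ll - prev_ll < tol:
            converged = True
            break
        prev_ll = ll
        weights, means, sds = new_w, new_m, new_s
        collapsed = (sds < sd_floor) | ~np.isfinite(sds) | (weights < 1e-12)
        if collapsed.any():
            for k in np.where(collapsed)[0]:
                means[k] = x[rng.integers(n)]
                sds[k] = max(float(np.std(x)), sd_floor)
                weights[k] = 1.0 / len(weights)
                logger.warning("component %d collapsed (sd < floor); re-spawned", k)
            weights = weights / weights.sum()
            prev_ll = -np.inf
        sds = np.maximum(sds, sd_floor)
    if not converged:
        # params were updated after ll was measured; report their own ll
        ll = log_likelihood(x, weights, means, sds)
    return weights, means, sds, ll, it, converged


def _moment_start(x, means, rng, jitter):
    """Turn candidate means into a full start by nearest-mean assignment."""
    sd = float(np.std(x))
    means = np.sort(np.asarray(means, dtype=float))
    if jitter:
        means = np.sort(means + rng.normal(0.0, 0.15 * sd, size=len(means)))
    mid = 0.5 * (means[:-1] + means[1:])
    cluster = np.searchsorted(mid, x)
    K = len(means)
    weights = np.empty(K)
    sds = np.empty(K)
    for k in range(K):
        sel = x[cluster == k]
        weights[k] = max(len(sel), 1) / len(x)
        sds[k] = float(np.std(sel)) if len(sel) > 1 else sd / K
        sds[k] = max(sds[k], 1e-3 * sd)
    weights /= weights.sum()
    return weights, means, sds


def _spread_start(x, K, rng, restart):
    """Quantile-positioned start for one restart.

    Even restarts place means at interior quantiles; odd restarts use
    tail-emphasized (Chebyshev-spaced) quantiles, which reach low-weight
    extreme components far faster on heavily unbalanced mixtures.
    Restarts beyond the first pair are jittered.
    """
    if restart % 2 == 0:
        qs = (np.arange(K) + 0.5) / K
    else:
        qs = 0.5 * (1.0 - np.cos(np.pi * (np.arange(K) + 0.5) / K))
        if K > 1:  # push the outermost starts into the tails
            qs[0], qs[-1] = min(qs[0], 0.02), max(qs[-1], 0.98)
    means = np.quantile(x, qs)
    return _moment_start(x, means, rng, jitter=restart >= 2)


def em_fit(data, K, init: GMMFit | dict | None = None, tol: float = 1e-9,
           max_iter: int = 500, n_restarts: int = 5, seed: int = 0,
           sd_floor_frac: float = 1e-6) -> GMMFit:
    """Fit a K-component Gaussian mixture by EM.

    With ``init`` given (a :class:`GMMFit` or dict with weights/means/sds)
    that single start is used as-is; otherwise ``n_restarts`` quantile-spread
    starts with jitter are run and the best log-likelihood wins.
    """
    x = np.asarray(data, dtype=float).ravel()
    x = x[np.isfinite(x)]
    n = len(x)
    if K < 1:
        raise InputError("K must be >= 1")
    if 3 * K - 1 >= n:
        raise InputError(f"too few points (n={n}) for K={K} components")
    if np.ptp(x) == 0:
        raise DegenerateSampleError("all data values identical")
    sd_floor = sd_floor_frac * float(np.ptp(x))

    if K == 1:
        # closed-form MLE
        mu, sd = float(np.mean(x)), float(np.std(x))
        ll = log_likelihood(x, np.array([1.0]), np.array([mu]), np.array([sd]))
        return GMMFit(np.array([1.0]), np.array([mu]), np.array([sd]), ll, 0, True)

    rng = np.random.default_rng(seed)
    if init is not None:
        if isinstance(init, GMMFit):
            starts = [(init.weights.copy(), init.means.copy(), init.sds.copy())]
        else:
            starts = [(np.asarray(init["weights"], float),
                       np.asarray(init["means"], float),
                       np.asarray(init["sds"], float))]
    else:
        starts = [_spread_start(x, K, rng, restart=r) for r in range(n_restarts)]

    best = None
    for w0, m0, s0 in starts:
        w, m, s, ll, n_iter, conv = _em_once(x, w0, m0, s0, tol, max_iter, sd_floor, rng)
        if best is None or ll > best[3]:
            best = (w, m, s, ll, n_iter, conv)
    w, m, s, ll, n_iter, conv = best
    return GMMFit(w, m, s, ll, n_iter, conv)


# ------------------------------------------------------------ model selection

def aic(loglik: float, n_params: int) -> float:
    return 2.0 * n_params - 2.0 * loglik


def bic(loglik: float, n_params: int, n: int) -> float:
    return n_params * np.log(n) - 2.0 * loglik


def select_k(data, k_min: int = 1, k_max: int = 10, criterion: str = "both",
             **em_kwargs) -> ModelSelectionTable:
    """Fit every K in ``[k_min, k_max]`` and choose the criterion minimum.

    With ``criterion="both"`` the AIC and BIC argmins are compared; on
    disagreement BIC wins (logged), being the more conservative mode counter.
    """
    if criterion not in ("AIC", "BIC", "both"):
        raise InputError(f"unknown criterion {criterion!r}")
    x = np.asarray(data, dtype=float).ravel()
    x = x[np.isfinite(x)]
    n = len(x)
    rows, fits = [], {}
    for K in range(k_min, k_max + 1):
        fit = em_fit(x, K, **em_kwargs)
        fits[K] = fit
        rows.append({"K": K, "loglik": fit.loglik, "n_params": fit.n_params,
                     "AIC": aic(fit.loglik, fit.n_params),
                     "BIC": bic(fit.loglik, fit.n_params, n)})
    k_aic = min(rows, key=lambda r: r["AIC"])["K"]
    k_bic = min(rows, key=lambda r: r["BIC"])["K"]
    agree = None
    if criterion == "AIC":
        chosen = k_aic
    elif criterion == "BIC":
        chosen = k_bic
    else:
        agree = k_aic == k_bic
        chosen = k_bic
        if not agree:
            logger.warning("AIC chooses K=%d but BIC chooses K=%d; using BIC", k_aic, k_bic)
    return ModelSelectionTable(rows=rows, chosen_k=chosen, criterion=criterion,
                               agree=agree, fits=fits)


# ------------------------------------------------------------- classification

_CLASS_NAMES_3 = ["low", "typical", "high"]


def class_names(K: int) -> list[str]:
    return _CLASS_NAMES_3 if K == 3 else [f"class{i}" for i in range(K)]


def classify(fit: GMMFit, data) -> ClassAssignment:
    """Bayes posterior classification: label = argmax_k w_k phi(x; mu_k, sd_k).

    Ties go to the lower-mean component.  Non-finite inputs get label -1 and
    NaN posterior rows.  Decision boundaries are the crossing points of
    adjacent components' weighted densities, found between adjacent means.
    """
    x = np.asarray(data, dtype=float).ravel()
    n = len(x)
    posteriors = np.full((n, fit.K), np.nan)
    labels = np.full(n, -1, dtype=int)
    finite = np.isfinite(x)
    if finite.any():
        log_dens = _log_component_density(x[finite], fit.weights, fit.means, fit.sds)
        post = np.exp(log_dens - logsumexp(log_dens, axis=1)[:, None])
        posteriors[finite] = post
        # argmax with ties toward the lower-mean (first) component
        labels[finite] = post.argmax(axis=1)
    boundaries = _decision_boundaries(fit)
    return ClassAssignment(posteriors=posteriors, labels=labels,
                           boundaries=boundaries, class_names=class_names(fit.K))


def _decision_boundaries(fit: GMMFit) -> np.ndarray:
    """Decision thresholds between adjacent classes.

    With unequal SDs the weighted densities of neighbouring components need
    not cross between their means (a low-weight component can be dominated
    everywhere near its own mean), so the argmax transitions are located by
    scanning and each bracket refined to the exact density crossing.
    """
    if fit.K == 1:
        return np.asarray([])

    def diff(x, a, b):
        return (fit.weights[a] * stats.norm.pdf(x, fit.means[a], fit.sds[a])
                - fit.weights[b] * stats.norm.pdf(x, fit.means[b], fit.sds[b]))

    lo = float(np.min(fit.means - 8 * fit.sds))
    hi = float(np.max(fit.means + 8 * fit.sds))
    xs = np.linspace(lo, hi, 4001)
    lab = np.argmax(_log_component_density(xs, fit.weights, fit.means, fit.sds), axis=1)
    bounds = {}
    for i in np.where(np.diff(lab) != 0)[0]:
        a, b = int(lab[i]), int(lab[i + 1])
        if b == a + 1 and a not in bounds:
            bounds[a] = optimize.brentq(diff, xs[i], xs[i + 1], args=(a, b), xtol=1e-12)
    # components never attaining argmax get a midpoint placeholder
    return np.asarray([bounds.get(k, 0.5 * (fit.means[k] + fit.means[k + 1]))
                       for k in range(fit.K - 1)])


# ------------------------------------------------------------ goodness of fit

def goodness_of_fit(fit: GMMFit, data, n_bins: int = 50) -> GoFReport:
    """Chi-square on equal-probability bins, one-sample KS, and QQ pairs.

    Chi-square df = n_bins - 1 - n_params; KS uses the asymptotic p-value;
    QQ pairs are taken at the 1..99 percentiles with model quantiles from
    numeric inversion of the mixture CDF.
    """
    x = np.asarray(data, dtype=float).ravel()
    x = x[np.isfinite(x)]
    n = len(x)
    if n_bins < 2:
        raise InputError("n_bins must be >= 2")
    if n < 5 * n_bins:
        raise InputError(f"need n >= 5*n_bins ({5 * n_bins}), got {n}")

    edges = fit.ppf(np.arange(1, n_bins) / n_bins)
    observed = np.histogram(x, bins=np.concatenate([[-np.inf], edges, [np.inf]]))[0]
    expected = np.full(n_bins, n / n_bins)
    chi2_stat = float(((observed - expected) ** 2 / expected).sum())
    chi2_df = max(n_bins - 1 - fit.n_params, 1)
    chi2_p = float(stats.chi2.sf(chi2_stat, chi2_df))

    ks = stats.ks_1samp(x, fit.cdf, mode="asymp")
    qs = np.arange(1, 100) / 100.0
    qq = np.column_stack([np.quantile(x, qs), fit.ppf(qs)])
    return GoFReport(chi2_stat=chi2_stat, chi2_df=chi2_df, chi2_p=chi2_p,
                     ks_stat=float(ks.statistic), ks_p=float(ks.pvalue), qq_pairs=qq)
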