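"""Statistical rhythm tests: ARSER and exact rank-based trend tests (JTK/RAIN).

ARSER detrends and smooths a record, locates candidate periods as peaks of an
autoregressive spectrum, fits a harmonic regression at those periods, and
scores it with an F test.

The trend tests fold the record into n phase groups per cycle and count
concordant pairs between groups.  JTK tests a monotone ordering
F_1 < ... < F_n (or its reverse); RAIN tests an umbrella with a wrap,
F_1 < ... < F_e > ... > F_n > F_1, rewarding a rise to peak group e followed
by a fall back toward the next cycle's trough.  Both use exact null
distributions under exchangeability.

Exact nulls via generating functions
------------------------------------
For JTK the statistic is the Jonckheere-Terpstra count and its null pmf is
the Gaussian (q-)multinomial: G(z) = prod_{u=1}^{N} (1 - z^u) /
prod_d prod_{v=1}^{m_d} (1 - z^v).

For RAIN, the set of counted comparisons is the comparability graph of a
series-parallel partial order: trough group 1, then the rising chain
(groups 2..e-1) in parallel with the reversed falling chain (groups n..e+1),
then peak group e on top.  The exact null pmf of a concordance count over a
series-parallel poset factorizes: a series composition contributes a
Mann-Whitney q-binomial for the cross-block comparisons, and a parallel
composition is a plain convolution.  Every factor is of the form
(1 - z^a) / (1 - z^b), so the full pmf is computed by exact integer
polynomial multiplication and division and matches brute-force enumeration
(this cannot be said of a naive product of independent per-segment nulls,
which double-uses the shared trough/peak groups).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import scipy.signal
import scipy.stats

from .timeseries import TimeSeries

try:
    from sklearn.base import BaseEstimator
except ImportError:  # pragma: no cover
    class BaseEstimator:  # type: ignore[no-redef]
        pass

__all__ = [
    "ArserResult",
    "TrendTestResult",
    "arser_preprocess",
    "ar_spectrum",
    "arser_test",
    "trend_statistic",
    "exact_null_pmf",
    "trend_pvalue",
    "scan_rhythm",
    "Arser",
    "TrendTest",
]

EXACT_BUDGET = 60  # max total observations for the exact null pmf

AR_METHODS = ("yule-walker", "mle", "burg")


# --------------------------------------------------------------------------
# ARSER
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ArserResult:
    """Outcome of the AR-spectrum + harmonic-regression + F-test pipeline."""

    periods: tuple
    amplitudes: tuple
    phases: tuple
    F_statistic: float
    p_value: float
    ar_method_chosen: str
    aic: float
    coefficients: np.ndarray | None = field(default=None, compare=False)


def arser_preprocess(ts: TimeSeries | np.ndarray, window: int | None = None,
                     polyorder: int = 4) -> TimeSeries:
    """Linear detrend followed by Savitzky-Golay smoothing of order 4.

    The default window is the largest odd integer <= N/4 (never below
    polyorder + 1); a window longer than the record is shrunk with a warning.
    """
    ts = ts if isinstance(ts, TimeSeries) else TimeSeries(np.asarray(ts, float))
    y = ts.values
    n = y.size
    if n < 9:
        raise ValueError("need at least 9 samples for ARSER preprocessing")
    if window is None:
        window = max(n // 4, polyorder + 1)
        if window % 2 == 0:
            window += 1
    if window > n:
        window = n if n % 2 == 1 else n - 1
        warnings.warn(f"smoothing window shrunk to {window}", stacklevel=2)
    if window <= polyorder:
        window = polyorder + 1 + (polyorder % 2)  # next odd above polyorder
    detrended = scipy.signal.detrend(y, type="linear")
    smoothed = scipy.signal.savgol_filter(detrended, window, polyorder)
    return ts.with_values(smoothed)


def _ar_fit(y: np.ndarray, order: int, method: str) -> tuple[np.ndarray, float]:
    """AR coefficients (y_t = sum a_k y_{t-k} + e) and innovation variance."""
    import statsmodels.regression.linear_model as smlm

    if method == "yule-walker":
        ar, sigma = smlm.yule_walker(y, order=order, method="mle")
        return ar, float(sigma) ** 2
    if method == "burg":
        ar, sigma2 = smlm.burg(y, order=order)
        return ar, float(sigma2)
    if method == "mle":
        # conditional MLE for a Gaussian AR = OLS on lagged values
        from statsmodels.tsa.ar_model import AutoReg

        fit = AutoReg(y, lags=order, trend="n").fit()
        return np.asarray(fit.params), float(fit.sigma2)
    raise ValueError(f"unknown AR method {method!r}; choose from {AR_METHODS}")


def ar_spectrum(y, order: int, method: str = "yule-walker",
                n_grid: int = 1024) -> tuple[np.ndarray, np.ndarray]:
    """AR power spectrum s(w) = sigma^2 / |1 - sum a_k exp(-iwk)|^2 on (0, pi].

    Returns (omega_grid, spectrum).  An unstable AR polynomial (roots on or
    outside the unit circle) is flagged with a warning but still evaluated.
    """
    y = y.values if isinstance(y, TimeSeries) else np.asarray(y, dtype=float)
    if order >= y.size / 2:
        raise ValueError("AR order must be below N/2")
    ar, sigma2 = _ar_fit(y, order, method)
    roots = np.roots(np.concatenate(([1.0], -ar)))
    if np.any(np.abs(roots) >= 1.0 + 1e-9):
        warnings.warn(f"unstable AR polynomial (method={method})", stacklevel=2)
    omega = np.linspace(np.pi / n_grid, np.pi, n_grid)
    k = np.arange(1, order + 1)
    denom = np.abs(1.0 - np.exp(-1j * np.outer(omega, k)) @ ar.astype(complex)) ** 2
    return omega, sigma2 / np.maximum(denom, 1e-300)


def _spectrum_peak_periods(omega: np.ndarray, s: np.ndarray, dt: float,
                           window: tuple[float, float]) -> list[float]:
    idx, _ = scipy.signal.find_peaks(s)
    periods = 2.0 * np.pi * dt / omega[idx]
    lo, hi = window
    found = [float(p) for p in periods if lo <= p <= hi]
    return sorted(found, reverse=True)


def _harmonic_fit(y: np.ndarray, t: np.ndarray, periods: list[float]):
    cols = [np.ones_like(t)]
    for T in periods:
        cols.append(np.cos(2 * np.pi * t / T))
        cols.append(np.sin(2 * np.pi * t / T))
    X = np.column_stack(cols)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    yhat = X @ beta
    rss = float(np.sum((y - yhat) ** 2))
    n = y.size
    n_par = X.shape[1]
    aic = n * math.log(max(rss, 1e-300) / n) + 2 * (n_par + 1)
    return beta, yhat, rss, aic


def arser_test(ts: TimeSeries | np.ndarray, search_window=(20.0, 28.0),
               ar_methods=AR_METHODS, order: int | None = None,
               preprocess: bool = True,
               fallback_period: float | None = "auto") -> ArserResult:
    """Full ARSER pipeline on one record.

    For each AR estimator the spectrum peaks inside ``search_window`` (hours)
    give candidate periods; a harmonic regression is fitted and the estimator
    with the best AIC wins.  The F statistic compares the harmonic fit against
    the detrended record with (r-1, N-r) degrees of freedom, r = number of
    regression coefficients.  When the spectrum shows no peak inside the
    window, the regression falls back to ``fallback_period`` ("auto" = the
    window midpoint, e.g. 24 h for the circadian window) so that p-values
    stay approximately uniform under the null; with ``fallback_period=None``
    such records instead return empty periods and p_value 1.

    The Savitzky-Golay smoothing only feeds the AR period search (it removes
    pseudo-peaks from the spectrum); the regression and F test use the
    detrended but unsmoothed record, otherwise the test statistic would be
    grossly anticonservative on autocorrelation the smoother itself creates.
    """
    ts = ts if isinstance(ts, TimeSeries) else TimeSeries(np.asarray(ts, float))
    if preprocess:
        pre = arser_preprocess(ts)
        y_fit = ts.with_values(scipy.signal.detrend(ts.values, type="linear")).values
    else:
        pre = ts
        y_fit = ts.values
    y = pre.values
    t = pre.time
    n = y.size
    if order is None:
        order = min(round(24.0 / pre.dt), n // 3)
    order = max(int(order), 1)

    best = None
    for method in ar_methods:
        try:
            omega, s = ar_spectrum(y, order, method)
        except Exception as exc:  # pragma: no cover - estimator edge failures
            warnings.warn(f"AR fit failed for {method}: {exc}", stacklevel=2)
            continue
        periods = _spectrum_peak_periods(omega, s, pre.dt, search_window)
        if not periods:
            if fallback_period is None:
                candidate = (math.inf, method, [], None, None, None)
            else:
                fb = (0.5 * (search_window[0] + search_window[1])
                      if fallback_period == "auto" else float(fallback_period))
                beta, yhat, rss, aic = _harmonic_fit(y_fit, t, [fb])
                candidate = (aic, method, [fb], beta, yhat, rss)
        else:
            beta, yhat, rss, aic = _harmonic_fit(y_fit, t, periods)
            candidate = (aic, method, periods, beta, yhat, rss)
        if best is None or candidate[0] < best[0]:
            best = candidate
    if best is None or not best[2]:
        method = best[1] if best else ar_methods[0]
        return ArserResult((), (), (), 0.0, 1.0, method, math.inf)

    aic, method, periods, beta, yhat, rss = best
    r = beta.size
    num = float(np.sum((yhat - yhat.mean()) ** 2)) / (r - 1)
    den = rss / (n - r)
    F = num / max(den, 1e-300)
    p = float(scipy.stats.f.sf(F, r - 1, n - r))
    amps, phases = [], []
    for i in range(len(periods)):
        b1, b2 = beta[1 + 2 * i], beta[2 + 2 * i]
        amps.append(float(math.hypot(b1, b2)))
        phases.append(float(math.atan2(-b2, b1)))
    return ArserResult(tuple(periods), tuple(amps), tuple(phases),
                       float(F), p, method, float(aic), coefficients=beta)


# --------------------------------------------------------------------------
# Exact trend tests
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TrendTestResult:
    """Exact trend-test outcome (statistic, null pmf and p-value)."""

    statistic: int
    null_pmf: np.ndarray
    p_value: float
    variant: str
    peak_index: int | None = None
    phase: int | None = None
    period: float | None = None
    n_tests: int = 1
    p_raw: float | None = None


def trend_statistic(groups, variant: str = "jtk", e: int | None = None,
                    midrank: bool = False) -> float:
    """Concordance count of the ordered groups against the tested shape.

    ``U_ij`` counts pairs (x in group i, y in group j) with x <= y.  JTK sums
    U_ij over i < j (monotone rise).  RAIN with peak index e sums the rising
    comparisons up to e, the falling comparisons after e with direction
    reversed (U_ji), and the wrap comparisons of the trough group 1 against
    every post-peak group.  With ``midrank`` ties count 1/2 instead of 1.
    """
    gs = [np.asarray(g, dtype=float).ravel() for g in groups]
    if any(g.size == 0 for g in gs):
        raise ValueError("empty phase group")
    n = len(gs)
    if n < 2:
        raise ValueError("need at least 2 groups")

    def U(i: int, j: int) -> float:
        a, b = gs[i][:, None], gs[j][None, :]
        if midrank:
            return float(np.sum(a < b) + 0.5 * np.sum(a == b))
        return float(np.sum(a <= b))

    if variant == "jtk":
        s = sum(U(i, j) for i in range(n) for j in range(i + 1, n))
    elif variant == "rain":
        if e is None or not (1 <= e <= n):
            raise ValueError("RAIN needs a peak index e with 1 <= e <= n")
        ei = e - 1  # 0-based peak
        s = sum(U(i, j) for i in range(ei) for j in range(i + 1, ei + 1))
        s += sum(U(j, i) for i in range(ei, n) for j in range(i + 1, n))
        s += sum(U(0, i) for i in range(ei + 1, n))
    else:
        raise ValueError(f"unknown variant {variant!r}")
    return int(s) if not midrank else s


# -- integer polynomial helpers (exact arithmetic on Python ints) ----------

def _mul_factor(p: list[int], u: int) -> list[int]:
    """p(z) * (1 - z^u)."""
    out = p + [0] * u
    for i in range(len(p)):
        out[i + u] -= p[i]
    return out


def _div_factor(p: list[int], v: int) -> list[int]:
    """Exact p(z) / (1 - z^v); raises if the division leaves a remainder."""
    out = [0] * (len(p) - v)
    for i in range(len(out)):
        out[i] = p[i] + (out[i - v] if i >= v else 0)
    if _mul_factor(out, v) != p:
        raise ArithmeticError("inexact polynomial division")
    while len(out) > 1 and out[-1] == 0:
        out.pop()
    return out


def _mw_factors(n1: int, n2: int) -> tuple[list[int], list[int]]:
    """Numerator/denominator exponents of the Mann-Whitney q-binomial
    qbinom(n1 + n2, n1)."""
    num = list(range(1, n1 + n2 + 1))
    den = list(range(1, n1 + 1)) + list(range(1, n2 + 1))
    return num, den


def _chain_factors(sizes) -> tuple[list[int], list[int]]:
    """Factors of the q-multinomial null of a monotone chain of groups."""
    num: list[int] = []
    den: list[int] = []
    total = 0
    for m in sizes:
        if total > 0:
            a, b = _mw_factors(total, m)
            num += a
            den += b
        total += m
    return num, den


def _expand(num: list[int], den: list[int]) -> list[int]:
    poly = [1]
    for u in sorted(num):
        poly = _mul_factor(poly, u)
    for v in sorted(den, reverse=True):
        poly = _div_factor(poly, v)
    return poly


@lru_cache(maxsize=512)
def _null_pmf_cached(sizes: tuple, variant: str, e: int | None) -> tuple:
    sizes_l = list(sizes)
    if variant == "jtk":
        num, den = _chain_factors(sizes_l)
    else:  # rain
        n = len(sizes_l)
        if e is None or not (2 <= e <= n):
            raise ValueError(
                "RAIN exact null needs 2 <= e <= n (e=1 makes the wrap term "
                "contradict the falling chain)")
        rise = sizes_l[1:e - 1]          # groups 2..e-1
        fall = sizes_l[e:][::-1]         # groups n..e+1 (reversed falling chain)
        num, den = _chain_factors(rise)
        a, b = _chain_factors(fall)
        num += a
        den += b
        n_mid = sum(rise) + sum(fall)
        for lo, hi in ((sizes_l[0], n_mid), (sizes_l[0] + n_mid, sizes_l[e - 1])):
            if lo and hi:
                a, b = _mw_factors(lo, hi)
                num += a
                den += b
    counts = _expand(num, den)
    total = sum(counts)
    return tuple(c / total for c in counts)


def exact_null_pmf(group_sizes, variant: str = "jtk",
                   e: int | None = None) -> np.ndarray:
    """Exact null pmf f(0..s_max) of the trend statistic under exchangeability.

    Computed by exact integer polynomial arithmetic (see module docstring);
    the result sums to 1 up to float conversion.  Total observations are
    capped at ``EXACT_BUDGET`` = 60.
    """
    sizes = tuple(int(m) for m in group_sizes)
    if any(m < 1 for m in sizes) or len(sizes) < 2:
        raise ValueError("need >= 2 groups with sizes >= 1")
    if sum(sizes) > EXACT_BUDGET:
        raise ValueError(
            f"total observations {sum(sizes)} exceed the exact-arithmetic "
            f"budget {EXACT_BUDGET}; subsample or pool phase groups")
    return np.asarray(_null_pmf_cached(sizes, variant, e), dtype=float)


def trend_pvalue(s: float, pmf: np.ndarray,
                 alternative: str = "greater") -> float:
    """Exact p-value from the null pmf.

    ``greater``: upper tail P(S >= s).  ``two-sided`` (JTK's monotone test):
    twice the smaller of the increasing/decreasing tails, capped at 1.
    """
    pmf = np.asarray(pmf, dtype=float)
    s_ceil = int(math.ceil(s - 1e-9))
    if not (0 <= s_ceil <= pmf.size - 1):
        raise ValueError("statistic outside the pmf support")
    upper = 1.0 if s_ceil == 0 else float(pmf[s_ceil:].sum())
    if alternative == "greater":
        return min(1.0, max(upper, 0.0))
    if alternative == "two-sided":
        lower = float(pmf[:int(math.floor(s + 1e-9)) + 1].sum())
        return min(1.0, 2.0 * min(upper, lower))
    raise ValueError(f"unknown alternative {alternative!r}")


def _fold_groups(values: np.ndarray, n: int) -> list[np.ndarray]:
    return [values[i::n] for i in range(n)]


@lru_cache(maxsize=512)
def _null_sf_cached(sizes: tuple, variant: str, e: int | None) -> np.ndarray:
    """Survival function sf[s] = P(S >= s) of the cached exact null."""
    pmf = np.asarray(_null_pmf_cached(sizes, variant, e))
    return np.concatenate([pmf[::-1].cumsum()[::-1], [0.0]])


def _pair_matrix(groups, midrank: bool) -> np.ndarray:
    """U[i, j] = number of pairs (x in group i, y in group j) with x <= y."""
    n = len(groups)
    U = np.empty((n, n))
    for i in range(n):
        a = groups[i][:, None]
        for j in range(n):
            b = groups[j][None, :]
            if midrank:
                U[i, j] = np.sum(a < b) + 0.5 * np.sum(a == b)
            else:
                U[i, j] = np.sum(a <= b)
    return U


def scan_rhythm(ts: TimeSeries | np.ndarray, period: float,
                variant: str = "jtk", midrank: bool = False) -> TrendTestResult:
    """Scan phases (and peak positions for RAIN) for a rhythm of given period.

    Samples are folded into ``n = period / dt`` phase groups across cycles.
    JTK evaluates the two-sided monotone test at every cyclic phase rotation;
    RAIN evaluates the umbrella test at every rotation and every peak position
    e in 2..n.  The best raw p-value is Bonferroni-corrected by the number of
    tests performed.
    """
    ts = ts if isinstance(ts, TimeSeries) else TimeSeries(np.asarray(ts, float))
    ratio = period / ts.dt
    n = int(round(ratio))
    if abs(ratio - n) > 1e-9:
        warnings.warn(f"period/dt = {ratio:.4g} is not an integer; "
                      f"using n = {n} phase groups", stacklevel=2)
    if n < 3:
        raise ValueError("period must span at least 3 samples")
    if len(ts) < n:
        raise ValueError("record shorter than one period")
    groups = _fold_groups(ts.values, n)
    if sum(len(g) for g in groups) > EXACT_BUDGET:
        raise ValueError(
            f"record length {len(ts)} exceeds the exact-null budget "
            f"{EXACT_BUDGET}; subsample first")
    U = _pair_matrix(groups, midrank)

    # statistics for every phase rotation are masked sums over the pair matrix
    tests = []  # (p_raw, statistic, phase, e)
    for phase in range(n):
        idx = (np.arange(n) + phase) % n
        Ur = U[np.ix_(idx, idx)]
        sizes = tuple(len(groups[i]) for i in idx)
        if variant == "jtk":
            s = float(np.triu(Ur, 1).sum())
            sf = _null_sf_cached(sizes, "jtk", None)
            s_hi = int(math.ceil(s - 1e-9))
            upper = sf[s_hi]
            lower = 1.0 - sf[int(math.floor(s + 1e-9)) + 1]
            tests.append((min(1.0, 2.0 * min(upper, lower)), s, phase, None))
        elif variant == "rain":
            # incremental rising / falling / wrap sums over the peak position
            col_lower = [float(Ur[p + 1:, p].sum()) for p in range(n)]
            row_upper = [float(Ur[:p, p].sum()) for p in range(n)]
            wrap_sfx = np.concatenate([np.cumsum(Ur[0, ::-1])[::-1], [0.0]])
            rising = 0.0
            falling = [0.0] * (n + 1)
            for p in range(n - 1, -1, -1):
                falling[p] = falling[p + 1] + col_lower[p]
            for e in range(2, n + 1):
                p_peak = e - 1
                rising += row_upper[p_peak]
                s = rising + falling[p_peak] + float(wrap_sfx[p_peak + 1])
                sf = _null_sf_cached(sizes, "rain", e)
                tests.append((float(sf[int(math.ceil(s - 1e-9))]), s, phase, e))
        else:
            raise ValueError(f"unknown variant {variant!r}")
    n_tests = n if variant == "jtk" else n * (n - 1)

    p_raw, s, phase, e = min(tests, key=lambda t: t[0])
    pmf = np.asarray(_null_pmf_cached(
        tuple(len(groups[(i + phase) % n]) for i in range(n)), variant, e))
    return TrendTestResult(
        statistic=int(round(s)), null_pmf=np.asarray(pmf), p_value=min(1.0, p_raw * n_tests),
        variant=variant, peak_index=e, phase=phase, period=period,
        n_tests=n_tests, p_raw=p_raw)


# --------------------------------------------------------------------------
# Estimator wrappers
# --------------------------------------------------------------------------

class Arser(BaseEstimator):
    """ARSER as a fit-style detector.

    Attributes after ``fit``: ``result_`` (ArserResult), ``p_value_``,
    ``periods_``, ``amplitudes_``, ``phases_``.
    """

    def __init__(self, search_window=(20.0, 28.0), ar_methods=AR_METHODS,
                 order: int | None = None):
        self.search_window = search_window
        self.ar_methods = ar_methods
        self.order = order

    def fit(self, y, X=None):
        self.result_ = arser_test(y, search_window=self.search_window,
                                  ar_methods=self.ar_methods, order=self.order)
        self.p_value_ = self.result_.p_value
        self.periods_ = self.result_.periods
        self.amplitudes_ = self.result_.amplitudes
        self.phases_ = self.result_.phases
        return self


class TrendTest(BaseEstimator):
    """JTK/RAIN phase-scanning trend test as a fit-style detector."""

    def __init__(self, period: float = 24.0, variant: str = "jtk",
                 midrank: bool = False):
        self.period = period
        self.variant = variant
        self.midrank = midrank

    def fit(self, y, X=None):
        self.result_ = scan_rhythm(y, self.period, variant=self.variant,
                                   midrank=self.midrank)
        self.p_value_ = self.result_.p_value
        self.statistic_ = self.result_.statistic
        return self
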