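"""Catalog of 25 scalar time-series measures.

The catalog combines the three elementary statistics (minimum, maximum,
average) with 22 measures drawn from the canonical "catch22" set of
time-series features: distribution shape (histogram modes), temporal
run statistics, autocorrelation timescales, spectral summaries, simple
forecasting errors, information-theoretic symbolization statistics,
fluctuation analysis and a periodicity estimate.  Each measure maps a
real-valued series to a single float and is deterministic.

All 22 non-elementary measures are computed on the z-scored series
(sample standard deviation, guarded so that a constant series z-scores
to all zeros); MIN/MAX/AVG use the raw values.  A measure applied to a
series shorter than its ``min_length``, or degenerate in a way that
makes its definition vacuous (e.g. fluctuation analysis with too few
usable scales), returns ``nan`` — an explicit "undefined" sentinel that
downstream consumers must skip, never a silent zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import LSQUnivariateSpline

__all__ = [
    "MeasureId",
    "FeatureTriple",
    "measure_catalog",
    "compute_measure",
    "feature_matrix",
    "MEASURE_SYMBOLS",
]


@dataclass(frozen=True)
class MeasureId:
    """Identity of a catalog measure: symbol, prose description, minimum series length."""

    symbol: str
    description: str
    min_length: int


@dataclass(frozen=True)
class FeatureTriple:
    """An (electrode, band, measure) feature address.

    For a 64-electrode montage with 13 bands the full enumeration has
    64 x 13 x 25 = 20800 triples.
    """

    electrode: str
    band: int  # 1..13
    measure: str  # catalog symbol

    @property
    def name(self) -> str:
        return f"{self.electrode}.F{self.band}.{self.measure}"


# ---------------------------------------------------------------------------
# shared helpers
# ---------------------------------------------------------------------------


def _zscore(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    sd = y.std(ddof=1) if y.size > 1 else 0.0
    if sd == 0.0:
        return np.zeros_like(y)
    return (y - y.mean()) / sd


def _acf(y: np.ndarray) -> np.ndarray:
    """Autocorrelation at lags 0..n-1 (biased estimator, FFT-based)."""
    y = np.asarray(y, dtype=float)
    n = y.size
    yc = y - y.mean()
    nfft = 1 << int(n * 2 - 1).bit_length()
    f = np.fft.rfft(yc, nfft)
    ac = np.fft.irfft(f * np.conj(f), nfft)[:n]
    if ac[0] <= 0:
        out = np.zeros(n)
        out[0] = 1.0
        return out
    return ac / ac[0]


def _first_zero_ac(y: np.ndarray) -> int:
    """Smallest lag tau >= 1 with acf(tau) <= 0, capped at n - 1."""
    a = _acf(y)
    for tau in range(1, len(a)):
        if a[tau] <= 0:
            return tau
    return len(a) - 1


def _longest_run(mask: np.ndarray) -> int:
    best = run = 0
    for v in mask:
        run = run + 1 if v else 0
        best = max(best, run)
    return best


def _histogram_mode(z: np.ndarray, n_bins: int) -> float:
    lo, hi = float(z.min()), float(z.max())
    if lo == hi:
        return lo
    counts, edges = np.histogram(z, bins=n_bins, range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    return float(centers[counts == counts.max()].mean())


def _tertial_symbols(y: np.ndarray) -> np.ndarray:
    """Equiprobable 3-letter symbolization: letters 0/1/2 split at the tertiles."""
    t1, t2 = np.quantile(y, [1.0 / 3.0, 2.0 / 3.0])
    return np.digitize(y, [t1, t2], right=True)


# ---------------------------------------------------------------------------
# measure implementations (z-scored input unless noted)
# ---------------------------------------------------------------------------


def _m_min(y):
    return float(np.min(y))


def _m_max(y):
    return float(np.max(y))


def _m_avg(y):
    return float(np.mean(y))


def _m_z5(y):
    return _histogram_mode(_zscore(y), 5)


def _m_z10(y):
    return _histogram_mode(_zscore(y), 10)


def _m_c(y):
    # longest run of consecutive values strictly above the series mean
    y = np.asarray(y, dtype=float)
    return float(_longest_run(y > y.mean()))


def _prefix_medians(seq: np.ndarray) -> np.ndarray:
    """Running median after each prefix of ``seq`` (two-heap algorithm)."""
    import heapq

    lo: list[float] = []  # max-heap (negated)
    hi: list[float] = []  # min-heap
    out = np.empty(len(seq))
    for i, v in enumerate(seq):
        if not lo or v <= -lo[0]:
            heapq.heappush(lo, -v)
        else:
            heapq.heappush(hi, v)
        if len(lo) > len(hi) + 1:
            heapq.heappush(hi, -heapq.heappop(lo))
        elif len(hi) > len(lo):
            heapq.heappush(lo, -heapq.heappop(hi))
        out[i] = -lo[0] if len(lo) > len(hi) else (-lo[0] + hi[0]) / 2.0
    return out


def _outlier_include_mdrmd(z: np.ndarray, sign: int) -> float:
    """Median (over inclusion thresholds) of the relative median position of
    extreme events at least ``thr`` standard deviations above (sign=+1) or
    below (sign=-1) the mean; thresholds advance in 0.01-sd steps and are
    trimmed where fewer than 2% of points qualify."""
    y = sign * z
    n = y.size
    inc = 0.01
    top = float(y.max())
    if top < inc:
        return 0.0
    thresholds = np.arange(0.0, top + inc, inc)
    # events at threshold thr are the top-k positions by value, k = #{y >= thr};
    # their median position comes from a running prefix median over positions
    # ordered by descending value
    order = np.argsort(-y, kind="stable")
    y_desc = y[order]
    ks = np.searchsorted(-y_desc, -thresholds, side="right")
    ks = ks[ks >= 1]
    pos_medians = _prefix_medians((order + 1).astype(float))
    rel_pos = pos_medians[ks - 1] / (n / 2.0) - 1.0
    spacing_pct = (ks - 1) * 100.0 / n
    above = np.flatnonzero(spacing_pct > 2.0)
    keep = int(above[-1]) if above.size else 0
    return float(np.median(rel_pos[: keep + 1]))


def _m_a(y):
    return _outlier_include_mdrmd(_zscore(y), +1)


def _m_b(y):
    return _outlier_include_mdrmd(_zscore(y), -1)


def _m_fc(y):
    # first 1/e crossing of the autocorrelation function, linearly interpolated
    a = _acf(_zscore(y))
    thresh = 1.0 / math.e
    for i in range(len(a) - 1):
        if a[i + 1] < thresh:
            return float(i + (thresh - a[i]) / (a[i + 1] - a[i]))
    return float(len(a))


def _m_fm(y):
    a = _acf(_zscore(y))
    for i in range(1, len(a) - 1):
        if a[i] < a[i - 1] and a[i] < a[i + 1]:
            return float(i)
    return float(len(a))


def _spectrum(z: np.ndarray):
    """One-sided rectangular-window periodogram of a z-scored series,
    zero-padded to the next power of two; returns (freqs in cycles/sample, power)."""
    n = z.size
    nfft = 1 << int(n - 1).bit_length()
    spec = np.abs(np.fft.rfft(z, nfft)) ** 2 / n
    freqs = np.fft.rfftfreq(nfft)
    return freqs, spec


def _m_tp(y):
    freqs, spec = _spectrum(_zscore(y))
    df = freqs[1] - freqs[0]
    mask = freqs <= freqs[-1] / 5.0
    return float(spec[mask].sum() * df)


def _m_ce(y):
    freqs, spec = _spectrum(_zscore(y))
    cs = np.cumsum(spec)
    if cs[-1] <= 0:
        return 0.0
    half = cs[-1] / 2.0
    k = int(np.searchsorted(cs, half))
    if k == 0:
        return float(freqs[0])
    # linear interpolation inside the crossing bin
    frac = (half - cs[k - 1]) / (cs[k] - cs[k - 1])
    return float(freqs[k - 1] + frac * (freqs[k] - freqs[k - 1]))


def _m_me(y):
    z = _zscore(y)
    w = 3
    means = np.convolve(z, np.ones(w) / w, mode="valid")[:-1]
    res = z[w:] - means
    if res.size < 2:
        return float("nan")
    return float(res.std(ddof=1))


def _m_tr(y):
    z = _zscore(y)
    return float(np.mean(np.diff(z) ** 3))


def _m_ai(y, tau: int = 2, n_bins: int = 5):
    # automutual information with even-width binning, lag 2, 5 bins, in nats
    z = _zscore(y)
    lo, hi = float(z.min()), float(z.max())
    if lo == hi:
        return 0.0
    edges = np.linspace(lo, hi, n_bins + 1)
    edges[-1] = np.nextafter(edges[-1], np.inf)
    joint, _, _ = np.histogram2d(z[:-tau], z[tau:], bins=[edges, edges])
    total = joint.sum()
    if total == 0:
        return 0.0
    p = joint / total
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    return float(np.sum(p[nz] * np.log(p[nz] / (px @ py)[nz])))


def _m_fmai(y):
    # first minimum of the Gaussian auto-mutual-information function over lags 1..40
    z = _zscore(y)
    a = _acf(z)
    tau_max = min(40, len(a) - 1)
    if tau_max < 1:
        return float("nan")
    rho2 = np.clip(a[1 : tau_max + 1] ** 2, 0.0, 1.0 - 1e-15)
    ami = -0.5 * np.log(1.0 - rho2)
    for i in range(1, len(ami) - 1):
        if ami[i] < ami[i - 1] and ami[i] < ami[i + 1]:
            return float(i + 1)  # lags are 1-based
    return float(tau_max)


def _m_pd(y):
    z = _zscore(y)
    return float(np.mean(np.abs(np.diff(z)) > 0.04))


def _m_lp(y):
    # longest run of successive decreases
    d = np.diff(np.asarray(y, dtype=float))
    return float(_longest_run(d < 0))


def _m_en(y):
    z = _zscore(y)
    letters = _tertial_symbols(z)
    pairs = letters[:-1] * 3 + letters[1:]
    counts = np.bincount(pairs, minlength=9).astype(float)
    p = counts / counts.sum()
    nz = p > 0
    return float(-np.sum(p[nz] * np.log(p[nz])))


def _m_cc(y):
    # ratio of the first-zero ACF timescale of the differenced series to
    # that of the original series
    z = _zscore(y)
    res = np.diff(z)
    if res.size < 3:
        return float("nan")
    return float(_first_zero_ac(res)) / float(_first_zero_ac(z))


def _m_ef(y):
    # 2-d time-delay embedding at the first-zero ACF lag; mean absolute
    # difference between the empirical density of successive point-to-point
    # distances and a max-likelihood exponential fit
    z = _zscore(y)
    n = z.size
    tau = min(_first_zero_ac(z), max(1, n // 10))
    x1, x2 = z[:-tau], z[tau:]
    d = np.hypot(np.diff(x1), np.diff(x2))
    if d.size < 3 or d.max() == d.min():
        return float("nan")
    lam = float(d.mean())
    n_bins = int(math.ceil(math.sqrt(d.size)))
    counts, edges = np.histogram(d, bins=n_bins)
    width = edges[1] - edges[0]
    density = counts / (d.size * width)
    centers = 0.5 * (edges[:-1] + edges[1:])
    pdf = np.exp(-centers / lam) / lam
    return float(np.mean(np.abs(density - pdf)))


def _fluct_prop_r1(y, kind: str) -> float:
    """Fluctuation analysis on the cumulative sum: F(tau) over ~50 log-spaced
    scales in [5, n/2]; two straight lines are fitted to (log tau, log F)
    around the split that minimizes total squared error, and the returned
    statistic is the fraction of scales assigned to the first (slower-growth)
    regime."""
    z = _zscore(y)
    n = z.size
    if n < 20:
        return float("nan")
    x = np.cumsum(z - z.mean())
    taus = np.unique(
        np.round(np.logspace(math.log10(5), math.log10(n / 2.0), 50)).astype(int)
    )
    taus = taus[(taus >= 5) & (taus <= n // 2)]
    if taus.size < 6:
        return float("nan")
    F = np.empty(taus.size)
    for k, tau in enumerate(taus):
        nseg = n // tau
        segs = x[: nseg * tau].reshape(nseg, tau)
        t = np.arange(tau, dtype=float)
        tc = t - t.mean()
        denom = float(np.sum(tc * tc))
        slopes = segs @ tc / denom
        resid = segs - segs.mean(axis=1, keepdims=True) - slopes[:, None] * tc
        if kind == "dfa":
            F[k] = math.sqrt(float(np.mean(resid**2)))
        elif kind == "rsrange":
            rng = resid.max(axis=1) - resid.min(axis=1)
            F[k] = math.sqrt(float(np.mean(rng**2)))
        else:  # pragma: no cover
            raise ValueError(kind)
    if np.any(F <= 0):
        return float("nan")
    lt, lf = np.log(taus.astype(float)), np.log(F)
    m = taus.size
    pre = _linfit_sse_prefixes(lt, lf)
    suf = _linfit_sse_prefixes(lt[::-1], lf[::-1])[::-1]
    best_k, best_err = None, math.inf
    for k in range(3, m - 2):  # each regime keeps >= 3 scales
        err = pre[k - 1] + suf[k]
        if err < best_err:
            best_k, best_err = k, err
    if best_k is None:
        return float("nan")
    return best_k / m


def _linfit_sse_prefixes(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """SSE of the least-squares line through (x[:k], y[:k]) for every k,
    via closed-form centered cumulative sums."""
    k = np.arange(1, x.size + 1, dtype=float)
    cx, cy = np.cumsum(x), np.cumsum(y)
    cxx, cxy, cyy = np.cumsum(x * x), np.cumsum(x * y), np.cumsum(y * y)
    sxx = cxx - cx * cx / k
    sxy = cxy - cx * cy / k
    syy = cyy - cy * cy / k
    with np.errstate(divide="ignore", invalid="ignore"):
        sse = syy - np.where(sxx > 0, sxy * sxy / np.maximum(sxx, 1e-300), 0.0)
    return np.maximum(sse, 0.0)


def _m_fdfa(y):
    return _fluct_prop_r1(y, "dfa")


def _m_flf(y):
    return _fluct_prop_r1(y, "rsrange")


def _m_tc(y):
    # 3-letter symbolization of the series downsampled at the first-zero ACF
    # lag; trace of the covariance matrix of the transition-probability matrix
    z = _zscore(y)
    tau = _first_zero_ac(z)
    ds = z[::tau]
    if ds.size < 5:
        return float("nan")
    letters = _tertial_symbols(ds)
    pairs = letters[:-1] * 3 + letters[1:]
    T = np.bincount(pairs, minlength=9).astype(float).reshape(3, 3)
    T /= T.sum()
    cov = np.cov(T, rowvar=False, ddof=1)
    return float(np.trace(cov))


def _m_pm(y):
    """Wang periodicity: detrend with a least-squares cubic spline (one
    interior knot), then return the lag of the first ACF peak that follows a
    trough and clears it by at least 0.01 while being positive; 0 if none."""
    z = _zscore(y)
    n = z.size
    t = np.arange(n, dtype=float)
    try:
        spline = LSQUnivariateSpline(t, z, [n / 2.0], k=3)
        yd = z - spline(t)
    except Exception:
        return float("nan")
    a = _acf(yd)
    th = 0.01
    i = 1
    m = len(a) - 1
    while i < m:
        # next trough
        while i < m and not (a[i] < a[i - 1] and a[i] < a[i + 1]):
            i += 1
        if i >= m:
            return 0.0
        trough = i
        # next peak after the trough
        j = trough + 1
        while j < m and not (a[j] > a[j - 1] and a[j] > a[j + 1]):
            j += 1
        if j >= m:
            return 0.0
        if a[j] - a[trough] >= th and a[j] > 0:
            return float(j)
        i = trough + 1
    return 0.0


# ---------------------------------------------------------------------------
# catalog
# ---------------------------------------------------------------------------

_CATALOG: list[tuple[str, str, int, Callable]] = [
    ("MIN", "minimum", 3, _m_min),
    ("MAX", "maximum", 3, _m_max),
    ("AVG", "average", 3, _m_avg),
    ("Z5", "mode of z-scored distribution (5-bin histogram)", 10, _m_z5),
    ("Z10", "mode of z-scored distribution (10-bin histogram)", 10, _m_z10),
    ("C", "longest period of consecutive values above the mean", 10, _m_c),
    ("A", "time intervals between successive extreme events above the mean", 10, _m_a),
    ("B", "time intervals between successive extreme events below the mean", 10, _m_b),
    ("FC", "first 1/e crossing of autocorrelation function", 10, _m_fc),
    ("FM", "first minimum of autocorrelation function", 10, _m_fm),
    ("TP", "total power in lowest 1/5 of frequencies in the Fourier power spectrum", 10, _m_tp),
    ("CE", "centroid of the Fourier power spectrum", 10, _m_ce),
    ("ME", "mean error from rolling 3-sample mean forecasting", 10, _m_me),
    ("TR", "time-reversibility statistic <(x_{t+1}-x_t)^3>_t", 10, _m_tr),
    ("AI", "automutual information (m=2, tau=5)", 10, _m_ai),
    ("FMAI", "first minimum of the automutual information function", 10, _m_fmai),
    ("PD", "proportion of successive differences exceeding 0.04 sigma", 10, _m_pd),
    ("LP", "longest period of successive incremental decreases", 10, _m_lp),
    ("EN", "entropy of two successive letters in equiprobable 3-letter symbolization", 10, _m_en),
    ("CC", "change in correlation length after iterative differencing", 10, _m_cc),
    ("EF", "exponential fit to successive distances in 2-d embedding space", 10, _m_ef),
    ("FDFA", "ratio of slower timescale fluctuations that scale with DFA (50% sampling)", 50, _m_fdfa),
    ("FLF", "ratio of slower timescale fluctuations that scale with linearly rescaled range fits", 50, _m_flf),
    ("TC", "trace of covariance of transition matrix between symbols in 3-letter alphabet", 10, _m_tc),
    ("PM", "periodicity measure", 10, _m_pm),
]

_FUNCS = {sym: fn for sym, _, _, fn in _CATALOG}
_IDS = {sym: MeasureId(sym, desc, ml) for sym, desc, ml, _ in _CATALOG}

MEASURE_SYMBOLS: tuple[str, ...] = tuple(sym for sym, _, _, _ in _CATALOG)


def measure_catalog() -> list[MeasureId]:
    """Return the 25 catalog measures in their canonical order."""
    return [_IDS[s] for s in MEASURE_SYMBOLS]


def compute_measure(measure: "MeasureId | str", series: Sequence[float]) -> float:
    """Apply a catalog measure to a series.

    Returns ``nan`` when the series is shorter than the measure's minimum
    length or the measure's definition is degenerate on the input.
    """
    symbol = measure.symbol if isinstance(measure, MeasureId) else measure
    if symbol not in _FUNCS:
        raise KeyError(f"unknown measure symbol: {symbol!r}")
    y = np.asarray(series, dtype=float)
    if y.ndim != 1:
        raise ValueError("series must be one-dimensional")
    if y.size < _IDS[symbol].min_length:
        return float("nan")
    return float(_FUNCS[symbol](y))


def feature_matrix(spectrograms, triples: Sequence[FeatureTriple]) -> pd.DataFrame:
    """Instances x features table of measures over whole-trial band series.

    ``spectrograms`` is a sequence of :class:`~eeglike.spectra.BandSpectrogram`;
    cell (i, j) applies triple j's measure to the full frame series of
    instance i at the triple's electrode and band.  Columns are named
    ``electrode.Fband.MEASURE``.
    """
    rows = []
    index = []
    for spec in spectrograms:
        row = np.empty(len(triples))
        for j, tr in enumerate(triples):
            row[j] = compute_measure(tr.measure, spec.series(tr.electrode, tr.band))
        rows.append(row)
        index.append(spec.key)
    return pd.DataFrame(rows, index=index, columns=[t.name for t in triples])
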