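"""Naive, loop-based reference implementations of the 22 non-elementary
catalog measures, written directly from their definitions and independently
of the package's vectorized versions.  Used as the oracle in the
measure-equivalence tests."""

from __future__ import annotations

import math

import numpy as np
from scipy.interpolate import LSQUnivariateSpline
from scipy.signal import periodogram


def zscore(y):
    y = np.asarray(y, dtype=float)
    sd = y.std(ddof=1)
    if sd == 0:
        return np.zeros_like(y)
    return (y - y.mean()) / sd


def acf_direct(y):
    """Autocorrelation lags 0..n-1 by direct products (no FFT)."""
    y = np.asarray(y, dtype=float)
    n = len(y)
    yc = y - y.mean()
    denom = float(np.dot(yc, yc))
    if denom <= 0:
        out = np.zeros(n)
        out[0] = 1.0
        return out
    return np.array([float(np.dot(yc[: n - k], yc[k:])) / denom for k in range(n)])


def first_zero_ac(y):
    a = acf_direct(y)
    for tau in range(1, len(a)):
        if a[tau] <= 0:
            return tau
    return len(a) - 1


def histogram_mode(z, nbins):
    lo, hi = min(z), max(z)
    if lo == hi:
        return float(lo)
    width = (hi - lo) / nbins
    counts = [0] * nbins
    for v in z:
        b = int((v - lo) / width)
        if b == nbins:  # the maximum lands in the last bin
            b -= 1
        counts[b] += 1
    mx = max(counts)
    centers = [lo + (b + 0.5) * width for b in range(nbins) if counts[b] == mx]
    return float(sum(centers) / len(centers))


def ref_z5(y):
    return histogram_mode(list(zscore(y)), 5)


def ref_z10(y):
    return histogram_mode(list(zscore(y)), 10)


def ref_c(y):
    y = np.asarray(y, dtype=float)
    m = y.mean()
    best = run = 0
    for v in y:
        run = run + 1 if v > m else 0
        best = max(best, run)
    return float(best)


def _ref_outlier(y, sign):
    z = sign * zscore(y)
    n = len(z)
    inc = 0.01
    top = float(max(z))
    if top < inc:
        return 0.0
    rel, pct = [], []
    thr = 0.0
    while thr <= top + inc:
        idx = [i + 1 for i in range(n) if z[i] >= thr]
        if idx:
            pct.append((len(idx) - 1) * 100.0 / n)
            rel.append(float(np.median(idx)) / (n / 2.0) - 1.0)
        thr += inc
    keep = 0
    for j in range(len(pct)):
        if pct[j] > 2.0:
            keep = j
    return float(np.median(rel[: keep + 1]))


def ref_a(y):
    return _ref_outlier(y, +1)


def ref_b(y):
    return _ref_outlier(y, -1)


def ref_fc(y):
    a = acf_direct(zscore(y))
    th = 1.0 / math.e
    for i in range(len(a) - 1):
        if a[i + 1] < th:
            return i + (th - a[i]) / (a[i + 1] - a[i])
    return float(len(a))


def ref_fm(y):
    a = acf_direct(zscore(y))
    for i in range(1, len(a) - 1):
        if a[i] < a[i - 1] and a[i] < a[i + 1]:
            return float(i)
    return float(len(a))


def _ref_spectrum(y):
    z = zscore(y)
    n = len(z)
    nfft = 1
    while nfft < n:
        nfft *= 2
    freqs, spec = periodogram(z, window="boxcar", nfft=nfft, scaling="density",
                              return_onesided=True, detrend=False)
    # undo the one-sided doubling so the spectrum is plain |X|^2 / n
    spec = spec.copy()
    spec[1:-1] /= 2.0
    return freqs, spec


def ref_tp(y):
    freqs, spec = _ref_spectrum(y)
    df = freqs[1] - freqs[0]
    return float(sum(s for f, s in zip(freqs, spec) if f <= freqs[-1] / 5.0) * df)


def ref_ce(y):
    freqs, spec = _ref_spectrum(y)
    cs = np.cumsum(spec)
    if cs[-1] <= 0:
        return 0.0
    half = cs[-1] / 2.0
    for k in range(len(cs)):
        if cs[k] >= half:
            if k == 0:
                return float(freqs[0])
            frac = (half - cs[k - 1]) / (cs[k] - cs[k - 1])
            return float(freqs[k - 1] + frac * (freqs[k] - freqs[k - 1]))
    return float(freqs[-1])


def ref_me(y):
    z = zscore(y)
    res = [z[i] - (z[i - 3] + z[i - 2] + z[i - 1]) / 3.0 for i in range(3, len(z))]
    return float(np.std(res, ddof=1))


def ref_tr(y):
    z = zscore(y)
    d = [(z[i + 1] - z[i]) ** 3 for i in range(len(z) - 1)]
    return float(sum(d) / len(d))


def ref_ai(y, tau=2, nbins=5):
    z = zscore(y)
    lo, hi = float(min(z)), float(max(z))
    if lo == hi:
        return 0.0
    width = (hi - lo) / nbins

    def bin_of(v):
        b = int((v - lo) / width)
        return nbins - 1 if b >= nbins else b

    joint = np.zeros((nbins, nbins))
    for i in range(len(z) - tau):
        joint[bin_of(z[i]), bin_of(z[i + tau])] += 1
    p = joint / joint.sum()
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mi = 0.0
    for i in range(nbins):
        for j in range(nbins):
            if p[i, j] > 0:
                mi += p[i, j] * math.log(p[i, j] / (px[i] * py[j]))
    return float(mi)


def ref_fmai(y):
    a = acf_direct(zscore(y))
    tau_max = min(40, len(a) - 1)
    ami = []
    for t in range(1, tau_max + 1):
        r2 = min(a[t] ** 2, 1.0 - 1e-15)
        ami.append(-0.5 * math.log(1.0 - r2))
    for i in range(1, len(ami) - 1):
        if ami[i] < ami[i - 1] and ami[i] < ami[i + 1]:
            return float(i + 1)
    return float(tau_max)


def ref_pd(y):
    z = zscore(y)
    d = [abs(z[i + 1] - z[i]) for i in range(len(z) - 1)]
    return float(sum(1 for v in d if v > 0.04) / len(d))


def ref_lp(y):
    y = np.asarray(y, dtype=float)
    best = run = 0
    for i in range(len(y) - 1):
        run = run + 1 if y[i + 1] - y[i] < 0 else 0
        best = max(best, run)
    return float(best)


def _symbols3(y):
    t1, t2 = np.quantile(y, [1.0 / 3.0, 2.0 / 3.0])
    return [0 if v <= t1 else (1 if v <= t2 else 2) for v in y]


def ref_en(y):
    letters = _symbols3(zscore(y))
    counts = {}
    for a, b in zip(letters[:-1], letters[1:]):
        counts[(a, b)] = counts.get((a, b), 0) + 1
    n = len(letters) - 1
    return float(-sum((c / n) * math.log(c / n) for c in counts.values()))


def ref_cc(y):
    z = zscore(y)
    res = np.diff(z)
    return float(first_zero_ac(res)) / float(first_zero_ac(z))


def ref_ef(y):
    z = zscore(y)
    n = len(z)
    tau = min(first_zero_ac(z), max(1, n // 10))
    pts = [(z[i], z[i + tau]) for i in range(n - tau)]
    d = [math.hypot(pts[i + 1][0] - pts[i][0], pts[i + 1][1] - pts[i][1])
         for i in range(len(pts) - 1)]
    if len(d) < 3 or max(d) == min(d):
        return float("nan")
    lam = sum(d) / len(d)
    nbins = int(math.ceil(math.sqrt(len(d))))
    counts, edges = np.histogram(d, bins=nbins)
    width = edges[1] - edges[0]
    diffs = []
    for b in range(nbins):
        c = 0.5 * (edges[b] + edges[b + 1])
        emp = counts[b] / (len(d) * width)
        diffs.append(abs(emp - math.exp(-c / lam) / lam))
    return float(sum(diffs) / len(diffs))


def _ref_fluct(y, kind):
    z = zscore(y)
    n = len(z)
    if n < 20:
        return float("nan")
    x = np.cumsum(z - z.mean())
    raw = np.round(np.logspace(math.log10(5), math.log10(n / 2.0), 50)).astype(int)
    taus = sorted({int(t) for t in raw if 5 <= t <= n // 2})
    if len(taus) < 6:
        return float("nan")
    F = []
    for tau in taus:
        nseg = n // tau
        acc = []
        for s in range(nseg):
            seg = x[s * tau : (s + 1) * tau]
            t = np.arange(tau, dtype=float)
            b1, b0 = np.polyfit(t, seg, 1)
            resid = seg - (b1 * t + b0)
            if kind == "dfa":
                acc.extend(resid**2)
            else:
                acc.append((resid.max() - resid.min()) ** 2)
        F.append(math.sqrt(float(np.mean(acc))))
    F = np.array(F)
    if np.any(F <= 0):
        return float("nan")
    lt = np.log(np.array(taus, dtype=float))
    lf = np.log(F)

    def sse(xs, ys):
        if len(xs) < 2:
            return 0.0
        b1, b0 = np.polyfit(xs, ys, 1)
        return float(np.sum((ys - (b1 * xs + b0)) ** 2))

    m = len(taus)
    best_k, best_err = None, math.inf
    for k in range(3, m - 2):
        err = sse(lt[:k], lf[:k]) + sse(lt[k:], lf[k:])
        if err < best_err:
            best_k, best_err = k, err
    return best_k / m if best_k is not None else float("nan")


def ref_fdfa(y):
    return _ref_fluct(y, "dfa")


def ref_flf(y):
    return _ref_fluct(y, "rsrange")


def ref_tc(y):
    z = zscore(y)
    tau = first_zero_ac(z)
    ds = z[::tau]
    if len(ds) < 5:
        return float("nan")
    letters = _symbols3(ds)
    T = np.zeros((3, 3))
    for a, b in zip(letters[:-1], letters[1:]):
        T[a, b] += 1
    T /= T.sum()
    cols = [T[:, j] for j in range(3)]
    cov = np.cov(np.array(cols).T, rowvar=False, ddof=1)
    return float(np.trace(cov))


def ref_pm(y):
    z = zscore(y)
    n = len(z)
    t = np.arange(n, dtype=float)
    spline = LSQUnivariateSpline(t, z, [n / 2.0], k=3)
    a = acf_direct(z - spline(t))
    troughs = [i for i in range(1, len(a) - 1) if a[i] < a[i - 1] and a[i] < a[i + 1]]
    peaks = [i for i in range(1, len(a) - 1) if a[i] > a[i - 1] and a[i] > a[i + 1]]
    for tr in troughs:
        after = [p for p in peaks if p > tr]
        if not after:
            return 0.0
        p = after[0]
        if a[p] - a[tr] >= 0.01 and a[p] > 0:
            return float(p)
    return 0.0


REFERENCES = {
    "Z5": ref_z5, "Z10": ref_z10, "C": ref_c, "A": ref_a, "B": ref_b,
    "FC": ref_fc, "FM": ref_fm, "TP": ref_tp, "CE": ref_ce, "ME": ref_me,
    "TR": ref_tr, "AI": ref_ai, "FMAI": ref_fmai, "PD": ref_pd, "LP": ref_lp,
    "EN": ref_en, "CC": ref_cc, "EF": ref_ef, "FDFA": ref_fdfa, "FLF": ref_flf,
    "TC": ref_tc, "PM": ref_pm,
}
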