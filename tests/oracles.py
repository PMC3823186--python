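"""Independent brute-force / textbook-formula oracles used by the tests.

Everything here is deliberately written the slow, literal way (explicit
loops over window positions, closed-form statistics) and shares no code
path with the package implementation it checks.
"""

from __future__ import annotations

import math

import numpy as np


# ---------------------------------------------------------------------------
# Detector oracle: a literal reading of the detection rule
# ---------------------------------------------------------------------------


def oracle_smooth(data: np.ndarray, span: int) -> np.ndarray:
    """Centred moving average with symmetrically shrinking edge windows."""
    n = len(data)
    half = span // 2
    out = np.empty_like(data, dtype=float)
    for i in range(n):
        m = min(half, i, n - 1 - i)
        out[i] = data[i - m : i + m + 1].mean(axis=0)
    return out


def oracle_window_ranges(data: np.ndarray, w: int) -> np.ndarray:
    n = len(data)
    out = np.empty((n - w + 1, data.shape[1]))
    for j in range(n - w + 1):
        win = data[j : j + w]
        out[j] = win.max(axis=0) - win.min(axis=0)
    return out


def oracle_detect(data: np.ndarray, fs: float, window_ms: float = 400.0,
                  threshold: float = 0.2, quiescence_ms: float = 400.0) -> list[tuple[int, int]]:
    """Literal event detection: per-window range scan, maximal supra-threshold
    runs, quiescence check before and after.  Returns (start, end) sample
    intervals (end = last run position + window span)."""
    w = int(round(window_ms * fs / 1000.0))
    q = max(1, int(round(quiescence_ms * fs / 1000.0)))
    n = len(data)
    if n < w + 2 * q or n < w:
        return []
    ranges = oracle_window_ranges(data, w)
    n_pos = len(ranges)
    above = [bool((ranges[j] > threshold).any()) for j in range(n_pos)]
    quiet = [bool((ranges[j] < threshold).all()) for j in range(n_pos)]
    events = []
    j = 0
    while j < n_pos:
        if not above[j]:
            j += 1
            continue
        f = j
        while j + 1 < n_pos and above[j + 1]:
            j += 1
        l = j
        j += 1
        if f - q < 0 or l + q > n_pos - 1:
            continue
        if all(quiet[p] for p in range(f - q, f)) and all(quiet[p] for p in range(l + 1, l + q + 1)):
            events.append((f, l + w))
    return events


# ---------------------------------------------------------------------------
# Textbook statistics
# ---------------------------------------------------------------------------


def t_pooled(a, b) -> tuple[float, int]:
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    sp2 = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) / (na + nb - 2)
    t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))
    return t, na + nb - 2


def t_one_sample(x) -> tuple[float, int]:
    x = np.asarray(x, float)
    n = len(x)
    sd = math.sqrt(((x - x.mean()) ** 2).sum() / (n - 1))
    return x.mean() / (sd / math.sqrt(n)), n - 1


def mann_whitney_u(a, b) -> float:
    """U statistic for sample a by direct pair counting."""
    u = 0.0
    for x in a:
        for y in b:
            if x > y:
                u += 1.0
            elif x == y:
                u += 0.5
    return u


def pearson_r(x, y) -> float:
    x, y = np.asarray(x, float), np.asarray(y, float)
    xc, yc = x - x.mean(), y - y.mean()
    return float((xc * yc).sum() / math.sqrt((xc**2).sum() * (yc**2).sum()))


def partial_r_precision(x, y, z) -> float:
    """Partial correlation via the inverse-correlation-matrix identity."""
    z = np.asarray(z, float)
    if z.ndim == 1:
        z = z[:, None]
    mat = np.column_stack([x, y, z])
    prec = np.linalg.inv(np.corrcoef(mat, rowvar=False))
    return float(-prec[0, 1] / math.sqrt(prec[0, 0] * prec[1, 1]))


def fisher_z(r1, n1, r2, n2) -> float:
    return (math.atanh(r1) - math.atanh(r2)) / math.sqrt(1 / (n1 - 3) + 1 / (n2 - 3))


def splitplot_interaction_f(groups, y1, y2) -> tuple[float, tuple[int, int]]:
    """Balanced split-plot interaction F from the full cell-mean
    sums-of-squares decomposition (between-subject factor × 2-level
    within factor)."""
    groups = np.asarray(groups)
    y = np.column_stack([np.asarray(y1, float), np.asarray(y2, float)])
    levels = list(dict.fromkeys(groups.tolist()))
    a, b = len(levels), 2
    n_per = {g: int((groups == g).sum()) for g in levels}
    assert len(set(n_per.values())) == 1, "oracle assumes balanced groups"
    n = next(iter(n_per.values()))
    grand = y.mean()
    cell = {(g, s): y[groups == g, s].mean() for g in levels for s in range(b)}
    gmean = {g: y[groups == g].mean() for g in levels}
    smean = {s: y[:, s].mean() for s in range(b)}
    ss_inter = n * sum((cell[(g, s)] - gmean[g] - smean[s] + grand) ** 2
                       for g in levels for s in range(b))
    subj_mean = y.mean(axis=1)
    ss_werr = 0.0
    for g in levels:
        yg = y[groups == g]
        sm = subj_mean[groups == g]
        for s in range(b):
            ss_werr += ((yg[:, s] - sm - cell[(g, s)] + gmean[g]) ** 2).sum()
    df1 = (a - 1) * (b - 1)
    df2 = a * n * (b - 1) - a * (b - 1) - (a * n - a)
    # equivalently (N - a)(b - 1)
    N = a * n
    df2 = (N - a) * (b - 1)
    f = (ss_inter / df1) / (ss_werr / df2)
    return f, (df1, df2)


def nested_f(y, x_full, x_red) -> tuple[float, tuple[int, int]]:
    """Group-effect F via residual sums of squares of nested OLS fits."""
    y = np.asarray(y, float)

    def rss(X):
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return float(r @ r)

    r_full, r_red = rss(x_full), rss(x_red)
    df1 = x_full.shape[1] - x_red.shape[1]
    df2 = len(y) - x_full.shape[1]
    return ((r_red - r_full) / df1) / (r_full / df2), (df1, df2)
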