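"""Independent brute-force oracles used to pin down expected values.

These deliberately avoid the library's own numerics: the exponential-fit
oracle is an exhaustive tau grid with per-tau linear least squares via
``numpy.linalg.lstsq``, and the leak oracle is direct summation plus the
two-point formula.
"""

from __future__ import annotations

import numpy as np


def grid_exponential_fit(ts, y, tau_lo, tau_hi, n_grid=2000):
    """Exhaustive single-exponential fit: tau over a log grid, (a, c) by
    exact linear least squares at each tau.  Returns (a, tau, c, rmse)."""
    ts = np.asarray(ts, float)
    y = np.asarray(y, float)
    best = (np.inf, None)
    for tau in np.geomspace(tau_lo, tau_hi, n_grid):
        X = np.column_stack([np.exp(-ts / tau), np.ones_like(ts)])
        coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ coef
        rss = float(r @ r)
        if rss < best[0]:
            best = (rss, (coef[0], tau, coef[1]))
    rss, (a, tau, c) = best
    return a, tau, c, np.sqrt(rss / len(y))


def two_point_leak(times, currents, t1_end, t2_end, v1, v2, window):
    """Window means by direct summation + the two-point leak formula."""
    times = np.asarray(times, float)
    currents = np.asarray(currents, float)

    def mean_in(lo, hi):
        total = 0.0
        count = 0
        for t, c in zip(times, currents):
            if lo <= t < hi:
                total += c
                count += 1
        return total / count

    i1 = mean_in(t1_end - window, t1_end)
    i2 = mean_in(t2_end - window, t2_end)
    g = (i1 - i2) / (v1 - v2)
    e = v1 - i1 / g
    return g, e


def brute_force_runs(voltages, delta_v):
    """Reference step segmentation: left-to-right maximal runs where every
    sample stays within +/-delta_v of the run median (recomputed each
    extension)."""
    runs = []
    start = 0
    current = [voltages[0]]
    for i in range(1, len(voltages)):
        candidate = current + [voltages[i]]
        med = float(np.median(candidate))
        if max(candidate) - med > delta_v or med - min(candidate) > delta_v:
            runs.append((start, i))
            start = i
            current = [voltages[i]]
        else:
            current = candidate
    runs.append((start, len(voltages)))
    return runs
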