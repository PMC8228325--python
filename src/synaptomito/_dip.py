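"""Dip-style unimodality statistic.

The statistic is the sup-norm distance from the empirical CDF to the nearest
unimodal CDF.  For a candidate mode position m the best unimodal fit is
convex to the left of m and concave to the right, and the sup distance of a
function to the convex (concave) cone equals half the maximal gap to its
greatest convex minorant (least concave majorant).  The statistic minimizes
over candidate modes at the sample points; the p-value is Monte Carlo against
the uniform null, the standard conservative (asymptotically least favorable)
reference distribution for unimodality testing.
"""

from __future__ import annotations

import numpy as np


def _max_above_gcm(x: np.ndarray, f: np.ndarray) -> float:
    """Max of f - (greatest convex minorant of f) over the points."""
    hull: list[int] = []
    n = len(x)
    for i in range(n):
        while len(hull) >= 2:
            i1, i2 = hull[-2], hull[-1]
            cross = (x[i2] - x[i1]) * (f[i] - f[i1]) - (f[i2] - f[i1]) * (x[i] - x[i1])
            if cross <= 0:  # middle point above or on chord: not part of minorant
                hull.pop()
            else:
                break
        hull.append(i)
    best = 0.0
    for a, b in zip(hull[:-1], hull[1:]):
        if x[b] == x[a]:
            continue
        slope = (f[b] - f[a]) / (x[b] - x[a])
        seg = f[a + 1 : b] - (f[a] + slope * (x[a + 1 : b] - x[a]))
        if seg.size:
            best = max(best, float(seg.max()))
    return best


def _max_below_lcm(x: np.ndarray, f: np.ndarray) -> float:
    """Max of (least concave majorant of f) - f over the points."""
    # lcm(f) = -gcm(-f), so lcm(f) - f = (-f) - gcm(-f)
    return _max_above_gcm(x, -f)


def dip_statistic(values) -> float:
    """Sup-norm distance from the empirical CDF to the nearest unimodal CDF."""
    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)
    if n < 4 or x[0] == x[-1]:
        return 0.0 if n == 0 else 1.0 / (2.0 * n)
    f = (np.arange(1, n + 1) - 0.5) / n
    # left deviations for all prefixes / right deviations for all suffixes
    left = np.empty(n)
    right = np.empty(n)
    for m in range(n):
        left[m] = _max_above_gcm(x[: m + 1], f[: m + 1])
        right[m] = _max_below_lcm(x[m:], f[m:])
    best = float(np.min(np.maximum(left, right)))
    return max(best / 2.0, 1.0 / (2.0 * n))


def dip_test(values, n_mc: int = 200, seed=None) -> tuple[float, float]:
    """Dip statistic plus Monte-Carlo p-value vs the uniform unimodal null."""
    x = np.asarray(values, dtype=float)
    d_obs = dip_statistic(x)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_mc):
        if dip_statistic(rng.random(len(x))) >= d_obs:
            exceed += 1
    p = (1.0 + exceed) / (n_mc + 1.0)
    return d_obs, p
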