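"""Independent reference implementations used only to check the package.

These deliberately share no code with icefox internals: the speed filter is
checked against exhaustive subset enumeration, and the bridge UD against a
dense per-cell loop built on scipy.stats.norm.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import norm


def brute_force_speed_filter(t_s, x, y, v_max_kmh, v_burst_kmh, t_burst_min):
    """Maximal prefix-greedy retained set via exhaustive enumeration.

    Enumerates every subset containing the first fix whose consecutive
    retained pairs all satisfy the elapsed-time-conditional speed rule, and
    returns the one with the lexicographically greatest inclusion vector
    (i.e. preferring to keep earlier points). Only for tracks of <= 12 fixes.
    """
    n = len(t_s)
    assert n <= 12

    def ok(i, j):
        dt = t_s[j] - t_s[i]
        speed = np.hypot(x[j] - x[i], y[j] - y[i]) / 1000.0 / (dt / 3600.0)
        limit = v_burst_kmh if dt <= t_burst_min * 60.0 else v_max_kmh
        return speed <= limit

    best = None
    for bits in range(1 << (n - 1)):
        subset = [0] + [i + 1 for i in range(n - 1) if (bits >> i) & 1]
        if all(ok(subset[k], subset[k + 1]) for k in range(len(subset) - 1)):
            vec = tuple(1 if i in set(subset) else 0 for i in range(n))
            if best is None or vec > best[0]:
                best = (vec, subset)
    return best[1]


def dense_bridge_ud(traj, sigma2, geom, n_alpha=30, err_factor=0.5, floor_frac=0.1):
    """Static Brownian-bridge UD by dense per-cell evaluation."""
    t = traj["timestamp"].astype("int64").to_numpy() / 1e9
    x = traj["x"].to_numpy()
    y = traj["y"].to_numpy()
    sd = err_factor * traj["error_radius"].to_numpy()
    xs = geom.x_centers
    ys = geom.y_centers
    vals = np.zeros((geom.nrows, geom.ncols))
    alphas = np.linspace(0.0, 1.0, n_alpha)
    w = np.ones(n_alpha)
    w[0] = w[-1] = 0.5
    w /= w.sum()
    floor = (floor_frac * geom.cell_size) ** 2
    for s in range(len(traj) - 1):
        T = t[s + 1] - t[s]
        for a, wk in zip(alphas, w):
            v = T * a * (1 - a) * sigma2 + (1 - a) ** 2 * sd[s] ** 2 + a**2 * sd[s + 1] ** 2
            v = max(v, floor)
            mx = x[s] + a * (x[s + 1] - x[s])
            my = y[s] + a * (y[s + 1] - y[s])
            sdv = np.sqrt(v)
            vals += T * wk * np.outer(norm.pdf(ys, my, sdv), norm.pdf(xs, mx, sdv))
    return vals / vals.sum()


def bridge_negloglik_hand(obs_xy, p1, p2, t1, t_obs, t2, sigma2, sd1=0.0, sd2=0.0, sd_obs=0.0):
    """Hand evaluation of one leave-one-out bivariate-normal density term."""
    T = t2 - t1
    a = (t_obs - t1) / T
    v = T * a * (1 - a) * sigma2 + (1 - a) ** 2 * sd1**2 + a**2 * sd2**2 + sd_obs**2
    mx = p1[0] + a * (p2[0] - p1[0])
    my = p1[1] + a * (p2[1] - p1[1])
    r2 = (obs_xy[0] - mx) ** 2 + (obs_xy[1] - my) ** 2
    return np.log(2 * np.pi * v) + r2 / (2 * v)
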