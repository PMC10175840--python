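"""Independent brute-force oracles used by the test suite.

Each function re-derives an expected value by direct enumeration or a literal
framewise re-implementation, deliberately avoiding the vectorized library
code paths it is used to check.
"""

import math
from itertools import combinations
from math import comb

import numpy as np
import scipy.stats as sps

from nemoresponse.behavior import _merge_short_bouts


def peak_amplitudes_brute(t_s, dr_pct, window):
    """Window extrema by an explicit python scan (half-open window)."""
    included = [v for t, v in zip(t_s, dr_pct) if window[0] <= t < window[1]]
    return max(included), min(included)


def segmentation_brute(traj, params):
    """Literal framewise classifier + the documented merge rule."""
    xs, ys, dt = traj.x_mm, traj.y_mm, traj.dt_s
    labels = []
    mode, ref = "forward", None
    alpha = min(1.0, dt / params.heading_ref_tau_s)
    thr = math.radians(params.reversal_angle_deg)
    for i in range(len(xs) - 1):
        dx, dy = xs[i + 1] - xs[i], ys[i + 1] - ys[i]
        sp = math.hypot(dx, dy) / dt
        if sp < params.pause_speed_mm_s:
            labels.append("pause")
            continue
        h = math.atan2(dy, dx)
        if ref is None:
            ref = h
        else:
            d = (h - ref + math.pi) % (2 * math.pi) - math.pi
            if abs(d) > thr:
                mode = "reverse" if mode == "forward" else "forward"
                ref = h
            else:
                ref = ref + alpha * d
        labels.append(mode)
    return _merge_short_bouts(labels, dt, params.min_bout_s)


def mann_whitney_exact(a, b):
    """Two-sided exact Mann-Whitney p by full enumeration of rank splits."""
    pooled = np.concatenate([a, b])
    n1, n2 = len(a), len(b)
    ranks = sps.rankdata(pooled)
    u_obs = np.sum(ranks[:n1]) - n1 * (n1 + 1) / 2
    lo = min(u_obs, n1 * n2 - u_obs)
    hits = 0
    for idx in combinations(range(n1 + n2), n1):
        u = np.sum(ranks[list(idx)]) - n1 * (n1 + 1) / 2
        if u <= lo or u >= n1 * n2 - lo:
            hits += 1
    return min(1.0, hits / comb(n1 + n2, n1))


def fisher_exact_enum(table):
    """Two-sided Fisher p by hypergeometric enumeration (point-mass rule)."""
    (a, b), (c, d) = table
    row1, col1, n = a + b, a + c, a + b + c + d
    dist = sps.hypergeom(n, row1, col1)
    p_obs = dist.pmf(a)
    support = np.arange(max(0, col1 - (n - row1)), min(col1, row1) + 1)
    probs = dist.pmf(support)
    return float(np.sum(probs[probs <= p_obs * (1 + 1e-9)]))
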