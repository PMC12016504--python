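"""Independent brute-force oracles shared across test modules."""

import itertools
import math

import numpy as np

from goredox import welch_t_statistic


def enumerate_bootstrap_p(x, y, alternative="two-sided"):
    """Exhaustive enumeration oracle for the pooled-shift bootstrap.

    Walks every ordered resample pair (n^n × m^m) from the shifted arms,
    excluding pairs where both arms are constant, and returns the exact
    probability of a resample statistic at least as extreme as observed.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    zbar = np.concatenate([x, y]).mean()
    xs = x - x.mean() + zbar
    ys = y - y.mean() + zbar
    t_obs = welch_t_statistic(x, y)
    hits = valid = 0
    for bx in itertools.product(xs, repeat=x.size):
        for by in itertools.product(ys, repeat=y.size):
            vx, vy = np.var(bx, ddof=1), np.var(by, ddof=1)
            if vx == 0.0 and vy == 0.0:
                continue
            t = (np.mean(bx) - np.mean(by)) / math.sqrt(vx / x.size + vy / y.size)
            valid += 1
            if alternative == "two-sided":
                hits += abs(t) >= abs(t_obs)
            else:
                hits += t >= t_obs
    return hits / valid
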