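"""Compiled kernels for the circular-arc segmentation scan.

The circular statistic for an arc ``x[i:j]`` against its complement is the
pooled two-sample t statistic.  The scan is O(N^2) in the number of bins of
a chromosome; these kernels keep that affordable for permutation testing.
"""

import numpy as np
from numba import njit


@njit(cache=False, fastmath=True)
def max_arc_stat(x):
    """Best circular split of ``x``: returns (t_max, i, j).

    The arc is ``x[i:j]`` (half-open); ties broken toward the leftmost
    (smallest i, then smallest j) pair.  Constant input returns t = 0.
    """
    n = x.shape[0]
    c1 = np.empty(n + 1)
    c2 = np.empty(n + 1)
    c1[0] = 0.0
    c2[0] = 0.0
    for k in range(n):
        c1[k + 1] = c1[k] + x[k]
        c2[k + 1] = c2[k] + x[k] * x[k]
    tot = c1[n]
    tot2 = c2[n]
    # cumulative-sum roundoff floor: differences at this scale are zero
    eps_d = 1e-9 * (1e-300 + np.sqrt(tot2 / n))
    eps_ss = 1e-12 * (1e-300 + tot2)
    best = 0.0
    bi = 0
    bj = n
    for i in range(n):
        for j in range(i + 1, n + 1):
            k = j - i
            if k == n:
                continue
            r = n - k
            s = c1[j] - c1[i]
            q = c2[j] - c2[i]
            d = s / k - (tot - s) / r
            ss = (q - s * s / k) + (tot2 - q) - (tot - s) * (tot - s) / r
            if ss <= eps_ss:
                t2 = 0.0 if -eps_d < d < eps_d else 1.0e300
            else:
                t2 = d * d * (n - 2) / (ss * (1.0 / k + 1.0 / r))
            if t2 > best * (1.0 + 1e-12) and t2 > best + 1e-15:
                best = t2
                bi = i
                bj = j
    return np.sqrt(best), bi, bj


@njit(cache=False, fastmath=True)
def perm_max_stats(perms):
    """Max arc statistic for each row of a matrix of permuted profiles."""
    b = perms.shape[0]
    out = np.empty(b)
    for row in range(b):
        t, _, _ = max_arc_stat(perms[row])
        out[row] = t
    return out
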