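"""Independent brute-force oracle for the exact binomial interval.

Inverts the exact binomial test over a p-grid of step 1e-5: the lower
bound is the smallest grid p whose upper tail P(X >= s | p) exceeds
alpha/2, the upper bound the largest grid p whose lower tail
P(X <= s | p) exceeds alpha/2.  Both tails are monotone in p, so the
grid crossing is located by bisection over grid indices; the result is
identical to a full scan of the grid.
"""

import numpy as np
from scipy.stats import binom

GRID_STEP = 1e-5
_N_GRID = round(1.0 / GRID_STEP)  # grid points are k * GRID_STEP, k = 0.._N_GRID


def _first_true_index(predicate, lo, hi):
    """Smallest integer array index in [lo, hi] where the vectorized,
    monotone (false->true) predicate holds; hi+1 where it never does."""
    lo = np.asarray(lo).copy()
    hi = np.asarray(hi).copy()
    while np.any(lo < hi):
        mid = (lo + hi) // 2
        holds = predicate(mid)
        hi = np.where(holds, mid, hi)
        lo = np.where(holds, lo, mid + 1)
    return lo


def brute_force_binomial_ci(n: int, alpha: float = 0.05):
    """Grid-inversion intervals for every s = 0..n; returns (lower, upper)
    arrays of length n+1."""
    s = np.arange(n + 1)
    a2 = alpha / 2.0

    # lower: first grid p with P(X >= s | p) > alpha/2 (monotone increasing)
    lower_idx = _first_true_index(
        lambda k: binom.sf(s[1:] - 1, n, k * GRID_STEP) > a2,
        np.ones(n, dtype=np.int64),
        np.full(n, _N_GRID, dtype=np.int64),
    )
    lower = np.concatenate([[0.0], lower_idx * GRID_STEP])

    # upper: last grid p with P(X <= s | p) > alpha/2; the complement
    # predicate (tail <= alpha/2) is monotone false->true in p
    first_fail = _first_true_index(
        lambda k: binom.cdf(s[:-1], n, k * GRID_STEP) <= a2,
        np.zeros(n, dtype=np.int64),
        np.full(n, _N_GRID, dtype=np.int64),
    )
    upper = np.concatenate([(first_fail - 1) * GRID_STEP, [1.0]])
    return lower, upper
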