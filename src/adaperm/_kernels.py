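"""Numba permutation kernels.

The permutation engines spend essentially all their time drawing random
re-pairings of trait and genotype and re-scoring them, so that inner loop
is JIT-compiled.  Two tricks keep it cheap:

* Only group sums matter.  For a fixed genotype column, both supported F
  statistics are strictly increasing functions of a scalar score
  computable from the per-class trait sums (ANOVA: sum of S_g^2/n_g;
  regression: squared centred cross-product).  Comparing scores is
  therefore equivalent to comparing F values, including the
  zero-residual F = inf case, and needs no divisions per permutation.
* Only the smaller classes need shuffling.  The trait vector is stored
  grouped by class with the largest class last; a partial Fisher-Yates
  pass over the first k = n - n_largest slots yields a uniformly random
  assignment, and the largest class's sum falls out by subtraction.

Each permutation consumes exactly k calls to ``np.random.randint``, so
kernels seeded identically draw identical permutation streams, which the
test suite exploits to check standard/adaptive concordance.
"""

from __future__ import annotations

import numpy as np
from numba import njit

MODE_ANOVA = 0
MODE_REGRESSION = 1


@njit(cache=False)
def _score(yv, sizes, vals, mode, c0, total):
    K = sizes.shape[0]
    pos = 0
    rest = total
    if mode == MODE_ANOVA:
        sc = 0.0
        for g in range(K - 1):
            s = 0.0
            for t in range(pos, pos + sizes[g]):
                s += yv[t]
            pos += sizes[g]
            rest -= s
            sc += s * s / sizes[g]
        sc += rest * rest / sizes[K - 1]
        return sc
    else:
        sxy = 0.0
        for g in range(K - 1):
            s = 0.0
            for t in range(pos, pos + sizes[g]):
                s += yv[t]
            pos += sizes[g]
            rest -= s
            sxy += vals[g] * s
        sxy += vals[K - 1] * rest
        d = sxy - c0
        return d * d


@njit(cache=False)
def observed_score(y, sizes, vals, mode, c0):
    """Score of the unpermuted (class-grouped) arrangement."""
    total = 0.0
    for i in range(y.shape[0]):
        total += y[i]
    return _score(y, sizes, vals, mode, c0, total)


@njit(cache=False)
def run_permutations(y, sizes, vals, mode, c0, score_obs, r, b, seed, strict):
    """Sequential permutation loop with early stopping.

    Returns (R, B): successes seen and permutations performed.  Stops at
    the exact permutation index where the r-th success occurs; passing
    r > b yields the fixed-budget (standard) behaviour, always (R, b).
    """
    np.random.seed(seed)
    n = y.shape[0]
    K = sizes.shape[0]
    k = n - sizes[K - 1]
    total = 0.0
    for i in range(n):
        total += y[i]
    yv = y.copy()
    R = 0
    for j in range(1, b + 1):
        for t in range(k):
            u = np.random.randint(t, n)
            tmp = yv[t]
            yv[t] = yv[u]
            yv[u] = tmp
        sc = _score(yv, sizes, vals, mode, c0, total)
        if strict:
            success = sc > score_obs
        else:
            success = sc >= score_obs
        if success:
            R += 1
            if R == r:
                return R, j
    return R, b


@njit(cache=False)
def success_stream(y, sizes, vals, mode, c0, score_obs, b, seed, strict):
    """Per-permutation success indicators for the first b permutations.

    Draws the same stream as :func:`run_permutations` under the same
    seed; intended for diagnostics and concordance checks at small b.
    """
    np.random.seed(seed)
    n = y.shape[0]
    K = sizes.shape[0]
    k = n - sizes[K - 1]
    total = 0.0
    for i in range(n):
        total += y[i]
    yv = y.copy()
    out = np.empty(b, dtype=np.uint8)
    for j in range(b):
        for t in range(k):
            u = np.random.randint(t, n)
            tmp = yv[t]
            yv[t] = yv[u]
            yv[u] = tmp
        sc = _score(yv, sizes, vals, mode, c0, total)
        if strict:
            out[j] = 1 if sc > score_obs else 0
        else:
            out[j] = 1 if sc >= score_obs else 0
    return out
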