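"""Permutation-budget design: choose (b, r) for a target precision.

An adaptive permutation test for a single marker stops as soon as *r*
permuted statistics have matched or beaten the observed one, or after a
ceiling of *b* permutations.  The number of permutations ``B`` needed to
reach the r-th success is negative-binomially distributed, so both the
budget ``b`` and the success cutoff ``r`` can be chosen analytically from

* the point-wise significance level ``alpha_p`` at which p-values must be
  well estimated (after Bonferroni division of the experiment-wise level
  ``alpha_e`` by the number of independent tests ``m``), and
* a precision fraction ``c``: when the true p-value equals ``alpha_p`` the
  standard error of its estimate should be ``c * alpha_p``.

With those inputs, ``b = (1 - alpha_p) / (c^2 * alpha_p)`` matches the
binomial standard error of a fixed-budget permutation test, and ``r`` is
the smallest success cutoff for which the estimate ``r/B`` stays inside
``(1 - c) * alpha_p < r/B < (1 + c) * alpha_p`` with the coverage of a
one-standard-error normal interval (each tail at most ``1 - Phi(1)``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import nbinom, norm

__all__ = [
    "DEFAULT_TAIL",
    "PermutationPlan",
    "bonferroni_alpha",
    "max_permutations",
    "min_successes",
    "recommend_plan",
    "standard_se",
    "coverage_probability",
]

#: Maximal one-sided miss probability for the precision interval.  This is
#: the exact normal one-sigma tail 1 - Phi(1) ~ 0.158655, so that
#: P((1-c)*alpha < r/B < (1+c)*alpha) is at least the ~68% coverage of a
#: one-standard-error confidence interval.
DEFAULT_TAIL: float = float(norm.sf(1.0))

_R_SEARCH_CEILING = 10_000


@dataclass(frozen=True)
class PermutationPlan:
    """The design tuple governing an adaptive permutation run.

    Attributes
    ----------
    m : int
        Number of independent tests (or an effective number of tests).
    alpha_e : float
        Experiment-wise (family-wise) error rate to control.
    alpha_p : float
        Point-wise error rate, ``alpha_e / m`` under Bonferroni.
    c : float
        Precision fraction: target SE of the p-value estimate at
        ``p = alpha_p``, expressed as a fraction of ``alpha_p``.
    b : int
        Maximum permutations per marker (censoring point).
    r : int
        Success cutoff: stop once r permuted statistics reach the
        observed one.
    """

    m: int
    alpha_e: float
    alpha_p: float
    c: float
    b: int
    r: int

    def __post_init__(self) -> None:
        if not 0 < self.alpha_p < 1:
            raise ValueError(f"alpha_p must be in (0, 1), got {self.alpha_p}")
        if self.r > self.b:
            raise ValueError(f"success cutoff r={self.r} exceeds budget b={self.b}")
        if self.b < 1 or self.r < 1:
            raise ValueError("b and r must be positive integers")


def _check_alpha(alpha: float, name: str = "alpha") -> None:
    if not (isinstance(alpha, (int, float)) and 0 < alpha < 1):
        raise ValueError(f"{name} must lie strictly in (0, 1), got {alpha!r}")


def _check_c(c: float) -> None:
    if not (isinstance(c, (int, float)) and 0 < c <= 1):
        raise ValueError(f"precision c must lie in (0, 1], got {c!r}")


def bonferroni_alpha(alpha_e: float, m: int) -> float:
    """Point-wise level ``alpha_e / m`` for m independent tests.

    ``m`` may be an *effective* number of tests (e.g. after collapsing
    correlated markers); it only needs to be a positive integer.
    """
    _check_alpha(alpha_e, "alpha_e")
    if not (isinstance(m, (int,)) and m >= 1):
        raise ValueError(f"m must be a positive integer, got {m!r}")
    return alpha_e / m


def max_permutations(alpha_p: float, c: float) -> int:
    """Permutation budget ``b = (1 - alpha_p) / (c^2 * alpha_p)``.

    This is the fixed budget at which a standard permutation test
    estimates a p-value of ``alpha_p`` with standard error
    ``c * alpha_p``; the adaptive test reuses it as its censoring point.
    The value is rounded half-up to an integer (all the standard design
    grids are exactly integral, so rounding only matters for unusual
    user-supplied combinations).
    """
    _check_alpha(alpha_p, "alpha_p")
    _check_c(c)
    return int(math.floor((1.0 - alpha_p) / (c * c * alpha_p) + 0.5))


def min_successes(alpha_p: float, c: float, tail: float = DEFAULT_TAIL) -> int:
    """Smallest success cutoff r meeting the precision condition.

    Let ``B`` be the number of permutations needed for r successes, each
    with probability ``alpha_p`` (negative binomial).  The estimate
    ``r/B`` must escape the relative precision band on either side with
    probability at most ``tail``::

        P(r/B < (1 - c) * alpha_p) <= tail      (estimate too small)
        P(r/B > (1 + c) * alpha_p) <= tail      (estimate too large)

    Both probabilities are evaluated exactly via the negative binomial
    CDF, with outcomes landing exactly on a band edge counted as covered.
    ``tail`` defaults to the normal one-sigma tail :data:`DEFAULT_TAIL`,
    giving the band ~68% coverage.

    Raises
    ------
    RuntimeError
        If no r below the search ceiling (10,000) satisfies both bounds.
    """
    _check_alpha(alpha_p, "alpha_p")
    _check_c(c)
    if not 0 < tail < 0.5:
        raise ValueError(f"tail must lie in (0, 0.5), got {tail!r}")
    for r in range(1, _R_SEARCH_CEILING + 1):
        # p_hat = r/B < (1-c)*alpha  <=>  B > r / ((1-c)*alpha), strictly
        if c < 1.0:
            hi = r / ((1.0 - c) * alpha_p)
            p_under = nbinom.sf(math.floor(hi) - r, r, alpha_p)
        else:
            p_under = 0.0  # band floor is 0; p_hat = r/B is always positive
        # p_hat = r/B > (1+c)*alpha  <=>  B < r / ((1+c)*alpha), strictly
        lo = r / ((1.0 + c) * alpha_p)
        p_over = nbinom.cdf(math.ceil(lo) - 1 - r, r, alpha_p)
        if p_under <= tail and p_over <= tail:
            return r
    raise RuntimeError(
        f"no success cutoff r <= {_R_SEARCH_CEILING} achieves precision "
        f"c={c} at alpha_p={alpha_p}"
    )


def recommend_plan(
    m: int, alpha_e: float, c: float, tail: float = DEFAULT_TAIL
) -> PermutationPlan:
    """Compose a full :class:`PermutationPlan` from (m, alpha_e, c)."""
    alpha_p = bonferroni_alpha(alpha_e, m)
    b = max_permutations(alpha_p, c)
    r = min_successes(alpha_p, c, tail=tail)
    return PermutationPlan(m=m, alpha_e=alpha_e, alpha_p=alpha_p, c=c, b=b, r=r)


def _success_positions(rng: np.random.Generator, b: int, k: int) -> np.ndarray:
    """k distinct permutation indices in 1..b, sorted ascending."""
    if b <= 100_000:
        return np.sort(rng.permutation(b)[:k]) + 1
    pos = np.unique(rng.integers(1, b + 1, size=k))
    while pos.size < k:  # collisions are rare for k << b
        extra = rng.integers(1, b + 1, size=k - pos.size)
        pos = np.unique(np.concatenate([pos, extra]))
    return pos


def coverage_probability(
    alpha: float,
    c: float,
    n_sims: int = 100_000,
    seed: int = 0,
    tail: float = DEFAULT_TAIL,
) -> float:
    """Monte-Carlo check of the precision construction behind (b, r).

    Simulates the adaptive estimator at true p-value ``alpha`` under its
    exact stopping law — successes in ``b`` Bernoulli(alpha) permutations,
    stop at the r-th success (estimate r/B) or at the budget (estimate
    (R+1)/(b+1)) — and returns the empirical probability that the
    estimate lands inside ``((1-c)*alpha, (1+c)*alpha)``.  By design this
    should sit near the one-sigma normal coverage, ~0.68.
    """
    b = max_permutations(alpha, c)
    r = min_successes(alpha, c, tail=tail)
    rng = np.random.default_rng(seed)
    R = rng.binomial(b, alpha, size=n_sims)
    p_hat = np.empty(n_sims)
    censored = R < r
    p_hat[censored] = (R[censored] + 1) / (b + 1)
    for i in np.nonzero(~censored)[0]:
        # conditional on R >= r successes, their positions are a uniform
        # R-subset of 1..b; B is the position of the r-th success
        pos = _success_positions(rng, b, int(R[i]))
        p_hat[i] = r / pos[r - 1]
    lo, hi = (1.0 - c) * alpha, (1.0 + c) * alpha
    return float(np.mean((p_hat > lo) & (p_hat < hi)))


def standard_se(alpha: float, b: int) -> float:
    """Standard error ``sqrt(alpha * (1 - alpha) / b)`` of a fixed-budget
    permutation p-value estimate at true p = alpha."""
    _check_alpha(alpha)
    if not (isinstance(b, int) and b >= 1):
        raise ValueError(f"b must be a positive integer, got {b!r}")
    return math.sqrt(alpha * (1.0 - alpha) / b)
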