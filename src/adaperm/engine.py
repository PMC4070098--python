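"""Standard and adaptive permutation engines.

The *standard* engine performs a fixed number ``b`` of random trait
permutations per marker and estimates the p-value as ``R/b``, where R
counts permuted statistics at least as extreme as the observed one.

The *adaptive* engine samples permutations until either ``r`` successes
have accumulated (stop early, estimate ``r/B`` with B the permutation
index of the r-th success) or the budget ``b`` is exhausted (estimate
``(R+1)/(b+1)``).  Markers with no evidence of association stop after a
few hundred permutations; only strongly associated markers consume the
full budget, which is what makes permutation p-values tractable at
genome-wide thresholds.

Permutations shuffle the phenotype vector, each an independent uniform
draw.  A permuted statistic counts as a success when it is greater than
or equal to the observed one (``tie="geq"``, the conservative convention
for ties; ``tie="gt"`` gives the strict reading, immaterial for
continuous traits).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

from . import _kernels, stats
from .design import PermutationPlan

__all__ = [
    "AdaptiveResult",
    "StandardResult",
    "estimate_adaptive_p",
    "adaptive_permute",
    "standard_permute",
    "scan",
    "success_stream",
]

logger = logging.getLogger(__name__)

SeedLike = Union[int, np.integer, np.random.SeedSequence, np.random.Generator]


@dataclass
class AdaptiveResult:
    """Per-marker outcome of an adaptive permutation run."""

    snp_id: str
    observed_stat: float
    R: int
    B: int
    p_hat: float
    stopped_early: bool
    untestable: bool = False
    significant: Optional[bool] = None


@dataclass
class StandardResult:
    """Per-marker outcome of a fixed-budget permutation run."""

    snp_id: str
    observed_stat: float
    R: int
    b: int
    p_hat: float
    untestable: bool = False


def estimate_adaptive_p(R: int, B: int, r: int, b: int) -> float:
    """P-value estimate of the sequentially stopped test.

    ``r/B`` when the run stopped at the r-th success, ``(R+1)/(b+1)``
    when the budget was exhausted with R < r successes.
    """
    if R == r:
        if not r <= B <= b:
            raise ValueError(f"stopped run requires r <= B <= b, got R={R}, B={B}, b={b}")
        return r / B
    if R < r:
        if B != b:
            raise ValueError(f"censored run requires B == b, got B={B}, b={b}")
        return (R + 1) / (b + 1)
    raise ValueError(f"success count R={R} exceeds cutoff r={r}")


def _kernel_seed(rng: SeedLike) -> int:
    """Collapse any accepted seed form to a 32-bit kernel seed."""
    if isinstance(rng, np.random.Generator):
        return int(rng.integers(0, 2**32, dtype=np.uint64))
    if isinstance(rng, np.random.SeedSequence):
        return int(rng.generate_state(1, dtype=np.uint32)[0])
    return int(np.random.SeedSequence(int(rng)).generate_state(1, dtype=np.uint32)[0])


def _prepare(y, g, statistic: str):
    """Group the trait by genotype class (largest class last) and compute
    everything the kernels need.  Returns None for untestable markers."""
    yc, gc = stats._complete_pairs(y, g)
    n = yc.size
    classes, counts = np.unique(gc, return_counts=True)
    if classes.size < 2 or n - classes.size < 1:
        return None
    order = np.argsort(counts, kind="stable")
    sizes = counts[order].astype(np.int64)
    vals = classes[order].astype(np.float64)
    y_ord = np.concatenate([yc[gc == classes[i]] for i in order])
    sst = float(np.sum((yc - yc.mean()) ** 2))
    if sst <= 0:
        return None  # constant trait: nothing to permute
    if statistic == "oneway_anova":
        mode, c0 = _kernels.MODE_ANOVA, 0.0
        f_obs = stats.oneway_anova_f(yc, gc)
    elif statistic == "additive_regression":
        mode = _kernels.MODE_REGRESSION
        c0 = float(vals @ sizes) * float(yc.sum()) / n
        f_obs = stats.additive_regression_f(yc, gc)
        if np.isnan(f_obs):
            return None
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    score_obs = _kernels.observed_score(y_ord, sizes, vals, mode, c0)
    return y_ord, sizes, vals, mode, c0, score_obs, f_obs


def _tie_flag(tie: str) -> bool:
    if tie not in ("geq", "gt"):
        raise ValueError(f"tie rule must be 'geq' or 'gt', got {tie!r}")
    return tie == "gt"


def adaptive_permute(
    y,
    g,
    plan: PermutationPlan,
    statistic: str = "oneway_anova",
    rng: SeedLike = 0,
    tie: str = "geq",
    snp_id: str = "snp",
) -> AdaptiveResult:
    """Adaptive permutation test of one marker under ``plan``.

    Draws permutations of ``y`` until ``plan.r`` successes or ``plan.b``
    permutations, whichever comes first, and fills the estimate
    accordingly.  Untestable markers (monomorphic genotype, constant
    trait) are flagged rather than raised.
    """
    if plan.r > plan.b:
        raise ValueError("plan.r must not exceed plan.b")
    prep = _prepare(y, g, statistic)
    if prep is None:
        return AdaptiveResult(snp_id, float("nan"), 0, 0, float("nan"), False, True)
    y_ord, sizes, vals, mode, c0, score_obs, f_obs = prep
    R, B = _kernels.run_permutations(
        y_ord, sizes, vals, mode, c0, score_obs, plan.r, plan.b,
        _kernel_seed(rng), _tie_flag(tie),
    )
    stopped = R == plan.r
    p_hat = estimate_adaptive_p(int(R), int(B), plan.r, plan.b)
    return AdaptiveResult(snp_id, f_obs, int(R), int(B), p_hat, stopped)


def standard_permute(
    y,
    g,
    b: int,
    statistic: str = "oneway_anova",
    rng: SeedLike = 0,
    tie: str = "geq",
    add_one: bool = False,
    snp_id: str = "snp",
) -> StandardResult:
    """Fixed-budget permutation test: exactly ``b`` permutations, ``p = R/b``.

    With ``add_one=True`` the estimate becomes ``(R+1)/(b+1)``, which
    cannot be zero.  A zero ``R/b`` estimate only bounds the p-value by
    the resolution ``1/b`` and is logged as such.
    """
    if b < 1:
        raise ValueError(f"permutation count b must be >= 1, got {b}")
    prep = _prepare(y, g, statistic)
    if prep is None:
        return StandardResult(snp_id, float("nan"), 0, b, float("nan"), True)
    y_ord, sizes, vals, mode, c0, score_obs, f_obs = prep
    R, _ = _kernels.run_permutations(
        y_ord, sizes, vals, mode, c0, score_obs, b + 1, b,
        _kernel_seed(rng), _tie_flag(tie),
    )
    p_hat = (R + 1) / (b + 1) if add_one else R / b
    if R == 0 and not add_one:
        logger.warning(
            "%s: no permuted statistic reached the observed one in %d "
            "permutations; p=0 means p < 1/b = %.3g", snp_id, b, 1 / b,
        )
    return StandardResult(snp_id, f_obs, int(R), b, p_hat)


def success_stream(
    y, g, b: int, statistic: str = "oneway_anova", rng: SeedLike = 0, tie: str = "geq"
) -> np.ndarray:
    """Success indicators of the first ``b`` permutations (diagnostic).

    Seeded identically, this is the exact stream both engines consume,
    so ``stream[:B].sum() == R`` for either engine's outcome.
    """
    prep = _prepare(y, g, statistic)
    if prep is None:
        raise ValueError("marker is untestable; no permutation stream exists")
    y_ord, sizes, vals, mode, c0, score_obs, _ = prep
    return _kernels.success_stream(
        y_ord, sizes, vals, mode, c0, score_obs, b, _kernel_seed(rng), _tie_flag(tie)
    )


def scan(
    genotypes,
    y,
    plan: PermutationPlan,
    statistic: str = "oneway_anova",
    rng: SeedLike = 0,
    tie: str = "geq",
    snp_ids: Optional[Sequence[str]] = None,
) -> list[AdaptiveResult]:
    """Adaptive permutation scan over every column of a genotype matrix.

    Each marker gets an independent permutation stream derived from the
    master seed and its column index, so results are reproducible and
    independent of execution order.  A marker is called significant when
    ``p_hat < plan.alpha_p`` (rejecting at experiment-wise level
    ``plan.alpha_e``).
    """
    G = np.asarray(genotypes)
    if G.ndim != 2:
        raise ValueError("genotypes must be a 2-d (samples x SNPs) array")
    n, m = G.shape
    y = np.asarray(y, dtype=float)
    if y.shape != (n,):
        raise ValueError(f"phenotype length {y.shape} does not match {n} samples")
    if snp_ids is None:
        snp_ids = [f"snp{j + 1}" for j in range(m)]
    if len(snp_ids) != m:
        raise ValueError("snp_ids length does not match number of SNP columns")
    if m == 0:
        logger.warning("empty genotype matrix: nothing to scan")
        return []

    master = np.random.SeedSequence(
        int(rng) if isinstance(rng, (int, np.integer)) else _kernel_seed(rng)
    )
    results: list[AdaptiveResult] = []
    exhausted = 0
    total_perms = 0
    for j in range(m):
        child = np.random.SeedSequence(entropy=master.entropy, spawn_key=(j,))
        res = adaptive_permute(
            y, G[:, j], plan, statistic=statistic, rng=child, tie=tie, snp_id=snp_ids[j]
        )
        if not res.untestable:
            res.significant = bool(res.p_hat < plan.alpha_p)
            total_perms += res.B
            if not res.stopped_early:
                exhausted += 1
        results.append(res)
        if (j + 1) % 1000 == 0:
            logger.info("scanned %d/%d SNPs (%d permutations so far)", j + 1, m, total_perms)
    if all(r.untestable for r in results):
        logger.warning("all %d SNPs were untestable", m)
    logger.info(
        "scan complete: %d SNPs, %d hit the budget b=%d, %d total permutations",
        m, exhausted, plan.b, total_perms,
    )
    return results
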