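"""Synthetic genotype/phenotype generation.

Markers are simulated as independent biallelic SNPs in Hardy-Weinberg
equilibrium at a given minor allele frequency ``p_a``: each individual's
dosage S (minor-allele count) is drawn from {0, 1, 2} with probabilities
((1-p_a)^2, 2 p_a (1-p_a), p_a^2), independently across individuals and
markers (no linkage disequilibrium).  Quantitative traits follow the
additive model

    Y = beta * S + eps,

with i.i.d. errors that are either standard normal or Student t with 5
degrees of freedom.  The t(5) errors are deliberately *not* rescaled to
unit variance (their variance is 5/3); they model a heavy-tailed trait
for which parametric ANOVA p-values are anti-conservative, while leaving
null permutation behaviour untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SimulationConfig",
    "simulate_genotypes",
    "simulate_phenotype",
    "simulate_dataset",
    "draw_errors",
]

ERROR_DISTS = ("normal", "t5")


@dataclass
class SimulationConfig:
    """Generative parameters for one simulated dataset.

    ``n_causal`` leading SNPs receive the effect ``beta`` (additively,
    equal effect each); the rest are null.  ``beta = 0`` gives a fully
    null dataset regardless of ``n_causal``.
    """

    n: int = 200
    m: int = 1
    maf: float = 0.1
    beta: float = 0.0
    error_dist: str = "normal"
    n_causal: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError(f"sample size n must be >= 3, got {self.n}")
        if self.m < 0:
            raise ValueError(f"SNP count m must be >= 0, got {self.m}")
        if not 0 <= self.n_causal <= self.m:
            raise ValueError("n_causal must lie in [0, m]")
        if self.error_dist not in ERROR_DISTS:
            raise ValueError(f"error_dist must be one of {ERROR_DISTS}")
        _check_maf(self.maf)


def _check_maf(maf: float) -> None:
    if not 0 < maf <= 0.5:
        raise ValueError(f"minor allele frequency must lie in (0, 0.5], got {maf!r}")


def simulate_genotypes(n: int, m: int, maf: float, rng: np.random.Generator) -> np.ndarray:
    """(n, m) int8 dosage matrix of independent HWE markers."""
    _check_maf(maf)
    q = 1.0 - maf
    cum = np.array([q * q, q * q + 2 * q * maf])  # genotype CDF cutpoints
    u = rng.random((n, m))
    return (np.searchsorted(cum, u.ravel()).reshape(n, m)).astype(np.int8)


def draw_errors(shape, error_dist: str, rng: np.random.Generator) -> np.ndarray:
    """I.i.d. error draws of the given shape from the named distribution."""
    if error_dist == "normal":
        return rng.standard_normal(shape)
    if error_dist == "t5":
        return rng.standard_t(5, shape)
    raise ValueError(f"error_dist must be one of {ERROR_DISTS}")


def simulate_phenotype(
    S, beta: float, error_dist: str, rng: np.random.Generator
) -> np.ndarray:
    """Trait ``Y = beta * S + eps`` for one dosage vector, or the additive
    sum ``sum_j beta * S_j + eps`` when S has several causal columns."""
    S = np.asarray(S, dtype=float)
    eps = draw_errors(S.shape[0], error_dist, rng)
    if S.ndim == 1:
        return beta * S + eps
    if S.ndim == 2:
        return beta * S.sum(axis=1) + eps
    raise ValueError("S must be a vector or an (n, k) matrix of causal dosages")


def simulate_dataset(config: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    """Genotype matrix and phenotype vector for a full config.

    Returns ``(G, y)`` with G of shape (n, m).  Reusing the same config
    (including seed) reproduces the dataset bit for bit.
    """
    rng = np.random.default_rng(config.seed)
    G = simulate_genotypes(config.n, config.m, config.maf, rng)
    causal = G[:, : config.n_causal] if config.beta != 0 else np.zeros((config.n, 0))
    y = simulate_phenotype(causal, config.beta, config.error_dist, rng)
    return G, y
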