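"""Per-SNP association statistics for quantitative traits.

Two statistics are supported, both F-ratios that are monotone in the
evidence against the null of no genotype-phenotype association:

* ``oneway_anova`` — genotype (0/1/2 minor-allele count) treated as a
  categorical factor with the classes actually observed; the classic
  between/within mean-square ratio.  This is the default.
* ``additive_regression`` — the slope F (squared t) from simple linear
  regression of the trait on the dosage, matching the additive
  generative model ``Y = beta * S + eps``.

Missing entries (NaN in the phenotype, NaN or negative in the genotype)
are removed pairwise before computing either statistic.  Degenerate
markers (a single genotype class, or zero dosage variance) yield NaN,
which downstream code reports as *untestable* rather than raising.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import f as f_dist

__all__ = [
    "StatisticSpec",
    "oneway_anova_f",
    "additive_regression_f",
    "parametric_pvalue",
    "statistic_spec",
    "anova_pvalues",
]

_KINDS = ("oneway_anova", "additive_regression")


@dataclass(frozen=True)
class StatisticSpec:
    """Statistic family plus its F degrees of freedom.

    For ``oneway_anova``, ``df1`` is (observed genotype classes - 1) and
    ``df2`` is n - (observed classes); for ``additive_regression``,
    ``df1 = 1`` and ``df2 = n - 2``.
    """

    kind: str
    df1: int
    df2: int

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown statistic kind {self.kind!r}")
        if self.df1 < 1 or self.df2 < 1:
            raise ValueError(f"invalid degrees of freedom ({self.df1}, {self.df2})")


def _complete_pairs(y, g):
    y = np.asarray(y, dtype=float)
    g = np.asarray(g, dtype=float)
    if y.shape != g.shape or y.ndim != 1:
        raise ValueError("y and g must be 1-d arrays of equal length")
    keep = np.isfinite(y) & np.isfinite(g) & (g >= 0)
    return y[keep], g[keep]


def oneway_anova_f(y, g) -> float:
    """One-way ANOVA F ratio of trait ``y`` across genotype classes ``g``.

    Genotype classes with zero members are simply absent from the factor.
    Returns NaN for untestable input (fewer than 2 classes after pairwise
    deletion, or n too small for a positive error df); returns ``inf``
    when the residual variance is zero but group means differ.
    """
    y, g = _complete_pairs(y, g)
    n = y.size
    classes = np.unique(g)
    k = classes.size
    if k < 2 or n - k < 1:
        return float("nan")
    grand = y.sum()
    sst = np.sum((y - grand / n) ** 2)
    ssb = 0.0
    for cls in classes:
        sel = y[g == cls]
        ssb += sel.sum() ** 2 / sel.size
    ssb -= grand**2 / n
    ssw = sst - ssb
    df1, df2 = k - 1, n - k
    if ssw <= 0:
        if ssb <= 0:
            return float("nan")  # constant trait: no variance to partition
        return float("inf")
    return float((ssb / df1) / (ssw / df2))


def additive_regression_f(y, s) -> float:
    """Slope F statistic of the regression of ``y`` on dosage ``s``.

    Equals ``(n - 2) * R^2 / (1 - R^2)``; NaN when the dosage (or trait)
    has zero variance, ``inf`` for an exact fit.
    """
    y, s = _complete_pairs(y, s)
    n = y.size
    if n < 3:
        return float("nan")
    sxx = np.sum((s - s.mean()) ** 2)
    syy = np.sum((y - y.mean()) ** 2)
    if sxx <= 0 or syy <= 0:
        return float("nan")
    sxy = np.sum((s - s.mean()) * (y - y.mean()))
    ss_model = sxy**2 / sxx
    ss_resid = syy - ss_model
    if ss_resid <= 0:
        return float("inf")
    return float(ss_model / (ss_resid / (n - 2)))


def statistic_spec(kind: str, y, g) -> StatisticSpec:
    """Degrees-of-freedom bookkeeping for ``parametric_pvalue``."""
    y, g = _complete_pairs(y, g)
    n = y.size
    if kind == "oneway_anova":
        k = int(np.unique(g).size)
        return StatisticSpec(kind=kind, df1=k - 1, df2=n - k)
    if kind == "additive_regression":
        return StatisticSpec(kind=kind, df1=1, df2=n - 2)
    raise ValueError(f"unknown statistic kind {kind!r}")


def parametric_pvalue(f: float, spec: StatisticSpec) -> float:
    """Upper-tail probability of F(df1, df2) at the observed statistic."""
    if not isinstance(spec, StatisticSpec):
        raise TypeError("spec must be a StatisticSpec")
    if np.isnan(f):
        return float("nan")
    if f < 0:
        raise ValueError(f"F statistic must be non-negative, got {f}")
    return float(f_dist.sf(f, spec.df1, spec.df2))


def anova_pvalues(genotypes, y) -> np.ndarray:
    """Vectorised parametric one-way ANOVA p-values for every SNP column.

    ``genotypes`` is an (n, m) array of 0/1/2 dosages (negative = missing).
    ``y`` is either a length-n trait shared by all SNPs, or an (n, m)
    matrix giving each SNP its own trait (independent single-SNP
    replicates simulated side by side).  Intended for simulation studies
    where m is large and missingness is absent; columns with missing
    entries or degenerate classes fall back to the scalar routine.

    Returns a length-m array; untestable columns are NaN.
    """
    G = np.asarray(genotypes)
    y = np.asarray(y, dtype=float)
    n, m = G.shape
    if y.shape == (n,):
        Y = np.broadcast_to(y[:, None], (n, m))
        shared = True
    elif y.shape == (n, m):
        Y = y
        shared = False
    else:
        raise ValueError("phenotype shape matches neither (n,) nor (n, m)")
    if not np.all(np.isfinite(Y)):
        if not shared:
            raise ValueError("per-SNP phenotype matrix must be fully observed")
        # fall back column-wise when the trait itself has holes
        return np.array(
            [
                parametric_pvalue(
                    oneway_anova_f(y, G[:, j]), statistic_spec("oneway_anova", y, G[:, j])
                )
                if np.unique(G[np.isfinite(y) & (G[:, j] >= 0), j]).size >= 2
                else np.nan
                for j in range(m)
            ]
        )

    counts = np.stack([(G == v).sum(axis=0) for v in (0, 1, 2)])  # (3, m)
    sums = np.stack([np.where(G == v, Y, 0.0).sum(axis=0) for v in (0, 1, 2)])
    valid = counts.sum(axis=0) == n  # no missing entries in the column
    k = (counts > 0).sum(axis=0)

    grand = Y.sum(axis=0)
    sst = np.sum((Y - grand / n) ** 2, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ssb = np.where(counts > 0, sums**2 / np.maximum(counts, 1), 0.0).sum(axis=0)
        ssb -= grand**2 / n
        df1 = k - 1.0
        df2 = n - k.astype(float)
        ssw = sst - ssb
        fstat = (ssb / df1) / (ssw / df2)

    pvals = np.full(m, np.nan)
    ok = valid & (k >= 2) & (df2 >= 1) & (ssw > 0)
    pvals[ok] = f_dist.sf(fstat[ok], df1[ok], df2[ok])
    exact_fit = valid & (k >= 2) & (df2 >= 1) & (ssw <= 0) & (ssb > 0)
    pvals[exact_fit] = 0.0

    slow = valid & ~ok & ~exact_fit & (k >= 2)
    for j in np.nonzero(~valid | slow)[0]:
        gj = G[:, j]
        yj = Y[:, j]
        fj = oneway_anova_f(yj, gj)
        if np.isnan(fj):
            continue
        pvals[j] = parametric_pvalue(fj, statistic_spec("oneway_anova", yj, gj))
    return pvals
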