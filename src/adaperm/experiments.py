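"""Monte-Carlo evaluation of error rates and power.

These runners replicate the two simulation layouts used to validate the
adaptive test against parametric one-way ANOVA:

* **Null studies** (``run_type1`` / ``run_ewer``): many replicate
  datasets of independent null SNPs.  Per replicate, the fraction of
  p-values below a nominal level measures the point-wise type I error;
  the fraction of replicates containing at least one p-value below the
  Bonferroni threshold measures the experiment-wise error rate (EWER).
  With heavy-tailed (t with 5 df) trait errors, ANOVA's parametric
  p-values are anti-conservative — mildly at the 0.05 level, drastically
  in the far tail that EWER probes — while permutation p-values stay
  calibrated.

* **Power studies** (``run_power``): a single causal SNP with additive
  effect ``beta`` and normal errors; power is the fraction of replicates
  rejected at the point-wise level, with binomial standard error
  ``sqrt(p(1-p)/reps)``.

Every runner accepts a replicate count directly, so reduced-scale runs
(with proportionally wider Monte-Carlo tolerances) use the same code
path as full-scale ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import stats
from .design import PermutationPlan
from .engine import adaptive_permute, scan, standard_permute
from .synthdata import SimulationConfig, draw_errors, simulate_dataset

__all__ = [
    "ExperimentReport",
    "run_null_study",
    "run_type1",
    "run_ewer",
    "run_power",
    "qq_summary",
    "permutation_usage_summary",
]

_METHODS = ("anova", "adaptive", "standard")


@dataclass
class ExperimentReport:
    """Summary statistics of a simulation experiment.

    Only the fields relevant to the experiment type are populated:
    type-I studies fill ``type1_*`` and ``ewer``; power studies fill
    ``power`` and ``power_se``.  ``pvalues`` pools per-method p-values
    across replicates for QQ export.
    """

    design: str
    n_replicates: int
    nominal_level: Optional[float] = None
    threshold: Optional[float] = None
    type1_mean: dict = field(default_factory=dict)
    type1_sd: dict = field(default_factory=dict)
    type1_per_replicate: dict = field(default_factory=dict)
    ewer: dict = field(default_factory=dict)
    power: dict = field(default_factory=dict)
    power_se: dict = field(default_factory=dict)
    pvalues: dict = field(default_factory=dict)


def _check_methods(methods: Sequence[str]) -> list[str]:
    bad = [m for m in methods if m not in _METHODS]
    if bad:
        raise ValueError(f"unknown methods {bad}; choose from {_METHODS}")
    return list(methods)


def _rep_seed(base: int, rep: int, stream: int) -> int:
    ss = np.random.SeedSequence(entropy=int(base), spawn_key=(rep, stream))
    return int(ss.generate_state(1, dtype=np.uint32)[0])


def _snp_seed(base: int, rep: int, snp: int) -> int:
    ss = np.random.SeedSequence(entropy=int(base), spawn_key=(rep, 1, snp))
    return int(ss.generate_state(1, dtype=np.uint32)[0])


def run_null_study(
    config: SimulationConfig,
    plan: PermutationPlan,
    n_replicates: int,
    nominal_level: float = 0.05,
    threshold: Optional[float] = None,
    methods: Sequence[str] = ("anova", "adaptive"),
    statistic: str = "oneway_anova",
    standard_b: Optional[int] = None,
    store_pvalues: bool = True,
    shared_phenotype: bool = False,
) -> ExperimentReport:
    """Type I error and EWER in one pass over null replicates.

    By default every SNP within a replicate is an *independent*
    single-SNP dataset (its own genotype and trait draw), so the m
    p-values per replicate are independent and EWER behaves as
    ``1 - (1 - q)^m``; this is the layout the validation studies use.
    ``shared_phenotype=True`` instead draws one trait per replicate
    shared by all m SNPs — the structure of a real GWAS scan, where a
    single heavy-tailed trait realisation correlates the tests.

    ``threshold`` defaults to the plan's Bonferroni level ``alpha_p``.
    The ``standard`` method (fixed budget ``standard_b``, default
    ``plan.b``) is meant for modest budgets; at genome-wide budgets only
    the adaptive engine is tractable.
    """
    if config.beta != 0:
        raise ValueError("type I error studies require a null config (beta = 0)")
    methods = _check_methods(methods)
    if threshold is None:
        threshold = plan.alpha_p
    if standard_b is None:
        standard_b = plan.b

    fractions: dict[str, list[float]] = {m: [] for m in methods}
    any_hit: dict[str, list[bool]] = {m: [] for m in methods}
    pooled: dict[str, list[np.ndarray]] = {m: [] for m in methods}

    for rep in range(n_replicates):
        cfg = SimulationConfig(
            n=config.n, m=config.m, maf=config.maf, beta=0.0,
            error_dist=config.error_dist, n_causal=0,
            seed=_rep_seed(config.seed, rep, 0),
        )
        G, y = simulate_dataset(cfg)
        if shared_phenotype:
            Y = None
        else:
            rng = np.random.default_rng(_rep_seed(config.seed, rep, 3))
            Y = draw_errors((config.n, config.m), config.error_dist, rng)
        for method in methods:
            if method == "anova":
                p = stats.anova_pvalues(G, y if Y is None else Y)
            elif method == "adaptive":
                if Y is None:
                    res = scan(G, y, plan, statistic=statistic,
                               rng=_rep_seed(config.seed, rep, 1))
                else:
                    res = [
                        adaptive_permute(
                            Y[:, j], G[:, j], plan, statistic=statistic,
                            rng=_snp_seed(config.seed, rep, j),
                        )
                        for j in range(config.m)
                    ]
                p = np.array([r.p_hat for r in res])
            else:
                p = np.array([
                    standard_permute(
                        y if Y is None else Y[:, j], G[:, j], standard_b,
                        statistic=statistic,
                        rng=_rep_seed(config.seed, rep, 2 + j),
                    ).p_hat
                    for j in range(config.m)
                ])
            p = p[np.isfinite(p)]
            fractions[method].append(float(np.mean(p < nominal_level)))
            any_hit[method].append(bool(np.any(p < threshold)))
            if store_pvalues:
                pooled[method].append(p)

    report = ExperimentReport(
        design="null", n_replicates=n_replicates,
        nominal_level=nominal_level, threshold=threshold,
    )
    for method in methods:
        fr = np.array(fractions[method])
        report.type1_mean[method] = float(fr.mean())
        report.type1_sd[method] = float(fr.std(ddof=1)) if n_replicates > 1 else float("nan")
        report.type1_per_replicate[method] = fr
        report.ewer[method] = float(np.mean(any_hit[method]))
        if store_pvalues:
            report.pvalues[method] = np.concatenate(pooled[method])
    return report


def run_type1(
    config: SimulationConfig,
    plan: PermutationPlan,
    nominal_level: float = 0.05,
    methods: Sequence[str] = ("anova", "adaptive"),
    n_replicates: int = 100,
    **kwargs,
) -> ExperimentReport:
    """Mean and SD (across replicates) of the per-replicate fraction of
    p-values below ``nominal_level``, per method."""
    return run_null_study(
        config, plan, n_replicates, nominal_level=nominal_level,
        methods=methods, **kwargs,
    )


def run_ewer(
    config: SimulationConfig,
    plan: PermutationPlan,
    n_replicates: int = 100,
    methods: Sequence[str] = ("anova", "adaptive"),
    threshold: Optional[float] = None,
    **kwargs,
) -> ExperimentReport:
    """Fraction of replicates with at least one p-value below the
    Bonferroni threshold (default ``plan.alpha_p``), per method."""
    return run_null_study(
        config, plan, n_replicates, threshold=threshold, methods=methods, **kwargs,
    )


def run_power(
    config: SimulationConfig,
    plan: PermutationPlan,
    methods: Sequence[str] = ("anova", "adaptive"),
    n_replicates: int = 5000,
    statistic: str = "oneway_anova",
) -> ExperimentReport:
    """Rejection rate at ``plan.alpha_p`` for a single causal SNP.

    The config must specify ``beta > 0`` and normal errors are the
    intended setting (parametric power is only meaningful when its
    assumptions hold).  Returns power with binomial SE per method.
    """
    if config.beta <= 0:
        raise ValueError("power studies require beta > 0")
    methods = _check_methods(methods)
    rejected: dict[str, list[bool]] = {m: [] for m in methods}
    usage: list[int] = []

    for rep in range(n_replicates):
        cfg = SimulationConfig(
            n=config.n, m=1, maf=config.maf, beta=config.beta,
            error_dist=config.error_dist, n_causal=1,
            seed=_rep_seed(config.seed, rep, 0),
        )
        G, y = simulate_dataset(cfg)
        g = G[:, 0]
        for method in methods:
            if method == "anova":
                fobs = stats.oneway_anova_f(y, g)
                p = (
                    stats.parametric_pvalue(fobs, stats.statistic_spec("oneway_anova", y, g))
                    if np.isfinite(fobs) else (0.0 if fobs == np.inf else np.nan)
                )
            elif method == "adaptive":
                res = adaptive_permute(
                    y, g, plan, statistic=statistic,
                    rng=_rep_seed(config.seed, rep, 1),
                )
                p = res.p_hat
                if not res.untestable:
                    usage.append(res.B)
            else:
                p = standard_permute(
                    y, g, plan.b, statistic=statistic,
                    rng=_rep_seed(config.seed, rep, 2),
                ).p_hat
            rejected[method].append(bool(np.isfinite(p) and p < plan.alpha_p))

    report = ExperimentReport(design="power", n_replicates=n_replicates, threshold=plan.alpha_p)
    for method in methods:
        hits = np.array(rejected[method], dtype=float)
        p_hat = float(hits.mean())
        report.power[method] = p_hat
        report.power_se[method] = float(np.sqrt(p_hat * (1 - p_hat) / n_replicates))
    if usage:
        report.pvalues["adaptive_B"] = np.array(usage)
    return report


def qq_summary(pvalues) -> pd.DataFrame:
    """Sorted observed p-values paired with uniform order-statistic
    expectations i/(k+1), ready for a QQ plot (-log10 both axes)."""
    p = np.asarray(pvalues, dtype=float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        raise ValueError("no finite p-values to summarise")
    obs = np.sort(p)
    exp = np.arange(1, p.size + 1) / (p.size + 1)
    return pd.DataFrame({"expected": exp, "observed": obs})


def permutation_usage_summary(results_by_beta: dict) -> pd.DataFrame:
    """Distribution of permutations consumed (B) per effect size.

    ``results_by_beta`` maps an effect size to a list of
    :class:`~adaperm.engine.AdaptiveResult`.  Mean B grows with the
    effect size until it saturates at the budget b, which is the whole
    efficiency argument for adaptive stopping: computation concentrates
    on the (few) markers with real signal.
    """
    rows = []
    for beta in sorted(results_by_beta):
        B = np.array([r.B for r in results_by_beta[beta] if not r.untestable])
        if B.size == 0:
            continue
        rows.append({
            "beta": beta,
            "n_snps": B.size,
            "mean_B": B.mean(),
            "median_B": float(np.median(B)),
            "q90_B": float(np.quantile(B, 0.9)),
            "max_B": int(B.max()),
        })
    return pd.DataFrame(rows)
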