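"""Type I error and EWER under heavy-tailed trait errors (reduced scale).

With Student-t(5) errors, parametric ANOVA p-values are slightly
inflated at the 0.05 level and badly inflated in the far tail that the
Bonferroni threshold probes, while adaptive permutation p-values stay
calibrated.  Full-scale runs (100 replicates x 1,000 SNPs) reproduce
mean type I errors of ~0.055 (ANOVA) vs ~0.050 (adaptive) and ANOVA
EWER ~0.71; this example runs 10 replicates of 300 SNPs.
"""

from adaperm import SimulationConfig, qq_summary, recommend_plan, run_null_study

m = 300
plan = recommend_plan(m, 0.05, 0.1)
cfg = SimulationConfig(n=200, m=m, maf=0.1, beta=0.0, error_dist="t5", seed=8)
report = run_null_study(cfg, plan, n_replicates=10, nominal_level=0.05)

for method in ("anova", "adaptive"):
    print(
        f"{method:>9}: type I mean {report.type1_mean[method]:.4f} "
        f"(SD {report.type1_sd[method]:.4f}), "
        f"EWER at {plan.alpha_p:g}: {report.ewer[method]:.2f}"
    )

qq = qq_summary(report.pvalues["anova"])
tail = qq.head(3)
print("\nsmallest ANOVA p-values vs uniform expectation:")
print(tail.to_string(index=False))
print("Reading: observed << expected in the tail is exactly the parametric")
print("inflation that produces spurious genome-wide hits; the adaptive rows")
print("of the same summary sit on the diagonal.")
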