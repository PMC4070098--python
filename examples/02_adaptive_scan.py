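"""A small genome scan with adaptive permutation.

Simulates 50 independent SNPs (one causal with a strong additive
effect), designs a plan for m=50 tests, runs the adaptive scan and
prints the result table.  Null markers stop after a few hundred
permutations; the causal marker exhausts the budget and is called
significant at the experiment-wise 5% level.
"""

import numpy as np

from adaperm import SimulationConfig, recommend_plan, results_frame, scan, simulate_dataset

cfg = SimulationConfig(n=300, m=50, maf=0.2, beta=0.8, error_dist="normal",
                       n_causal=1, seed=11)
G, y = simulate_dataset(cfg)

plan = recommend_plan(m=50, alpha_e=0.05, c=0.1)
print(f"plan: alpha_p={plan.alpha_p:g}, b={plan.b:,}, r={plan.r}")

results = scan(G, y, plan, rng=2024)
df = results_frame(results)
print(df.head(8).to_string(index=False))

called = df[df["significant"].astype(bool)]
print(f"\nsignificant markers: {list(called['snp_id'])} (snp1 carries the effect)")
print(f"mean permutations per null marker: {df['B'][1:].mean():,.0f} of budget {plan.b:,}")
print("Reading: early stopping spends ~1% of the budget on null markers while")
print("the causal marker gets the full-resolution p-value it needs.")
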