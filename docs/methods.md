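# Methods

## Model and procedure

A marker's association with a quantitative trait is tested by a one-way
ANOVA F ratio, treating the genotype (minor-allele count 0/1/2) as a
categorical factor with the classes actually observed; an additive simple
regression F (the squared slope t) is available as an alternative. Under the
null hypothesis of no association the trait is exchangeable across
individuals, so uniformly random permutations of the trait vector generate
the exact null distribution of either statistic conditional on the genotype
column.

The sequential (adaptive) test draws permutations one at a time and counts
*successes* — permuted statistics at least as large as the observed one. It
stops at the r-th success after B permutations (estimate p̂ = r/B) or at the
budget b with R < r successes (estimate p̂ = (R+1)/(b+1)). B follows a
negative binomial law with success probability equal to the true permutation
p-value, censored at b; both branches of the estimator inherit their
precision from that law. A marker is called significant when p̂ < α_p, the
Bonferroni point-wise level α_e/m.

## Design parameters

| parameter | meaning | default |
|---|---|---|
| m | number of independent tests (may be an *effective* count) | — |
| α_e | experiment-wise (family-wise) error rate | 0.05 |
| c | precision: SE(p̂)/α_p at p = α_p | 0.1 |
| b | permutation ceiling, (1−α_p)/(c²α_p), rounded half-up | derived |
| r | success cutoff from the negative-binomial search | derived |
| tail | per-side miss probability in the r search | 1 − Φ(1) |

The r search scans upward from 1 (ceiling 10,000; r ≤ 121 for every
standard setting) and evaluates, exactly via the negative binomial CDF,
P(r/B < (1−c)α_p) and P(r/B > (1+c)α_p) with strict inequalities on B —
outcomes landing exactly on a band edge count as covered. The tail constant
is the exact normal one-sigma tail 1 − Φ(1) ≈ 0.158655 rather than a
rounded 0.16: the band is meant to be a one-standard-error (≈68%) interval,
and the exact constant reproduces the standard recommendation grid
(r = 115 at α_p = 0.05, stabilizing at 121 for α_p ≤ 10⁻³ at c = 0.1; 34
stabilizing at 36 for c = 0.2) cell for cell, which a 0.16 cutoff does not
(it yields r one smaller in most cells). `coverage_probability` verifies the
construction by simulating the full censored stopping law; note that for
small α_p the budget b sits below the mean of the uncensored law
(b/E[B] = (1−α_p)/(1+... ) ≈ 0.83 at c = 0.1), so most of the ~68% coverage
is actually delivered by the censored branch, whose binomial standard error
c·α_p is what the b formula fixes. The two branches are two halves of one
design.

## Engine

Permutations shuffle the phenotype; each is an independent uniform draw.
Success comparison uses ≥ by default (`tie="gt"` gives the strict variant;
the choice is immaterial for continuous traits and ≥ is conservative for
discrete ones). Exact F ties — permutations assigning the same value
multiset to every genotype class — are therefore successes by convention,
and the exhaustive-enumeration oracle in the test suite counts them the
same way.

The inner loop is JIT-compiled (numba) and sequential, so B is recorded at
the exact permutation index of the r-th success. Two implementation choices
make it fast without changing semantics:

- Both F statistics are strictly increasing functions of a scalar score
  computable from per-class trait sums (ANOVA: Σ S_g²/n_g, since the total
  sum of squares is permutation-invariant; regression: the squared centred
  cross-product). Comparing scores is equivalent to comparing F values —
  including the zero-residual F = ∞ case, which corresponds to the maximal
  score — and needs no divisions or tail evaluations per permutation.
- The trait vector is stored grouped by genotype class with the largest
  class last; a partial Fisher–Yates pass over the smaller classes' slots
  yields a uniformly random assignment and the largest class's sum falls
  out by subtraction. For n = 200 at MAF 0.1 this shuffles ~38 slots
  instead of 200.

Each marker's stream derives deterministically from (master seed, column
index), so scans are reproducible and order-independent; the
`success_stream` helper replays the identical stream, which the tests use
to check that standard and adaptive runs agree success-for-success.

Degenerate markers (monomorphic genotype after pairwise-complete deletion,
or a constant trait) are flagged untestable rather than given p = 1 or an
exception. The standard engine reports p̂ = R/b, which can be zero; a log
message notes the 1/b resolution floor and an add-one variant is available.

## Synthetic data

Genotypes are i.i.d. HWE draws at a given MAF — each entry 0/1/2 with
probabilities ((1−p)², 2p(1−p), p²) — with no linkage disequilibrium;
traits follow Y = βS + ε with ε i.i.d. standard normal or Student t(5).
The t(5) errors are deliberately not rescaled to unit variance (variance
5/3): they model a heavy-tailed trait, and scaling would only shift power,
not null behaviour. This generator omits LD structure, population
stratification, dominance/epistasis and genotyping error, so passing
simulations demonstrate calibration and power for independent markers under
an additive model — not robustness to confounding or correlated tests. An
effective (rather than actual) m can be supplied to the design module when
markers are correlated.

## Simulation studies

The null studies simulate every SNP as an *independent* single-SNP dataset
(its own genotype and trait draw). This matches the validation design the
error-rate figures come from: with 1,000 independent tests and a per-test
tail probability q, EWER = 1 − (1−q)^1000, which is what both the ANOVA
(~0.71 at q ≈ 1.2×10⁻³ under t(5)) and adaptive (~0.05 at q = 5×10⁻⁵)
rates reflect. A `shared_phenotype` option instead draws one trait per
replicate across all m SNPs — the structure of a real GWAS scan, where a
single heavy-tailed trait realisation correlates the tests and concentrates
false positives in fewer replicates (measurably lower EWER at identical
marginal rates).

Power simulations use a sample size of 200, MAF 0.1 and normal errors, with
effect sizes (β, α_p) paired as (0.21, 0.1), (0.27, 0.05), (0.37, 0.01),
(0.49, 0.001) to hold expected ANOVA power near 0.3; a noncentral-F check
(λ = nβ²·2p(1−p)) confirms ~0.28–0.30 at n = 200 for every pair, which is
the regime the matched-power comparison targets. Adaptive rejection uses
p̂ < α_p with the plan (b, r) for that α_p.

Default problem sizes are chosen to keep the full validation suite
desk-scale: the acceptance script runs 100 replicates × 1,000 SNPs for the
error-rate study and 5,000 replicates for power (a few minutes on one CPU);
the test suite runs a 25-replicate error-rate surrogate and 1,000-replicate
power with tolerances widened as 1/√reps. All tolerances on simulated
quantities are 2–4 Monte-Carlo standard errors of the quantity at the scale
run.

## Numerical choices and edge cases

- b is rounded half-up; every standard design cell is exactly integral.
- Score ties at the float level track genuine F ties up to 1-ulp summation
  noise; the enumeration oracle uses a 10⁻⁹ relative tie guard for the same
  convention. The residual effect on p̂ is orders of magnitude below the
  design precision c·p.
- Missing data: per-marker pairwise-complete deletion (NaN trait entries,
  negative or NaN genotype entries); degrees of freedom adjust to the
  classes observed after deletion. No minimum-class-size filter is applied:
  permutation p-values remain valid for markers with tiny genotype classes,
  which is precisely where the parametric test fails first.
- Genotype classes with zero members are dropped from the factor.
- Seeds: a single master seed; per-replicate and per-marker streams are
  spawned via `numpy.random.SeedSequence` keys, and the kernel consumes a
  32-bit derivation of each.

## Known limitations

- The engine permutes the trait only; stratified or covariate-adjusted
  permutation schemes (and multivariate responses) are out of scope.
- No LD-aware effective-test estimation is provided; the design module
  accepts an externally supplied effective m instead.
- p̂ from the censored branch is bounded below by 1/(b+1); associations
  stronger than the design resolution are reported at that floor.
- Parametric comparisons are limited to the one-way ANOVA and simple
  additive regression F tests.
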