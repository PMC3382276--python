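# Methods

## The liability-threshold model

All computations assume the classical liability-threshold model of complex
disease. Each individual has an unobserved liability ℓ = g + e with additive
genetic value g (variance h², the narrow-sense liability heritability) and
independent normal residual e (variance 1 − h²), so ℓ is standard normal in
the population. Disease occurs when ℓ > T = Φ⁻¹(1 − K), where K is the
population prevalence (lifetime, or age-group-specific: using the over-65
prevalence simply moves K and hence T). Conditioning on affection status
truncates the liability distribution: cases have mean liability i = z/K and
controls i₂ = −z/(1 − K), with z = φ(T); these moments drive everything in
`polyrisk.liability`.

Penetrance given genetic load is P(ℓ > T | g) = Φ((g − T)/√(1 − h²)),
degenerating to a step function at g = T as h² → 1 (value ½ at the
threshold by the symmetric limit). Its integral against the N(0, h²) density
of g recovers K for every (K, h²) — a property test.

## Maximum AUC of a genomic profile

A profile score capturing ρ² of liability variance is jointly normal with
liability (correlation ρ²/√ρ² = √ρ² on the standardized scale). Conditioning
on case/control status shifts the score means to iρ² and i₂ρ² and shrinks
the variances by the truncation factors 1 − ρ²i(i − T) and 1 − ρ²i₂(i₂ − T).
Treating the two conditional score distributions as normal gives

AUC(K, h², ρ²) = Φ( ρ²(i − i₂) / √(ρ²[1 − ρ²i(i − T)] + ρ²[1 − ρ²i₂(i₂ − T)]) ),

with the maximum attained at ρ² = h². This uses the truncation-reduced
variances for cases *and* controls, not an equal-variance shortcut; with the
cancer parameter sets (K = 0.007/h² = 0.42, 0.007/0.27, 0.004/0.35) it gives
0.925, 0.865, 0.913.

The conditional score distributions are not exactly normal, so the formula
is an approximation. Against an exact numerical integration of the
concordance probability (densities of the score in cases and controls
written in closed form, CDF and product integrated on a 4001-point grid) the
error is below 1e-3 for h² ≤ 0.42 and below 3e-3 for h² ≤ 0.6 at any
prevalence; it grows to ≈0.01 only for h² ≈ 0.8 combined with common
prevalence (K ≈ 0.2). The tests pin the formula to the integration oracle
and to a bivariate-normal simulation oracle on the disease-relevant grid.

`variance_from_auc` inverts the formula in ρ² by Brent root-finding
(xtol 1e-12; the function is strictly monotone in ρ²) and reports ρ²/h², the
share of *genetic* variance a profile must capture to reach a given AUC.
The same AUC of 0.75 can imply anything from ~10% to ~70%+ of genetic
variance depending on (K, h²), which is why an AUC quoted without its
parameters is ambiguous — a test sweeps the grid and checks the spread.

## Odds ratio → liability-scale variance

For a biallelic locus with risk-allele frequency p and per-allele odds ratio
OR, the default ("probit") conversion solves for the baseline odds x such
that the Hardy–Weinberg mixture of genotype risks k_g = x·ORᵍ/(1 + x·ORᵍ)
(g = 0, 1, 2 copies) averages to K; each genotype risk is mapped to a mean
liability shift μ_g = T − Φ⁻¹(1 − k_g) under unit residual variance; the
additive allele effect β is the regression of μ_g on allele count, and the
locus explains 2p(1 − p)β² of liability variance. A cruder "logit" scaling
β = ln(OR)·K(1 − K)/z is provided for comparison; both are exposed through
the `method` argument and the CLI.

On the rare-variant grid (p ∈ [0.01, 0.05], OR = 3.74, K ∈ [0.01, 0.20])
the probit conversion spans ≈0.006–0.06 of liability variance. The upper
end of the often-quoted 0.5–8% envelope is not reached by either conversion;
the envelope should be read as an order-of-magnitude statement and the tests
treat it that way.

## GWAS power and sample size

A 1-df association test for a variant explaining q² of trait variance has
non-centrality λ = n·q²; power at two-sided level α is
P(χ²₁(λ) > χ²₁;₁₋α). `required_n` solves the monotone power curve for λ*
(Brent, xtol 1e-9) and returns the smallest integer n with power ≥ target,
verified by stepping n by one in both directions. At α = 5×10⁻⁸ and 80%
power, λ* = 39.60: q² = 0.5% needs n = 7921 (≈7,900). The companion figure
of 460 samples sometimes quoted for q² = 8% is not reproduced by this
standard calculation, which gives 496; the discrepancy presumably reflects
rounding of the variance figure upstream, and the package reports the
calculation's own value.

## The synthetic-study generator

`polyrisk.simulate` emulates the simulation design, not any real cohort:

* **Allele frequencies** ~ Beta(a, b), default Beta(1, 1) (uniform — the
  shape is a free choice in the design, and the uniform is the neutral one),
  resampled into [maf_floor, 1 − maf_floor] with maf_floor = 0.01 so no
  locus is effectively monomorphic. Both knobs are in `ScenarioConfig`.
* **Effects**: raw βⱼ ~ N(0, 1), then one multiplicative rescaling so
  Σ 2pⱼ(1 − pⱼ)βⱼ² = h² exactly (to 1e-12, asserted). Effects keep their
  signs; the "risk allele" is simply the counted allele.
* **Genotypes**: xⱼ ~ Binomial(2, pⱼ) independently — Hardy–Weinberg and
  linkage equilibrium, no missingness. g = Σ xⱼβⱼ is centered by its
  analytic mean Σ 2pⱼβⱼ so liability has mean 0.
* **Ascertainment**: population chunks are simulated and individuals
  retained until the case and control quotas (default 10,000 + 10,000) are
  exactly filled — plain rejection sampling, which preserves the exact joint
  distribution of genotypes given status. Controls are unaffected
  individuals (ℓ ≤ T), not population controls. A cap (default 100/K times
  the total quota) turns an unreachable quota into an error.
* **Partition**: within each status group a random half goes to training,
  the rest to validation (±1 individual for odd counts).
* **Seeding**: one root seed per scenario; architecture, genotype stream,
  residual stream and partition each use an independent substream spawned
  from it (`numpy` `SeedSequence`), so (config, seed) regenerates any
  dataset bit-for-bit, including each pipeline replicate from the seed
  recorded in its result row.

What the generator does **not** emulate: linkage disequilibrium, genotyping
error or imputation uncertainty, population structure, non-additive
(dominance/epistatic) variance, gene–environment interaction, and
tag-SNP-versus-causal-variant attenuation. Passing tests therefore speak to
the behaviour of the method under the idealized additive architecture, not
to the accuracy of real-data risk profiles, which all of the above degrade.

### The genotype kernel

Rejection sampling at K = 0.004 means ~2.5 million simulated individuals
per 10,000-case replicate, so genotype generation dominates runtime. The
inner kernel (`polyrisk._genotypes`) draws one 32-bit uniform per genotype
from a counter-based splitmix64 stream — the counter is the (individual,
locus) index, so any row range can be regenerated independently and chunks
never overlap — thresholds it against the cumulative Hardy–Weinberg
probabilities scaled to uint32 (quantization 2⁻³², negligible beside the
0.01 frequency floor), and accumulates g in the same fused numba pass
(~8×10⁸ genotypes/s on one core). splitmix64 is the finalizer numpy itself
uses for seed hashing. A plain-numpy reference sampler is kept and the
kernel is checked against it distributionally (genotype frequencies, HWE
χ², seamless block continuation) in the tests. All other randomness uses
`numpy.random.Generator` (PCG64).

## Estimation and evaluation

Per-locus effects are estimated by linear regression of the 0/1 label on
genotype count (slope, Wald SE, 1-df χ² statistic, p-value), vectorized over
loci; this is the single-marker score test, and with ascertained 50/50
samples it ranks and weights loci essentially identically to logistic
regression, which is available as `method="logistic"` (statsmodels, looped,
slow — not used by the pipeline). Monomorphic loci get effect 0, p = 1 and
a flag. "Most significant" means smallest p-value; ties break by locus
index for determinism, and the top-15 selection keeps the estimated (not
re-fitted) effects. The test statistic is discrete, so under the null there
is an atom of exactly-zero slopes (mass ∝ 1/√n, ~0.7% at n = 10,000);
p-value uniformity holds to KS resolution at the study's training size.

Estimation sees only the training half; the validation half is used only
for scoring. AUC is the normalized Mann–Whitney U with half-credit ties,
computed from midranks in O(n log n); the O(n²) pair count is a test
oracle, and the trapezoidal area under the full ROC curve (all thresholds
retained) equals it to 1e-12 by construction. Expected validation AUC of
the true-effects predictor matches the closed-form maximum AUC — the
cross-module consistency test.

## Problem sizes and runtime

The pipeline's defaults follow the study design: 10,000 cases + 10,000
controls, 10 replicates per cell (replicate averaging stabilizes the cell
means; the SE of each mean is reported alongside). For the 10,000-locus
cells the pipeline offers a scaled mode (2,000 + 2,000 individuals,
`--scaled`) that keeps the full grid tractable on a desk machine; the
acceptance script uses it for the polygenicity grid. The scaled cohorts
have half the training data for locus selection, which measurably lowers
the top-15 AUC: at full size the six-cell range is ≈0.53–0.57 (spot-checked
at 0.553 for the prostate all-ages cell), while scaled cells run ≈0.50–0.53.
The scaled numbers are reported as what they are — the same method under a
smaller design — and the bound-style comparisons in the acceptance report
account for the shift in the conservative direction.

## Numerical and design choices

* Brent root-finding for all 1-d inversions (monotone functions, bracketed).
* χ² p-values for the Wald statistic (the t-vs-χ² difference is < 1e-3 in
  distribution at the sample sizes used).
* Genotypes stored as int8; scores and liabilities in float64.
* Ties in AUC: half credit, consistent with the Mann–Whitney equivalence.
* Config files are flat YAML mirroring `ScenarioConfig` exactly; unknown
  keys are rejected by name. Result CSVs round-trip losslessly.
* The genetic-load axis for penetrance is the standardized liability scale
  (g in standard deviations of total liability).
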