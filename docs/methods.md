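# Methods

`rarewin` implements a region-based association analysis for rare genomic
variants (alternate-allele frequency ≤ 1%) in two cohort designs: a
family-based discovery stage built on sibships, and an unrelated
case-control replication stage, joined by Fisher meta-analysis. This note
records the models, the choices made where the design was open, and what
the synthetic-data tests do and do not demonstrate.

## Testing unit: fixed-size variant windows

Post-QC variants are sorted by (chromosome, position) and partitioned into
non-overlapping consecutive sets of `k = 10` per chromosome. The terminal
window of each chromosome keeps its partial remainder and is tested like
any other, so the number of windows is Σ_c ⌈n_c / 10⌉. Windows are defined
on variant *order*; base-pair spans are reported metadata. Window size 10
balances signal aggregation against the combinatorial growth of the
family null; sparsely distributed signals wider than one window can be
missed.

## Family-based region tests

For siblings with affection y_i ∈ {0, 1}, the trait residual is
t_i = y_i − μ with offset μ = 0.15, the assumed population prevalence of
the disease. The offset makes unaffected siblings informative: they enter
with weight −0.15 against +0.85 for affected siblings. With per-variant
weights w_v (flat by default) and dosages g_iv:

- burden: B = Σ_f Σ_i t_i (Σ_v w_v g_iv)
- variance component (SKAT-style):
  Q = Σ_v w_v² (Σ_f Σ_i t_i (g_iv − ḡ_fv))², ḡ_fv the within-family mean.

The burden statistic aggregates signed dosage and is most powerful when
causal variants share an effect direction; Q aggregates squared
per-variant scores and wins under mixed directions or sparse signals.

**Conditional null.** Offspring multi-locus genotypes are i.i.d. draws
given the parental genotypes, hence *exchangeable* within a sibship. The
null distribution therefore permutes each family's sibling genotype
*rows* uniformly while phenotypes stay fixed, conditioning on the
observed multiset of genotype vectors per family. This preserves all
within-window LD exactly, requires no haplotype reconstruction or
between-variant correlation estimates, and is immune to population
stratification because between-family contrasts never enter the
reference distribution. Parental genotypes, when available, are used for
Mendel-error QC but ignored by the null — a conservative, valid choice.
Families with one sibling, constant residuals, or identical genotype rows
contribute constants to B and nothing to Q; they are excluded from the
permutation space.

When the number of permutation configurations (Π_f m_f!) is at most 10⁵
the null is enumerated exactly; otherwise Monte Carlo with
p̂ = (1 + #extreme)/(1 + N) (never zero, floor 1/(N+1)). Both tests
consume the same permutation stream; for a single-variant window the
SKAT and two-sided burden p-values then coincide exactly. The burden
p-value is two-sided around the exact permutation mean of B
(Pr(|B* − E B*| ≥ |B − E B*|)); SKAT is one-sided upper. The per-window
RNG is keyed by (seed, window id), making scans order-independent and
parallelisable.

The two-sided deviation p-value on a discrete, asymmetric permutation
distribution is conservative: under the null its distribution is
stochastically larger than uniform. The null suite therefore checks the
burden test through its empirical type-I error (within the exact binomial
confidence band at α = 0.05) and checks approximate uniformity on the
variance-component p-values, which are closer to continuous.

## Case-control replication

A logistic null model with covariates — sequencing center (dummy-coded),
age, sex, and the top rare-variant PCs (default 4) — is fitted once by
maximum likelihood (statsmodels GLM, tolerance 1e-8, ≤ 100 iterations).
With μ̂ the fitted means, V = diag(μ̂(1−μ̂)) and
P₀ = V − VX(X'VX)⁻¹X'V:

- burden: U = c'(y − μ̂) with c = Gw; U²/(c'P₀c) ~ χ²₁.
- SKAT: Q = Σ_v (w_v g_v'(y − μ̂))² ~ Σ_j λ_j χ²₁ with λ_j the
  eigenvalues of (GW)'P₀(GW).
- SKAT-O: Q_ρ = (1−ρ)Q_SKAT + ρQ_burden over
  ρ ∈ {0, 0.01, 0.04, 0.09, 0.16, 0.25, 0.5, 1}; the minimum per-ρ
  p-value is combined by conditioning on the shared burden-direction
  χ²₁ factor and integrating its density against the conditional
  survival of the remainder (relative tolerance 1e-6). The result is
  clamped into [min-p, grid × min-p]; if the integration fails the
  Bonferroni bound grid × min-p is reported with a flag.

Mixture-of-chi-square tails use the modified Liu moment-matching
approximation by default; a characteristic-function (Imhof) integration
is available via `tail_method="integration"`. The small-sample moment
adjustment some implementations apply for n < 2000 is **not**
implemented; a `SmallSampleWarning` is emitted so users know tails can be
slightly anti-conservative in small cohorts. Replication tests each
discovery window on the subset of its variants present post-QC in the
replication cohort; absent variants are dropped, not imputed.

## Rare-variant PCA (Jaccard index)

Carrier sets C_i = {v : g_iv ≥ 1} are compared with
J_ij = |C_i ∩ C_j| / |C_i ∪ C_j| (0 for an empty union). Because rare
alleles are young, carrier-set sharing is sensitive to recent, fine-scale
structure that common-variant PCA misses. Variants are first LD-pruned
(greedy windowed removal of the later variant of any pair with dosage
r² > 0.01; window 50, step 5) and randomly subsampled to a budget
(100,000 by default; all survivors when fewer). The similarity matrix is
double-centered (PCoA-style; a flag disables centering) and
eigendecomposed; coordinates are eigenvectors scaled by √max(λ, 0) with
the sign convention that each axis's largest-magnitude loading is
positive. r² is computed on dosages rather than carrier indicators,
matching conventional pruning practice.

## Meta-analysis and reporting

Discovery and replication p-values for a window combine as
X² = −2 Σ ln p_i ~ χ²_{2k}. Discovery burden pairs with replication
burden; discovery SKAT pairs with replication SKAT-O (the replication
stage's omnibus test). Only cohorts configured as ethnically comparable
enter the combination. The report lists windows with discovery
p ≤ 5×10⁻⁶ (the suggestive screening threshold) under either test, with
per-cohort p-values and SNV counts, the Fisher statistic, the combined
p, and a flag against the Bonferroni genome-wide threshold α/n_windows.

## Quality control

Variant filters run in a fixed order, each reported with its attrition:
multiallelic; monomorphic; indel; singleton (a single ALT allele overall
*or* all ALT alleles within one family); any half call (exactly one
missing allele in a diploid GT); Mendel errors (threshold 0 — any error
removes the variant); call rate < 95%; HWE exact p < 1e-8; external AF
reference (kept if ≤ 1% in *either* AF column — the disjunctive reading;
a flag switches to conjunctive); optional allow-list. Variants absent
from the AF reference are removed (conservative). The HWE exact test is
the conditional test given allele counts, summing the probabilities of
heterozygote configurations no more likely than the observed one; it is
computed on founders plus one sibling per parentless sibship, since
sibships violate the HWE sampling model.

Sample QC flags call rate < 95%, inbreeding coefficient
F = 1 − observed/expected heterozygosity outside ±0.15, and pedigree/IBD
mismatches from a method-of-moments estimator of IBD sharing
(PI_HAT = P(IBD=1)/2 + P(IBD=2) from identity-by-state counts and sample
allele frequencies, without finite-sample bias corrections): declared
siblings with PI_HAT < 0.2, and nominally unrelated pairs with
PI_HAT ≥ 0.9. These thresholds are package defaults, not estimates.

## Synthetic cohorts

The generator emulates the statistical structure the tests assume, not
genome realism. Per-variant allele frequencies are uniform on
[1/20000, 0.01]; founder haplotypes are independent Bernoulli(AF) per
site within a subpopulation pool (default 4000 haplotypes). Families
draw two parents from the pool; each sibling inherits one haplotype per
parent per chromosome with no recombination inside a chromosome's
simulated span — windows are kilobase-scale, so transmitted haplotypes
carry the within-window LD the family null must respect. Affection is
Bernoulli(expit(β₀ + Σ signed effects)); β₀ is solved by 1-D root
finding so the unascertained prevalence equals 0.15 (tolerance 1e-3).
Families are rejection-sampled until ≥ 2 siblings are affected (cap 10⁵
attempts per family); parents are masked by default, matching a
sibling-based discovery design, with a flag to retain them for
Mendel-error tests. The case-control generator draws unrelated
individuals from the same panel until the case and control quotas fill,
with center/sex covariates (optional log-odds effects) and ages ≥ 60 for
controls. With `n_subpops > 1`, a configurable fraction of variants is
private per subpopulation — an idealised stand-in for divergence that
produces carrier-set structure without modelling drift. Causal windows
plant per-allele log-odds effects (all positive, or alternating signs
for the mixed configuration) on the simulated variant grid, recorded in
a truth file together with true AFs and subpopulation labels.

Not emulated: recombination and realistic LD maps, genotyping error,
sequencing depth, age-dependent penetrance, admixture gradients. Passing
tests therefore demonstrate correctness of the statistics under the
stated model — exchangeable sibling genotypes, logistic risk, rare
independent variants — not robustness to artefacts of real sequencing
data.

## Problem sizes in the test and acceptance suites

Simulation-based checks use deliberately scaled-down conditions chosen
once, before measurement, with the logic stated here:

- *Family null calibration*: 100 families, 500 windows (2 × 2500
  variants), 1999 permutations per window. 1999 makes
  (N+1)·α integral at α = 0.05, so the discrete Monte-Carlo p̂ attains
  the nominal level exactly under the null.
- *Power ordering* (burden vs SKAT under unidirectional vs mixed
  effects): 100 families, one 10-variant window with per-allele log-OR
  2.0 and AF ∈ [0.005, 0.01], 200 seeds per direction. The ordering
  property concerns the powered regime, so the window must carry enough
  carriers (~2 per variant per cohort) for either test to see signal.
- *Jaccard PCA structure recovery*: 600 samples, 10,000 variants with
  AF ∈ [0.009, 0.01], 50% private variants, 100 seeds. The between-group
  contrast of mean Jaccard similarity is invariant to the variant count,
  while pair-level noise shrinks like 1/√V and the signal eigenvalue
  grows linearly in n — recovery at small scale therefore needs the top
  of the rare band and a few hundred samples (the full-scale analysis
  uses 100,000 variants and thousands of samples).
- *End-to-end recovery*: 400 ascertained families plus 1000/1000
  cases/controls, a 60-variant genome, one planted unidirectional window
  (log-OR 1.2), 1999 permutations, and a report threshold of 1e-3
  matched a priori to the Monte-Carlo resolution 1/(N+1) = 5×10⁻⁴ (the
  production threshold 5×10⁻⁶ is unreachable at this permutation count).

## Numerical choices

- Extremity comparisons in permutation tests use a relative tolerance
  (1e-9) so ties are never lost to floating-point noise; ties count as
  extreme (conservative).
- Exact enumeration deduplicates per-family permutation outcomes before
  convolving families, keeping the joint support ≤ the configuration cap.
- Missing dosages are imputed to the within-family mean in the family
  tests and to the variant mean in the case-control tests (QC removes
  most missingness first).
- Monomorphic windows, all-zero genotype matrices, and windows with no
  informative family return p = 1 with a degenerate flag rather than
  failing.
- Eigenvalues below 1e-10 of the largest are treated as zero in mixture
  tails; a single surviving eigenvalue falls back to the exact χ²₁.
- The Liu approximation with one eigenvalue reduces to the exact χ²₁
  tail, which guarantees the SKAT/burden identity on rank-1 windows.

## Known limitations

- The family null conditions on sibship exchangeability only; it does
  not implement the general sufficient-statistic machinery for arbitrary
  pedigrees (parent-offspring pairs contribute nothing beyond QC).
- Burden p-values are conservative at small permutation counts
  (discreteness), which costs a little power but never validity.
- X/Y chromosomes and non-diploid genotypes are out of scope; non-diploid
  GT entries are a parse error.
- SKAT-O's combined p relies on moment-matched per-ρ quantiles; in the
  far tail (p ≪ 1e-8) the Bonferroni clamp dominates.
- The AF reference emitted by the generator reuses the true simulation
  frequencies; testing the external-AF filter against discordant
  references is done with hand-built fixtures instead.
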