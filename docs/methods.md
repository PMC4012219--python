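# Methods

## Model

`ibshe` estimates the additive genetic variance of a complex trait from
population (GWAS-style) genotype data with a Haseman–Elston (HE) regression
in which identity-by-state (IBS) relatedness replaces the identity-by-descent
score of the classical sib-pair method.  For every pair of individuals
*(i, j)* a phenotype similarity score

* squared difference: Y_ij = (y_i − y_j)², or
* cross-product: Y_ij = y_i · y_j

is regressed by ordinary least squares on the genomic relatedness

    Ω_ij = s_i · s_j / M,     s_ik = (x_ik − 2p_k) / √(2 p_k q_k),

where x_ik counts reference alleles, p_k is the reference-allele frequency
and M the number of markers.  Across unrelated pairs E(Ω) = 0, and the
regression coefficient of the squared-difference form has expectation

    E(b) = −2 σ²_A Λ + Δ,

with σ²_A the additive variance, Λ = ρ̄²_Q / ρ̄²_M the ratio of the mean
squared marker–QTL correlation to the mean squared marker–marker correlation
(how well markers tag causal loci; Λ = 1 for perfect random tagging), and Δ
a remainder collecting between-locus covariance terms.  With a z-scored
phenotype, −b/2 estimates h²Λ; the unstandardized path uses −b/μ, since the
intercept estimates twice the phenotypic variance.  The cross-product
coefficient has half the magnitude of the squared-difference coefficient
and estimates h²Λ directly.

Assumptions: random mating, biallelic loci, strictly additive effects (no
dominance or epistasis), unrelated individuals (no shared environment), and
Hardy–Weinberg marginals.  Cryptic relatedness violates the E(Ω) = 0
premise; `filter_relatedness` greedily drops the individual involved in the
most pairs above a cutoff (0.05 is a reasonable default) until none remain.

### Exact two-locus algebra

All closed forms flow through the haplotype parameterization (p_k, p_l, D):
r = p(a_l|a_k) = q_l + D/q_k, R = p(A_l|A_k) = p_l + D/p_k,
ρ = D/√(p_k q_k p_l q_l), τ = 1 − r − R = −D/(p_k q_k).  The single-marker
coefficient expectation is E(b) = −4τ² p_k q_k β² = −2ρ²σ²_l with
σ²_l = 2 p_l q_l β²; with L QTLs on one marker the τβ contributions add
before squaring, and the multi-marker expectation is the exact ratio

    E(b) = [Σ_k −4 p_k q_k (Σ_l τ_kl β_l)² / M] / [Σ_{k,k'} ρ²_{kk'} / M²].

Δ is **defined operationally** as the exact remainder
E(b) + 2 σ²_A(within) Λ.  Alternative closed forms for Δ that
differ by a factor of two in the cross terms; the remainder definition is
the only one guaranteed consistent with the ratio expectation, and the
Monte-Carlo regression oracle in the test suite confirms it.  Note that with
positively correlated (e.g. sorted) effects under positive LD the cross
terms make E(b) *more negative*, i.e. Δ < 0 and the −b/2 estimate inflates.

### Effective number of markers

var(Ω) = 1/M + (1/M²) Σ_{k≠l} ρ²_kl, so M_e = 1/var(Ω) counts "independent"
markers.  `effective_marker_count` uses the centered sample variance of the
off-diagonal entries: with sample-estimated frequencies the off-diagonal
mean is ≈ −1/(N−1) rather than 0, and centering removes that finite-sample
offset.  Diagonal entries are computed by the same formula but excluded from
both the HE fit and M_e.  For 100 equifrequent loci on a chain with adjacent
correlation 0 / 0.25 / 0.5 / 0.75 the analytic M_e is 100 / 88.3 / 60.3 /
28.5.

### Standard errors

The analytic coefficient SE treats pair responses as exchangeable:
SSE = var(Y) − b²var(Ω) = 8σ⁴_y − 4σ⁴_A, giving
se(b)² = SSE/(n_pairs − d) · M_e with d = 1 regression parameter, and the
large-sample simplification se(b) = √(16 M_e / (N(N−1))), se(h²) = se(b)/2.
Both are reported (`se_b_analytic` uses the simplified form, the full form
is kept alongside), together with the naive OLS SE.  None of these accounts
for the dependence among pairs sharing an individual — the realized sampling
spread of b̂ across replicates is several-fold larger than the analytic SE
(visible in the simulation studies), so analytic SEs should be read as
description of the fit, not honest frequentist uncertainty; the replicate
SEM is the right yardstick in simulation comparisons.

### Case-control traits and the liability scale

Disease status is modeled as a thresholded latent Gaussian liability: cases
exceed the upper-K quantile t, K the population prevalence.  Fitting the HE
regression to 0/1 status through the standardized path yields an
observed-scale h²_o (legitimately > 1 under strong ascertainment), which
converts to the liability scale by the linear map
h²_l = h²_o · K²(1−K)² / (z² P(1−P)), z = φ(t), P the sample case
proportion.  SEs transform by the same constant (delta method).

### GREML comparator

The single-component mixed model y = Xb + g + e, cov(g) = σ²_g Ω,
cov(e) = σ²_e I, is fitted by restricted maximum likelihood on the GRM
eigenbasis: one eigendecomposition, then the restricted likelihood —
with the total variance profiled out analytically — is maximized over
h² = σ²_g/(σ²_g + σ²_e) by a coarse grid plus bounded Brent refinement
(tolerance 1e-8).  The constrained fit searches [0, 1]; the non-constrained
fit searches the largest interval on which h²Ω + (1−h²)I stays positive
definite, clipped to (−5, 5).  Negative GRM eigenvalues above −1e-8 are
clipped to zero.  The SE comes from a central second difference of the
profile likelihood.  For one variance ratio this profiling is exact, so no
iterative REML scheme is needed.

## Synthetic-data generators

The generators emulate the idealized populations under which the closed
forms are derived, not real genomes:

* **AR(1) haplotype chain** — two independent haplotypes per individual;
  first allele Bernoulli(p), subsequent alleles drawn conditional on the
  left neighbor to give adjacent-locus correlation ρ, hence ρ^d at distance
  d.  Equifrequent loci (p = 0.5) are the default.  Under random mating the
  genotypic correlation equals the haplotypic one, so the analytic var(Ω)
  applies directly.
* **Polygenic trait** — markers coincide with the L = M QTLs; effects iid
  N(0, 1) (optionally sorted ascending along the segment to create the
  correlated-effect architecture); residual variance set from the analytic
  covariance-inclusive additive variance 2pq β'Rβ so the population h² hits
  its target (default 0.5 with N = 1000, M = 100 — the standard
  quantitative design of the studies this package replicates).
* **Case-control** — L loci in linkage equilibrium, effects
  N(0, h²_l/(2pqL)); liability standardized to unit variance with genetic
  share h²_l; rejection sampling in memory-bounded batches until the case
  and control quotas are met, with an effort cap that rejects infeasibly
  low prevalence/quota combinations.

Not emulated: realistic LD block structure, allele-frequency spectra,
frequency–effect coupling, dominance/epistasis, population stratification,
genotyping error and missingness patterns.  Passing tests therefore
demonstrate correctness of the estimators under their own assumptions, not
robustness on real cohort data.

All generators take explicit seeds; replicate streams are spawned
deterministically from one root seed (`numpy.random.SeedSequence`), so every
study is bit-reproducible from (seed, config).

## Numerical and design choices

* Allele orientation: PLINK .bim allele-1 is the counted allele by default;
  Ω and ĥ² are invariant to orientation, so the choice only affects reported
  frequencies.  A flag flips it.
* Missing genotypes: mean-imputed to 0 on the standardized scale (keeps
  E(Ω) unbiased); a per-pair complete-marker denominator mode is available.
  Monomorphic and rare loci are excluded by a MAF floor (default 0.01)
  because √(2pq) → 0 explodes standardized scores.
* HE sufficient statistics (ΣΩ, ΣΩ², ΣY, ΣYΩ, ΣY²) are accumulated by
  matrix identities; the pair-level design matrix is never materialized
  (O(N²) time, O(1) extra memory beyond the GRM).
* Heritability estimates outside [0, 1] are flagged with a warning, never
  clipped — constrained estimates would bias the case-control comparison.
* The breakeven sample size uses N = ⌈4/(h²ρ²)⌉; at exactly integral
  thresholds the tabulated convention keeps N = 4/(h²ρ²) itself.
* The generic power solver uses the non-central χ²₁ with NCP
  (N h²ρ²/2)² for the HE test and N h²ρ²/(1−h²ρ²) for single-marker linear
  regression; their ratio N h²ρ²/4 defines the breakeven.
* Degenerate inputs raise early: all-missing loci, monomorphic loci in
  standardization, zero relatedness variance, constant phenotypes,
  rank-deficient covariates, collinear relatedness components (|corr| >
  0.999), GRMs numerically proportional to the identity (REML
  unidentifiable).

## Study scales used in tests

The bundled replications run at the design scale of the original studies
where that is desk-sized — N = 1000, M = L = 100, 100 replicates for the
quantitative designs — and at 500 cases/500 controls, 30 replicates,
K ∈ {0.1, 0.01} for the case-control comparison; the generators accept the
larger grids (K down to 0.001, L up to 10⁴) for standalone use.

## Known limitations

* Analytic SEs ignore pair dependence (see above).
* The cross-product fit asserts only the coefficient-magnitude relation
  |b_CP| = |b_SD|/2; its sign follows the similarity-regression convention
  (positive coefficient on relatedness).
* Only a single ancestry stratum is modeled; stratification control is
  limited to covariate residualization of the phenotype.
* Multi-allelic sites and VCF input are out of scope; genotypes enter as
  PLINK binary filesets or 0/1/2 text matrices.
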