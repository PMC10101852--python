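# Methods

This note documents the models implemented in `matfet`, the choices made
where the methodology was genuinely open, and what the synthetic-data tests
do and do not establish.

## 1. The trio decomposition

For a phased mother–father–child trio, each bi-allelic autosomal SNP
contributes three resolvable allele dosages: maternal nontransmitted (MnT),
maternal transmitted (MT) and paternal transmitted (PT). By construction
MnT+MT equals the maternal genotype and MT+PT the child's; `trio_alleles`
enforces these identities exactly and flags Mendelian-inconsistent sites
(child haplotype matching neither parental haplotype) as missing, with
complete-case regression downstream. Mother–child duos are handled
identically once upstream phasing annotates the child's maternal-origin
haplotype; no statistical re-inference of origin is attempted.

The per-SNP model is ordinary least squares:

    GD_i = β_MnT·MnT_i + β_MT·MT_i + β_PT·PT_i + γ'C_i + ε_i

β_MnT estimates a pure maternal effect, β_PT a pure fetal effect, and β_MT
their sum (the MT allele sits in both genomes). Per-cohort estimates are
pooled component-wise by fixed-effect inverse-variance weighting.

## 2. Effect-origin clustering

SNPs are classified into five clusters by a Gaussian mixture whose
component means are constrained to the patterns the decomposition implies
for (β_MnT, β_MT, β_PT):

| cluster | mean pattern | constraint |
|---|---|---|
| maternal_only | (m, m, 0) | — |
| fetal_only | (0, f, f) | — |
| fetal_poe_mt | (0, f, 0) | effect only on the maternally transmitted allele |
| both_same | (m, m+f, f) | sign(m) = sign(f) |
| both_opposite | (m, m+f, f) | sign(m) = −sign(f) |

Latent magnitudes carry zero-mean Gaussian priors with cluster-level
variances τ²; the per-SNP observation noise is the diagonal matrix of
squared standard errors (coefficient sampling covariances are not retained
across meta-analysis — an approximation, since the three design columns are
nearly orthogonal). Marginal likelihoods are available in closed form via
Woodbury identities; the sign constraints are imposed by truncating the
(m, f) prior to the matching quadrants, with the truncated marginal computed
exactly from the bivariate-normal orthant probability (Owen's T function,
vectorized). Posterior cluster probabilities, mixture weights and the τ²
are estimated by EM with 50 deterministic random restarts.

Two regularizations, both standard remedies for EM degeneracies, matter:

- **Variance hyperprior.** Each τ² gets a weak inverse-gamma prior (one
  pseudo-observation at the data scale). Without it the two-effect clusters
  can drive their fetal variance to zero and become *exactly* equivalent to
  the maternal-only cluster — a likelihood ridge on which labels drift
  arbitrarily. The MAP update makes the collapsed solution pay its Occam
  factor.
- **Weight pseudo-count.** Mixture weights get a Dirichlet-MAP pseudo-count
  (default 1) so components cannot die of responsibility feedback.

Known limitation: with estimated mixture weights and coefficient SEs above
roughly 0.08 days (when effects are 0.3–0.6 days), weight feedback still
favors coarser solutions in which the flexible two-effect clusters absorb
single-origin SNPs; classification accuracy then degrades even though the
likelihood is genuinely higher. At the SE≈0.02–0.05 regime of a
136,000-sample analysis this does not occur. For balanced designs where the
class mix is known (as in the validation simulations) the documented
`fix_uniform_weights=True` option fixes the weights at the truth and is the
recommended setting. Sign alignment for reporting flips each SNP so β_MT ≥ 0
("maternal allele positive"); the choice of β_MT as the reference is
configurable since either maternal slot could anchor the orientation.

## 3. Association and meta-analysis

Quantitative GWAS uses Frisch–Waugh residualization (exact per-SNP OLS at
vectorized cost); binary traits use per-variant logistic MLE with
separation-flagging. Variant QC implements MAF < 1%, Hardy–Weinberg exact
test P < 1e-6 (enumeration-based, mid-p off), imputation INFO < 0.4 and
call rate < 98%. Meta-analysis is fixed-effect IVW with Cochran's Q,
I² = max(0, (Q−df)/Q)·100 and the half-max-N variant filter; allele
harmonization flips swapped alleles, resolves strand flips by complement,
aligns palindromic variants by allele frequency when |EAF−0.5| > 0.08 on
both sides and drops them otherwise. Binary cohorts pass an effective-
sample-size gate 4/(1/cases+1/controls) > 100. λ is the median association
χ² over 0.4549.

Loci are greedy ±250 kb windows around successive index SNPs with overlap
merging. Clumping follows plink semantics (defaults r²=0.001, 1000 kb,
p1=5e-8, p2=1e-5; ties on p broken by position). Conditional selection is
forward stepwise on the approximate joint model b_J = Σ⁻¹·c, where Σ is the
reference LD covariance (variants >10 Mb apart or on different chromosomes
treated as unlinked; ridge 1e-8; candidates with r² > 0.9 to the selected
set skipped) and c the marginal covariances; with the analysis sample as
reference the joint estimates reproduce full multiple regression to
numerical precision. The phenotypic variance needed for joint SEs is
estimated as the median of v_j(b_j² + n_j·se_j²).

## 4. Summary-statistic models

**LD-score regression.** χ² regressed on N·ℓ_j/M with free intercept,
weights 1/max(ℓ_j,1), and delete-one-block jackknife SEs (200 blocks by
default). The cross-trait version regresses z_a·z_b on √(N_aN_b)·ℓ_j/M;
r_g = gencov/√(h²_a·h²_b) is re-computed on every jackknife sample so its
SE propagates all three regressions. The MHC region
(chr6:28477797–33448354) is excluded. The slope is identified only if LD
scores vary; the simulator therefore supports per-block LD (rho drawn
uniformly per block), and a fixed-rho panel leaves the regression nearly
unidentified — a property of the method, not the implementation.

**Colocalization.** Wakefield approximate Bayes factors with prior effect
SD 0.15 on the standardized scale; hypothesis priors p1 = p2 = 1e-4,
p12 = 5e-6; PP4 > 0.9 flags strong colocalization. All sums are computed in
log space.

**Multitrait conditioning.** b_xy (covariate→target) is estimated from
clumped genome-wide-significant covariate instruments by IVW *after* an
outlier screen: a weighted-median preliminary slope anchors the majority of
instruments and instruments whose residual exceeds 3.29 outcome SEs are
dropped. The screen mirrors the HEIDI-style filtering of the published
multitrait-conditioning method and is essential when the reverse causal
path exists: instruments of the downstream trait that act through the
upstream trait otherwise corrupt b_xy (observed: 0.71 where ~0 is true).
Conditioned statistics are b_c = b_t − b_xy·b_cov with
se_c² = se_t² + b_xy²·se_cov²; the dropped sampling-covariance term of the
full method makes this valid for non-overlapping samples, the simulated
setting. Attenuation summaries report the median relative change in
|effect| over region-lead SNPs (fixed 1 Mb regions stand in for
LD-independent regions) with a Wilcoxon signed-rank test.

## 5. Mendelian randomization and the cross-genome analysis

IVW is the weighted through-origin regression of outcome on exposure betas
(weights 1/se_out²) with first-order fixed-effect SE; a multiplicative
random-effects variant scales the SE by √max(1, Q/(k−1)). MR-Egger frees
the intercept (directional-pleiotropy test); with the intercept forced to
zero it reproduces IVW exactly. The transmitted/nontransmitted score
regression builds three scores by summing external weights over the MnT,
MT and PT slots separately and fits them jointly with covariates.

The cross-genome analysis regresses fetal birth-weight effects on a
maternal-channel gestational-duration exposure across index SNPs. Because
exposure and outcome belong to two different genomes the slope is a
pleiotropy summary and the result is flagged non-causal. It defaults to the
random-effects SE: per-SNP pleiotropy spread is the expected regime, and
the fixed-effect test is anti-conservative there. Validation simulations
estimate exposure and outcome on disjoint trio cohorts; sharing one cohort
couples the estimation errors through the phenotypic GD–BW correlation and
biases even null channels (a ~20% false-positive rate was measured for the
paternal channel in the one-sample design).

## 6. Polygenic scores

Shrinkage-based score training is deliberately replaced by clumping +
thresholding: candidate weight sets are clumped training statistics over an
(r², p) grid, the cell maximizing tuning-sample R² wins, and outputs are
labelled accordingly. Scores are z-standardized in the scored sample;
missing dosages are mean-imputed per variant; a constant score raises
rather than silently standardizing. Validation reports incremental R² over
covariates, the per-SD effect in days, decile means with normal-theory 95%
CIs, logistic odds ratio per SD and ROC AUC with a 2,000-resample bootstrap
CI (both unadjusted and covariate-adjusted AUCs are available since
published reports rarely state which was used). The train/validation split
is IID (80/20); a kinship-exclusion hook accepts a precomputed list, as no
relatedness is simulated.

## 7. The synthetic world

The generator encodes the stated conditions rather than tuned ones: mean
gestation 282 days, birth weight 3,500 ± 400 g gaining 25 g per day of
gestation, per-allele effects of a fraction of a day (Normal(0, 0.4 d) by
default, or |m| ~ U(0.3, 0.6) d with random sign for balanced designs),
effect-allele frequencies uniform on the configured MAF range, a 20%
medically-initiated delivery flag independent of genotype, two
standard-normal "principal component" covariates and a categorical batch.
Antagonistic pleiotropy is a correlation (default −0.8) between the
maternal GD effect and the direct fetal BW effect at maternal-effect SNPs.
Parent-of-origin magnitudes reuse the fetal effect scale; no empirical
calibration exists for them and the class is configurable.

LD is a first-order Markov allele-copying chain within blocks: one
effect-allele frequency per block, allele copied from the previous SNP
with probability ρ, giving corr(x_j, x_{j+d}) = ρ^d exactly and preserving
marginal frequencies. Coalescent realism, recombination maps, imputation
noise, demography, relatedness and the X chromosome are deliberately
absent; trios sample parental haplotypes from a finite panel, and the
panel must be large relative to the cohort (haplotype reuse acts as
cryptic relatedness and inflates realized estimator error ~25% beyond
nominal SEs when the panel is 5× smaller than the haplotypes drawn).

Consequences for interpretation: a green simulation test establishes that
the estimator recovers the generative quantity under correct model
specification without population structure, relatedness or assortative
mating — not that it is robust to those forces in real cohorts. One noted
interaction: with 200 causal SNPs of 0.3–0.6 days at n = 20,000, the causal
background itself contributes ~24 days² to every per-SNP regression
residual, flooring coefficient SEs near 0.09 days regardless of the
environmental noise setting.

## 8. Numerical conventions

Positions are 1-based inclusive (VCF convention); region strings are
chrom:start-end inclusive. Ties on p-values break by smaller position.
I² is clamped at 0; Q uses df = K−1. The COJO ridge is 1e-8; EM declares
convergence at relative log-likelihood change < 1e-8 within 200 iterations
and returns the best solution found with a convergence flag otherwise. All
randomness flows from explicit integer seeds; reruns with the same seed are
bit-reproducible, and every pipeline artifact records the seed and a hash
of the scientific configuration (output paths excluded).
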