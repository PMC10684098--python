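# Methods

This note documents the models the package implements, the numerical
choices behind them, and what the synthetic cohorts do and do not emulate.

## The synthetic cohort

Downstream methods are validated on simulated cohorts whose genetic
architecture is known exactly.  The generator composes:

**Allele frequencies.** Each ancestry group draws its frequency for
variant *i* from the Balding–Nichols law
Beta(p(1−F)/F, (1−p)(1−F)/F) around a shared ancestral frequency *p*
(uniform on [0.05, 0.95] unless supplied), so the across-group frequency
variance is F·p(1−p).  F is per-group (default 0.1); F = 1 is rejected as
degenerate.  Groups are discrete populations — no admixture tracts.

**Genotypes.** Haplotypes carry block LD from an equicorrelated latent
Gaussian: within a block of `ld_block_size` variants every latent pair has
correlation `ld_rho`, and alleles are obtained by thresholding at the
frequency quantile.  Two independent haplotypes sum to a genotype, so
Hardy–Weinberg holds within each group.  Thresholding a Gaussian
attenuates the correlation on the allele scale (for frequency 0.5 the
allelic correlation is (2/π)·arcsin ρ), so `ld_rho` is an upper bound on
the realized genotypic r, not its exact value; tests that need a specific
LD level measure it from the generated data.  Related pairs are appended
by re-using one haplotype across two individuals, giving an expected
genomic relationship of 0.5 (parent-offspring-like); this exercises the
bK threshold.  Missingness is optional and 0 by default.

**Skin colour.** An ordinal six-level trait (very fair … black) from a
thresholded standard-normal liability combining designated pigmentation
variants, the leading principal component (fraction `skin_pc_frac` of
liability variance), and noise.  Default thresholds put ≈79% of samples
in the very fair + fair range, matching the roughly 79:21 light:dark
split a European cohort self-reports.

**Phenotype.** On the standardized scale,
y = Σβ_a(x−2p) + Σβ_d(z−2pq) + skin·level + Σβ_gxe·x·e + month + sex/age
+ ε, where z is the heterozygosity indicator and the month term is a
sinusoid over assessment months 1–12 scaled to `month_variance_frac`
(a design anchor of 15% is realistic for a high-latitude cohort).  The
noise variance tops the total up to ≈1, and the trait is mapped to
nmol/L as baseline (50 nmol/L) + scale·y with the scale set so the
residual s.d. equals `noise_sd` (default 18.8 nmol/L, a realistic
post-adjustment residual scale for 25OHD).  Values outside the 10–375
nmol/L assay range are flagged.  Effects are in phenotype-s.d. units, so
the realized per-variant h²_QTL equals 2p(1−p)β².

The generator does **not** emulate realistic human LD maps, imputation
dosages, fine-scale admixture, assortative mating, or shared-environment
effects.  Passing tests therefore demonstrate the estimators' correctness
under their stated models, not robustness to every real-data pathology.

## Ancestry assignment

PCA is run on reference genotypes standardized by reference frequencies
((x−2p)/√(2pq), monomorphic variants dropped); study samples are
projected with the *reference* means and scales, matching variants by
(chromosome, position, unordered allele pair), flipping dosages when the
effect allele is swapped, and dropping strand-ambiguous A/T and C/G pairs.
Missing genotypes project to the reference mean.  Each reference
population gets a multivariate Gaussian over the top k = 3 PCs
(covariance regularized by 1e-6 × mean diagonal × I); a sample's
posterior is prior × density, normalized, and the label is the argmax
(ties broken by population order and flagged).  Priors are equal by
default — reference panel sizes are design choices, not population
priors.  With equal spherical covariances this reduces exactly to
nearest-centroid assignment; the full covariance accounts for cluster
orientation.  No projection-shrinkage correction is applied; for small
reference panels the projected scores are biased toward the origin, which
is a known limitation.

## GRM and heritability

The GRM is the standard ratio estimator
A_jk = (1/m) Σ_i (x_ij−2p_i)(x_ik−2p_i)/(2p_i(1−p_i)) over variants with
MAF > 0.01, frequencies estimated in-sample; missing genotypes contribute
their expectation and the per-pair variant count is adjusted.  The bK
matrix zeroes off-diagonal entries below 0.05, keeping the diagonal.

The two-component model V = σ²_g A + σ²_bK A_bK + σ²_e I is fitted by
average-information REML: three EM warm-up iterations, then AI steps with
step-halving whenever a step would decrease the restricted likelihood,
components clamped to [1e-6·var(y), var(y)], convergence when the
log-likelihood changes by less than 1e-6, at most 100 iterations
(non-convergence is flagged and partial results returned).  Standard
errors come from the inverse AI matrix, h² ratios by the delta method.
h²_ped is defined as (σ²_g + σ²_bK)/σ²_P — the sum of both components
over the phenotypic variance.  Identification of σ²_bK rests entirely on
the related pairs, so its standard error is large unless relatives are
plentiful.  The comparison of two independent estimates uses
z = (est₁−est₂)/√(se₁²+se₂²) with a two-sided normal p.

## Association testing

RINT maps value ranks to Φ⁻¹((rank−3/8)/(n+1/4)) (the Blom offset; ties
averaged, missing preserved).  QC filters on MAF, the 1-df χ² HWE test
and missingness; MAC is reported as MAF × 2N with N the smallest analysis
group so that a MAF floor can be read as a minor-allele-count floor.

Additive OLS uses Frisch–Waugh residualization of the phenotype and all
genotype columns on the covariates, which reproduces the per-variant
multiple regression exactly (coefficients and standard errors, df
= n − covariates − 2).  The GLS mode estimates (σ²_g, σ²_e) once on the
null model with a sparse (bK-thresholded) GRM, then whitens by the
Cholesky factor of the fitted V and runs the same residualized
regression — the "variance components once, not per variant"
approximation used by large-scale mixed-model software.  With a zero
genetic component it coincides with OLS.

The dominance model fits intercept + additive coding (0,1,2) + dominance
indicator (0,1,0) jointly.  That design saturates the three genotype
classes, so the fit equals the class-means model: b_add = (m₂−m₀)/2,
b_dom = m₁−(m₀+m₂)/2, Var(b_dom) = s²(1/n₁+1/(4n₀)+1/(4n₂)) with s² the
pooled within-class variance on n−3 df — a closed form that the tests
verify against brute-force OLS.  The dominance term is tested by a 1-df
Wald χ²; the additive coefficient from this non-orthogonal coding is
biased and marked non-reportable.  The uncentred (0,1,0) indicator is
used deliberately; under Hardy–Weinberg its residual variance after the
additive term is (2pq)², which also gives the analytic power of the
dominance test via the non-centrality machinery below.

Meta-analysis is fixed-effect inverse-variance: β = Σwᵢβᵢ/Σwᵢ,
w = 1/se², se = 1/√Σw, after harmonizing alleles to the first stratum
(flips negate β; unresolvable allele pairs are skipped with a warning).
Polygenic scores are weighted sums of effect-allele dosages with
mean-imputation (2p) of missing genotypes.

## Conditional-and-joint selection

From marginal statistics (b_j, se_j, N_j) and a reference panel, the
machinery reconstructs the multiple regression of the phenotype on a
variant set.  With D_j the reference genotype variance and C the
reference covariance matrix of the set (pairs farther apart than the
10-Mb window, or on different chromosomes, fixed at exactly zero):
b_J = C⁻¹(b∘D), the phenotypic variance is reconstructed per variant as
var(y) = D(b² + se²(N−2)) and the median across variants is used, the
joint residual variance is (var(y) − b_J·(b∘D))(N−1)/(N−k−1) with N the
minimum per-variant sample size of the set, and
se_J = √(s²·diag(C⁻¹)/(N−1)).  When the LD reference *is* the GWAS
sample and the GWAS had no covariates, this algebra is an identity: joint
estimates equal the individual-level regression to machine precision,
which is the package's main oracle test.

Selection is stepwise: seed with the smallest marginal p below the
threshold (5×10⁻⁸), then repeatedly add the variant with the smallest
conditional p (its coefficient in the joint fit with the current set)
that stays below the threshold and has multiple-regression R² with the
selected set below 0.9.  Ties break by genomic position then identifier,
making the procedure deterministic and input-order invariant.  No
backward elimination step is performed.  The conditional scan applies the
same joint fit with a fixed conditioning set; a variant conditioned on
itself (or anything with R² ≥ 0.9) is flagged collinear with no estimate.

Dominance loci use the residual two-step procedure instead: residualize
the adjusted phenotype on both codings of the conditioning variant, then
re-test each candidate's dominance term on the residuals.  The residuals
are *not* re-RINTed — re-ranking residuals of an already-transformed
phenotype would distort planted effects; this is a documented
interpretation choice.

## Effect-size comparison

r_b divides the covariance of two aligned estimate vectors by the
geometric mean of their error-corrected variances (var(b̂) minus the mean
squared standard error on each side).  A side whose corrected variance is
non-positive has no detectable effect-size variance and is reported as an
error.  The standard error is a leave-one-variant-out jackknife: the
estimator's distribution is awkward analytically, the jackknife is
assumption-light, and the point estimate can slightly exceed |1| (flagged
beyond 1.05).  Locus classification labels each independent locus
shared / new / lost at the 5×10⁻⁸ and 10⁻⁶ thresholds, annotating new
and lost loci with the distance and maximum LD r² to the nearest
genome-wide-significant variant of the other analysis within a 1-Mb
radius (|Δpos| ≤ 1,000,000 bp on the same chromosome).

## Stratified analysis

Light skin = very fair + fair; dark = light olive + dark olive + brown;
black-skin reports and samples with inconsistent reports across visits
are excluded with per-reason counts.  Each stratum is analysed with the
phenotype RINT-transformed *within the stratum* and principal components
recomputed on the stratum's samples — together this absorbs both mean
and variance differences between the skin groups — and the strata are
combined by inverse-variance meta-analysis over variants passing the MAF
floor in both.  Within-stratum RINT (rather than pooled) is an
interpretation choice; it is what makes the variance adjustment exact.
The simulations show the mechanism by which this design gains loci: when
skin colour carries a large share of trait variance, the pooled design
leaves it in the residual while stratification removes the between-group
part, so marginal QTLs cross the significance threshold in the meta but
not the pooled analysis.  A variant acting *only* through a mediator that
stratification conditions on would, conversely, lose signal — both
directions are real properties of the design.

## Interactions

Pre-processing runs within each sex × supplement-intake stratum (up to
8): regress the raw nmol/L phenotype on age, assessment month and centre,
drop residuals beyond 5 s.d. (a configurable rule; for Gaussian data it
removes essentially nothing), re-standardize to mean 0 / variance 1, and
record the pre-standardization residual s.d. in nmol/L.  The mean of
those s.d.s is the package's conversion factor between s.d. units and
nmol/L (rounded to one decimal for reporting).

The variance screen is the Brown–Forsythe (median-centred Levene) test of
phenotype variance across the three genotype classes — a self-contained
way to nominate variance QTLs, which are the natural candidates for
interactions because an unmodelled g×e term inflates within-genotype
variance.  The interaction model is y ~ g + e + g×e with mean-centred
genotype and skin-level indicators against the very-fair reference;
family-wise significance divides α = 0.05 by the number of vQTLs tested
(25 → 0.002).  The genome-wide interaction scan restricts to one
two-level skin contrast and MAF > 0.05 (interaction tests at rarer
variants are fragile), flagging genome-wide (5×10⁻⁸) and suggestive
(10⁻⁶) hits.

## Enrichment and power

Enrichment draws 10,000 same-size SNP sets without replacement from the
candidate pool and counts, per set, how many SNPs are associated with at
least one queried trait (minimum p across traits below 5×10⁻⁸).  The
one-tailed empirical p is the fraction of null sets with a count at least
the observed one, with *no* pseudo-count — fidelity to the plain
counting rule — so the smallest reportable value, 1/n_perm, is returned
alongside and flagged when attained.  On the single-threshold reduction
the empirical p converges to the exact hypergeometric tail, which the
tests verify.

Power: h²_QTL = 2p(1−p)β² under Hardy–Weinberg, λ = N·h²/(1−h²), and the
detection probability is the upper tail of the non-central χ²₁ beyond the
central upper-α quantile.  λ = 0 returns α exactly.  `power_curve`
composes these over a sample-size grid.

## File formats and determinism

PLINK .bed is read and written at the bit level (variant-major, magic
0x6C 0x1B, mode 0x01; 2-bit codes 00/10/11/01 = hom-A1/het/hom-A2/missing
packed four samples per byte from the least-significant pair), with .bim
and .fam as 6-column tables; the codec is round-trip exact including
padding.  Summary statistics use the whitespace-separated
`SNP A1 A2 freq b se p N` layout.  Run configuration is a YAML dataclass
with a stable digest; result files carry `#`-prefixed provenance headers
(config hash, seed).  Every stochastic stage takes an explicit seed or
Generator, and identical configuration + seed reproduces outputs
byte-for-byte.

## Problem sizes

The validation suite exercises: the joint-fit oracle at n = 2,000
samples × 200 variants; REML recovery at n = 2,000 (500 related pairs)
with a 5,000-variant GRM and 1,000 untagged causal variants; dominance
calibration on 1,000 null variants at n = 3,000 and detection of a
0.15-s.d. heterozygote effect at n = 20,000 across replicates; r_b on
200 replicates of 1,000-variant panels; enrichment at 10,000
permutations; and ancestry assignment on four populations of 500 at
Fst = 0.1.  These sizes give each check clear statistical resolution
while keeping the full suite and the acceptance script fast on a single
CPU.

## Known limitations

* The GLS association mode fixes variance components at their null-model
  estimates; saddlepoint or exact-score refinements are out of scope.
* σ²_bK is weakly identified without many relatives; its standard error
  honestly reflects that.
* The summary-based joint fit assumes the LD reference matches the GWAS
  population; frequency mismatches beyond 0.2 between summary rows and
  the reference exclude the variant as a mislabeling guard.
* r_b can exceed |1| in small panels; values beyond 1.05 are flagged
  rather than truncated.
* The vQTL screen is a generic variance-heterogeneity test, not a
  replication of any specific published vQTL list.
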