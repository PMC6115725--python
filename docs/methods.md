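# Methods

`pgsx` asks two questions about the genetics of a quantitative trait
(BMI throughout): does the effect of a polygenic score grow across the
trait distribution (a PGS×environment signature), and does the effect of an
individual SNP grow with the polygenic background it sits on (allele
expressivity, a G×PGS signature)?  The package provides the full analysis
chain — genotype I/O, GWAS, score construction, decile-effect estimation,
expressivity — plus a synthetic cohort generator that embeds both
interaction structures so the chain can be validated end to end without
access-controlled biobank data.

## Generative model

The simulator draws, for individual *i* with dosages *g<sub>ij</sub>*:

    BMI_i = mu + c·x_i + alpha_env·E_i
            + A_i (1 + theta_gxe·E_i + lambda_gxg·Ã_i) + eps_i

where `A_i = Σ_j beta_j g_ij` is the aggregate genetic value, `Ã` its
z-score, `E ~ N(0,1)` an *unobserved* environmental exposure,
`x` the covariates (age ~ U(40, 69) years, sex ~ Bernoulli(0.5), ten
standard-normal principal components carrying no confounding), and
`eps ~ N(0, sigma_e²)`.  The two interaction knobs act multiplicatively on
the aggregate genetic value: `theta_gxe > 0` amplifies every allele's
effect in proportion to the exposure, `lambda_gxg > 0` in proportion to the
polygenic background.  Setting both to zero gives a purely additive cohort.
`E` is written to the truth table but never consumed by analysis stages:
the pipeline must infer amplification indirectly, which is exactly the
epidemiological setting the analyses target.

Genotypes are Hardy–Weinberg hard calls: per SNP a MAF is drawn uniformly
from `maf_range`, and each of the two alleles per individual is obtained by
thresholding a latent standard normal at Φ⁻¹(MAF).  Within an LD block the
latents share an equicorrelated factor `ld_rho` per haplotype; thresholding
attenuates the latent correlation (ρ = 0.9 at MAF 0.30 maps to genotype
r² ≈ 0.49, checked against direct Monte-Carlo sampling of the bivariate
normal).  With `ld_rho = 0` dosages are exactly Binomial(2, MAF).

Defaults describe a desk-scale but realistic BMI cohort: baseline
27 kg/m², residual sd 4 kg/m², exposure main effect 1 kg/m² per sd,
100 causal SNPs out of 500 with per-allele effects `beta_sd = 0.3` kg/m²
(≈ 17% of phenotypic variance, in line with common-variant heritability
estimates for BMI).  What the generator does *not* emulate: realistic
human LD maps, population structure or stratification, rare variants,
genotype missingness, assortative mating.  Passing tests therefore show
the estimators behave correctly under the stated model, not that every
real-data complication is handled.

## Association

Per-SNP models are OLS of phenotype on covariates plus additive dosage.
The genome-wide scan residualizes the phenotype and all dosage columns on
the covariates once (Frisch–Waugh–Lovell) and is algebraically identical
to fitting each full model; p-values use the t distribution with exact
residual degrees of freedom.  Missing dosages are mean-imputed within the
analysis sample; SNP filters default to MAF ≥ 0.01 and missingness ≤ 0.05.
BMI strata are half-open intervals — underweight (0, 20), normoweight
[20, 25), overweight [25, 30), obese [30, ∞) — so every sample falls in
exactly one stratum; assignment uses raw BMI before any transformation.
Replication counting against a reference SNP list reports observed counts
at each threshold alongside the null expectation (SNPs tested × α).

## Polygenic scores

Candidate SNPs are partitioned by summary p-value into half-open bins
(lower, upper]; the ladder defaults to (10⁻⁷, 10⁻⁵], (10⁻⁵, 10⁻³],
(10⁻³, 0.01], (0.01, 0.05], and a [0.95, 1] control of null SNPs.
Candidates in LD (r² > 0.2) with any anchor SNP (the genome-wide hits
forming the strongest score) are removed, then each bin is LD-pruned in
sliding windows (10 kb default, 5-SNP step, r² ceiling 0.5) keeping the
SNP with the stronger summary association, ties broken against the later
position.  Window width is interpreted in kilobases with a `snps` option,
since variant-count and kb dialects of the same pruning parameters
disagree.  Scores orient every SNP to its trait-increasing allele;
unweighted scores count those alleles, weighted scores use |summary beta|.
Strand-ambiguous (A/T, C/G) SNPs are kept by default; an option drops
them.  The residualization cascade replaces each weaker-bin score by its
OLS residuals on intercept + all stronger-bin scores (no covariates in
these regressions), which equals Gram–Schmidt orthogonalization and makes
the decile profiles of different bins attributable to independent signal.

## Decile effects

The default profile estimator is linear quantile regression of BMI on
score + covariates at the decile midpoints τ = 0.05, 0.15, …, 0.95
(a boundary grid 0.1…0.9 is available).  The check-loss minimizer is
computed exactly as a linear program: the dual (n box-constrained
variables, p equalities) is solved with HiGHS and the primal vertex
recovered from the strictly interior dual variables, falling back to the
primal LP on degeneracy.  On enumerable instances the objective matches
exhaustive vertex search to 1e-8 or better.

Inference on the profile needs care: quantile estimates at different taus
share the sample, and their errors follow a Brownian-bridge-like process
whose dominant mode is a *tilt* across taus.  Treating the ten estimates
as independent makes the trend test reject wildly under the null (we
measured p ≈ 1e-6 on additive-only data).  `pgsx` therefore estimates the
joint covariance of the score coefficient across taus under the iid-error
asymptotics, cov(β̂(s), β̂(t)) = (s∧t − st)·ŝ(s)ŝ(t)·(X′X)⁻¹, with
sparsities ŝ(τ) = 1/f(F⁻¹(τ)) from Hall–Sheather difference quotients of
each fit's residual quantile function, and tests the trend by GLS under
that covariance.  In 50-seed null simulations this test holds its 5%
level.  Case-bootstrap SEs (B = 200, seeded) are available as a
model-agnostic alternative for per-decile CIs.

The cross-check estimator bins samples into ten equal-count BMI deciles
(ties broken by stable order, bin sizes differ by ≤ 1) and runs OLS of BMI
on score + covariates within each bin.  Because bins are disjoint, the
decile estimates are independent and the trend test is inverse-variance
WLS.  Note its known distortion: conditioning on a narrow outcome band
attenuates middle-decile coefficients while the open-ended extreme bins
retain signal, so the stratified-OLS profile shape is not comparable to
the quantile profile even though both are flat under the null and rising
under genuine amplification.

The inverse normal transformation uses Blom scores,
Φ⁻¹((rank − 3/8)/(n + 1/4)) with average ranks for ties.  A purely
multiplicative-noise model y = (mu + A)(1 + η·eps) — scale inflation with
no genetic amplification — produces a rising raw-BMI profile that the INT
control flattens; this confound demonstration is a tested property, and is
why both raw and transformed analyses are always reported together.

## Expressivity

For each SNP in the panel (within-cohort MAF ≥ 0.05), BMI is regressed on
dosage (no covariates, matching the published model; adjustment is an
option) within each decile of the unweighted background PGS built from the
same panel.  The regression of the ten decile estimates on decile index
1…10 (unweighted OLS; inverse-variance weighting optional) gives the
SNP's expressivity slope; deciles where the SNP is monomorphic are
skipped, and SNPs with more than three undefined deciles are excluded.
Cohort-level evidence is the exact two-sided binomial test (minlike
convention: sum of all outcome probabilities not exceeding the observed
one) on the count of positive slopes against 0.5, computed by full pmf
enumeration, plus the Pearson correlation between slopes and external
effect sizes.

Including the focal SNP in its own background score (the published design,
kept as the default) induces a collider artifact: conditioning on the
total allele count couples the focal dosage negatively to the rest of the
background, and when background effects grow across deciles this adds a
negative offset to every slope.  In our simulations at lambda_gxg = 0.5
the offset (≈ −0.03 kg/m²/allele/decile) cancels much of the true
amplification signal, while the null (lambda = 0) remains calibrated
because the cross-contamination is then constant across deciles.  The
`background="loo"` mode excludes each focal SNP from its own background
before decile assignment, removing the artifact; power analyses should
use it, and comparisons with the published include-mode counts should
expect attenuation.

## Numerical and design notes

- PLINK 1 bed/bim/fam is the only genotype dialect (SNP-major, hard
  calls); the codec is bit-exact and round-trips byte-for-byte.
- Summary-statistics columns are mapped explicitly by the caller; no
  header auto-detection.
- All stochastic stages derive their seeds deterministically from one
  global seed; identical configs give byte-identical outputs.
- Equal-count decile assignment uses a stable sort on (value, input
  order), so ties never unbalance bins.
- Degenerate inputs are flagged, not silently dropped: constant dosage
  vectors yield NaN effect estimates, constant scores raise, strata with
  too few samples are skipped with a warning, and an all-zero genetic
  value with lambda_gxg ≠ 0 is an error (the background z-score is
  undefined).
- Validation problem sizes: oracle tests run at n ≤ 50 (OLS) and n = 12
  (quantile vertex enumeration); calibration and power simulations use
  cohorts of 20,000 samples × 500 SNPs (100 causal) over 50 and 7 seeds
  respectively, with theta_gxe = 0.5, alpha_env = 2.0 as the strong
  G×E setting and lambda_gxg = 0.5 as the strong G×background setting.

## Known limitations

Analytic quantile-profile inference assumes iid errors given the design;
under strong heteroskedasticity the GLS trend test is approximate (the
bootstrap option is the fallback).  LD pruning follows a documented greedy
rule that need not match PLINK's under-specified victim choice SNP for
SNP.  The stratified-OLS profile is a shape-distorted cross-check, not a
replacement for the quantile profile.  The simulator's interaction enters
through the aggregate genetic value only; per-SNP heterogeneous
interaction coefficients are out of scope.
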