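# Methods

## Model and estimands

The package fits the standard GREML linear mixed model
`y = X beta + Z u + e` with `u ~ N(0, (tau/m) I_m)` and
`e ~ N(0, sigma2 I_n)`, where `Z` is the n×m genotype matrix standardized
column-wise as `z = (g − 2p) / sqrt(2 p (1−p))` under the estimated allele
frequency `p` (missing dosages imputed to `2p`, i.e. z = 0). The genetic
covariance is then `tau·K` with `K = ZZ'/m` the genomic relationship
matrix, whose average diagonal is close to 1, so `tau` lives on the
phenotype scale and `h2 = tau/(tau+sigma2)`. The distributional forms of
`u` and `e` are the usual GREML convention; nothing in the package depends
on them beyond second moments except the likelihood itself.

Three estimands are reported per fit: the variance components with
average-information standard errors, the heritability with a delta-method
standard error (gradient `(sigma2, −tau)/(tau+sigma2)²` applied to the
inverse AI matrix), and a three-way decomposition of the phenotypic
variance. The covariate part of that decomposition uses

    var_fixed = ( ||C X b||² − tr(C X Cov(b) X') ) / (n−1),

where `C = I − 11'/n` and `b` is the GLS fixed-effect estimate at the REML
optimum. The subtraction matters: `E||C X b||²/(n−1)` exceeds the true
centered variance of `X beta` by exactly `tr(C X Cov(b) X')/(n−1)`, and
with hundreds of PC covariates the inflation is far from negligible. The
estimator is validated by a known-truth Monte Carlo in the test suite
(500 replicates: corrected estimator unbiased within two standard errors,
naive estimator demonstrably high). A negative corrected value — possible
when the trace correction is large relative to the signal — is clamped to
zero with a warning; the pre-clamp value is retained on the result object.

## REML computation

Single GRM. `V = tau·K + sigma2·I` is diagonal in the eigenbasis of `K`,
so after one symmetric eigendecomposition every restricted-likelihood
evaluation is O(n·p²). The likelihood is profiled over the heritability
ratio `gamma = tau/(tau+sigma2)`: at fixed `gamma` the scale
`s = tau+sigma2` has the closed form `s = y'P_W y/(n−p)`. The profile is
maximised by a coarse grid (log-spaced near both boundaries, 58 points)
followed by bounded scalar minimisation (`xatol = 1e-10`) between the
bracketing grid points, and the value at `gamma = 0` is always compared
explicitly so boundary optima are exact. `gamma < 1e-6` sets the boundary
flag. A phenotype lying exactly in the span of `X` yields a degenerate
flag rather than an exception. The restricted log-likelihood includes the
`+½ log|X'X|` normalisation, making it invariant to the error-contrast
basis and to invertible reparametrisations of `X`.

The eigendecomposition is cached on the GRM object and shared across every
fit that reuses the kinship — the PC sweep and the replicate studies refit
only `X` or `y`, which is the central performance decision: a sweep over
many values of p, or hundreds of phenotype replicates, costs one O(n³)
decomposition total.

Multi GRM (per-chromosome model). `V = Σ tau_c K_c + sigma2 I` is fitted
by average-information REML: two expectation-maximisation warm-up steps,
then AI updates with two safeguards that the near-collinearity of
chromosome GRMs (they share the population structure) makes necessary in
practice: (i) an active set — components at the non-negativity boundary
whose score is still negative are frozen and the AI system is solved over
the free components only; (ii) likelihood-guarded step halving, with EM as
the fallback direction. Convergence is declared when the largest parameter
change is below `1e-6·Var(y)`; the AI matrix condition number above 1e10
sets an `ai_singular` flag (e.g. two identical GRMs, where only the sum of
their components is identifiable). With a single GRM the AI path agrees
with the profile path to 1e-6 in all parameters (tested).

Standard errors come from the inverse AI matrix evaluated at the optimum
in both paths, matching mainstream GREML software conventions.

## Boundary-mixture LRT

H0: h2 = 0 places `tau` on the boundary, so twice the restricted
log-likelihood gap between the full fit and the fixed-effects-only fit is
asymptotically `½χ²₀ + ½χ²₁`: `p = ½ P(χ²₁ ≥ stat)` for positive
statistics, 1 at zero; the 5% threshold is 2.7055 ("2.70"). Both
likelihoods are restricted likelihoods of the same contrasts (the null is
the `gamma = 0` profile value), so the gap is well defined; it is clamped
at zero because the boundary optimum can sit numerically ~1e-12 below the
null. Calibration is checked by simulation: the test suite verifies the
~50% point mass at zero and a rejection rate in [0.03, 0.07] at the 2.70
threshold over 1000 null replicates. The asymptotics need information-rich
fits; the calibration fixture uses n = m = 300, where the GRM spectrum is
wide (eigenvalue dispersion grows with n/m) — with m ≫ n the likelihood
per replicate flattens and the finite-sample point mass drifts above ½.

## Chromosome-partitioning diagnostic

Heritability is estimated once per chromosome (single-GRM fits on each
chromosome's own standardized SNPs) and once jointly (one multi-GRM fit),
and `d_c = h2_single,c − h2_joint,c` is regressed on chromosome length by
OLS with two-sided t-tests. Conventions, stated because the literature
leaves them loose: `h2_single,c = tau_c/(tau_c + sigma2_c)` from the
single fit; `h2_joint,c = tau_c^joint/(Σ tau^joint + sigma2^joint)`;
"length" defaults to SNP count (equal information per SNP under uniform
density), with base-pair span available. Chromosomes under 10 SNPs are
excluded with a warning. A positive intercept indicates cryptic
relatedness (every chromosome's GRM sees the same pedigree signal, a
length-independent excess); a positive slope indicates stratification.

In the generator's world the slope arises because a chromosome's GRM
represents the shared ancestry axes with an accuracy that improves with
its SNP count, so longer chromosomes soak up more of the stratified
variance in single fits. That alignment effect is strongest when the
structure eigenvalue sits near the noise-bulk edge of the chromosome GRM
spectrum; the diagnostic tests therefore run at n = 300 with ~100-SNP
chromosomes spanning a 4:1 length range (the spread of real human
chromosomes; the generator's 2:1 default is conservative) and F_ST = 0.05,
where the detection power of the slope test is essentially 1.

## Synthetic data

The generator emulates a multi-centre European cohort at configurable
scale. Genotypes follow the Balding–Nichols model: ancestral frequency
`p_j ~ Uniform(maf_range)` (default 0.05–0.50), subpopulation frequency
`Beta(p(1−F)/F, (1−p)(1−F)/F)` with `F = fst`, genotypes `Binomial(2, p)`.
Individuals are assigned to subpopulations by the weight vector and given
birth coordinates = subpopulation centre + Gaussian jitter (default SD
0.3°); default centres resemble Bordeaux / Dijon / Montpellier. In cline
or mixed mode each SNP additionally receives an isotropic logit-frequency
gradient `a_j ~ N(0, cline_strength² I₂)` applied to the coordinate
deviation from the map centroid; frequencies leaving (0,1) are clipped to
[0.01, 0.99] and counted. Sex and age covariates default to the cohort
moments female fraction 0.603, age 74.30 ± 5.52 y. SNPs are split into 22
contiguous chromosome blocks with lengths decreasing linearly 2:1 by
default (configurable). All generators are pure functions of
(configuration, seed).

Phenotypes are drawn under the model itself: slope
`beta_i = sqrt(share_i)/sd(PC_i)` gives PC i its target variance share,
`u` is i.i.d. `N(0, tau/m)` over all SNPs, and the returned object records
the fixed, genetic and residual parts exactly (they sum to `y` to machine
precision). The reference design is ten causal PCs at 2% each with
`tau = sigma2 = 0.4`, i.e. truth 20% / 40% / 40% and h2 = 0.5.

What the generator does not emulate — and what passing tests therefore do
not establish about real data: linkage disequilibrium (SNPs are
independent within subpopulation, so LD pruning is exercised only through
injected duplicates and sampling correlation), genotyping artifacts beyond
uniform missingness, ascertainment, assortative mating, and any genuine
environmental geography beyond what the PC effects encode. Conclusions
about how many PCs real traits need are the method's to make on real data;
the simulations establish correctness of the machinery, not realism.

## Study scales and reproducibility

The replicate study runs at n = 600, m = 6000, three subpopulations,
F_ST = 0.02, 50 replicates — large enough that the 10-PC fit recovers
20/40/40 within two Monte-Carlo standard errors while one full study
completes in seconds (the per-replicate SD of h2 is ≈ 0.19 at this scale
and shrinks roughly as sqrt(m)/n, so the full-scale run reproduces the
≈ 0.05 replicate SD). Master seed s spawns replicate k's generator as
`default_rng([s, k])`, so any replicate is reproducible in isolation and
whole runs are bit-reproducible.

## Numerical choices and limitations

* HWE filtering uses a 1-df chi-square on genotype counts, not PLINK's
  exact test — adequate at the 1e-8 threshold for synthetic data; the two
  diverge for rare genotype classes.
* LD-pruning r² is the squared Pearson correlation of dosages (genotypic
  r², the PLINK default); within a window the lower-MAF member of the
  worst pair is dropped, ties broken toward the later position — any
  deterministic rule would do, this one is fixed so tests can be exact.
* Relatedness pruning greedily removes the individual in the most
  violating pairs, ties toward the higher index; the retained set is
  asserted to have all off-diagonals at or below the threshold.
* GRM eigenvalues below −1e-8 warn; small negatives are clipped to zero.
* PCs are unit-norm eigenvectors with sign fixed by the
  largest-magnitude entry; fixed-effect estimation is scale-invariant, so
  the convention only affects reported beta magnitudes.
* No BLUP prediction, no GxE, no X chromosome, no haplotype r², no
  case/control ascertainment; long-range-LD exclusion is supported only
  through a user-supplied region file.
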