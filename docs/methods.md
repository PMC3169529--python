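# Methods

This note documents the statistical models, numerical choices and
limitations of `twinmqtl`, in the order data flows through the pipeline.

## Cohort model and synthetic data

A cohort is a set of MZ pairs, DZ pairs and singletons. Pair-like units
attend clinic visits together (co-twins share every visit index and
collection time), each biological sample is split into technical-replicate
aliquots, and aliquots are allocated to plates by a seeded random
permutation (a randomized plate design). The default reference design is
51 MZ pairs (33 with two visits), 19 DZ pairs and 2 singletons — 142
subjects — with two aliquots per sample and collections at 10:00 or 14:00.

Genotypes are simulated at Hardy–Weinberg equilibrium. MZ co-twins share
one genome; DZ co-twins are produced by drawing two HWE parents and
transmitting one uniformly chosen allele from each parent to each twin.
This makes identity-by-descent sharing genuine rather than imposed, and
yields the standard expected within-pair dosage correlation of ½ for DZ
pairs (1 for MZ). A correlated-Gaussian shortcut would have matched second
moments only.

Phenotypes follow the twin variance-components model

    y_ijkl = b0 + bg*g_ij + plate_{p(ijkl)} + bt*t_ik
             + f_ij + e_ij + v_ik + w_ijk + eps_ijkl

with independent zero-mean Gaussian random effects at standard deviations
(sigma_f, sigma_e, sigma_vc, sigma_vi, sigma_eps). The familial effect f is
identical within MZ pairs and correlated `dz_familial_corr` within DZ
pairs. **Default `dz_familial_corr` = 0.5**, the classical twin-model value
for a pooled genetics-plus-shared-environment component under additivity;
it is configurable because the pooled component's DZ correlation is not
identifiable from MZ/DZ data without further assumptions. Units follow the
phenotype (log-concentration) scale; time effects are per clock hour.

Spectra are rendered as sums of unit-apex Lorentzians — the natural NMR
lineshape — scaled by concentration and a per-peak proton factor, plus a
piecewise-constant baseline (independent constant on each side of the
water region), optional interfering resonances, chemical-shift jitter and
iid Gaussian noise. The generator does **not** emulate phasing errors,
water-suppression artefacts, peak-width variation, urea chemical exchange,
or multiplet structure; passing tests therefore demonstrate correctness of
the downstream statistics under idealised lineshapes, not robustness to
acquisition artefacts.

## Spectral preprocessing

* **Alignment** shifts the ppm axis so the highest local maximum in a
  search window lands on the reference shift (δ0.00 TSP for urine, δ8.452
  formate for plasma). Sub-grid apex positions are linearly interpolated.
* **Denoising** (optional, off by default) is wavelet shrinkage: sym8,
  symmetric boundary, full decomposition depth, universal soft threshold
  sigma*sqrt(2 log n) with sigma estimated by the MAD of the finest detail
  coefficients. The exact wavelet family and threshold are package
  choices; results downstream are insensitive because peak heights are
  read after baseline correction.
* **Baseline** subtracts, on each side of the water interval, that side's
  empirical 5th percentile (linear-interpolation percentile definition,
  configurable). Water-interval points are excluded from both estimates
  and assigned the nearer side's offset.
* **Peak extraction** reads the height of the highest *interior* local
  maximum in a closed ppm bin. A local maximum is a point strictly greater
  than both neighbours; a maximal flat run strictly above both neighbours
  counts once, at its midpoint; runs touching a bin edge are not interior.
  No interior maximum ⇒ missing. This reproduces the two real missingness
  mechanisms: concentrations too low to form a maximum, and bins swamped
  by an overlapping neighbour (censoring).
* **Presence filter** keeps peaks present in ≥ 80% of records (boundary
  inclusive).
* **PQN** divides each record by the median, over its non-missing peaks,
  of the ratio to a median reference profile. Exact scale invariance of a
  record holds when the reference is unchanged by the rescaling; with few
  records an extreme rescaling can move the median itself, which is a
  property of PQN, not of this implementation.
* **Log transform**: one global affine map sends the table-wide min/max to
  0/100, then log2(x + c) with offset c = 1 (base and offset
  configurable). Base 2 makes unit differences interpretable as fold
  changes.

## Genome-wide scan

Replicate measurements are averaged per subject on the log scale, then
rank-mapped to Gaussian quantiles with offset (r − ½)/n and average ranks
for ties — the result is invariant to monotone transforms of the input.
Each SNP is tested by OLS slope t-statistic; monomorphic SNPs score t = 0
(flagged) so the SNP set is identical in every permutation.

The null distribution of T_max = max |t| is generated by uniformly
permuting MZ-pair phenotype blocks among MZ slots, DZ blocks among DZ
slots, and singletons among singletons, preserving within-pair order.
Identity permutations are allowed by default (excluding them would bias
the null; a derangement mode is available behind a flag). Within-pair
order is never swapped, which is conservative with respect to twin-order
effects. Rejection requires T_max to exceed *all* B draws, giving exact
size 1/(B+1) under exchangeability of pair blocks; the package reports the
empirical p-value (1 + #{draws ≥ T_max})/(B+1) and an exact 95%
Clopper–Pearson interval for the FWER based on the exceedance count. The
hit region is the per-chromosome [min, max] position span of SNPs with |t|
above the largest null draw; spanning multiple chromosomes triggers a
warning and per-chromosome regions.

## Genotype QC

MAF and Hardy–Weinberg statistics are computed over unrelated individuals
only (one twin per pair plus singletons) when cohort metadata is supplied,
since duplicated MZ genomes would distort both. The HWE test is the exact
conditional test: given the allele counts, the p-value sums the
probabilities of all heterozygote counts no more probable than the one
observed (computed by log-factorial enumeration; a chi-square variant was
deliberately not used because rare-allele SNPs are exactly where QC
operates). Removal rules use literal strict inequalities; a SNP with MAF
exactly 5% triggers neither the low-call-rate rule for common SNPs nor the
one for rare SNPs. QC is idempotent. Best-guess genotypes take the argmax
of the imputation probability triple, ties broken toward the lower dosage.

## Mixed-effects analysis of hit regions

The record-level covariance implied by the model is assembled blockwise by
shared-factor rules (same pair/subject/visit/aliquot membership), with the
DZ familial cross-twin correlation as above. Fits operate on independent
pair blocks grouped by structural pattern, so likelihood evaluations cost
O(pairs × block³) with tiny blocks.

**Maximum likelihood.** SDs are parameterized as sigma = s_y * exp(z) with
z bounded in [−15, 4] (the lower bound is an effective zero, handling
boundary estimates); fixed effects are profiled out by GLS inside the
objective; optimization is L-BFGS-B from a deterministic start, with
random restarts only on convergence failure. The SNP test is the
likelihood-ratio statistic 2(l_full − l_null) against chi-square(1) — the
SNP effect is a fixed effect, so no boundary correction is needed.
Identifiability is checked structurally before fitting (e.g. experimental
vs individual-visit variance needs replicated aliquots; individual-visit
vs individual-environment needs repeated visits) and unidentifiable
component pairs raise an error naming them.

**Bayesian fit.** Priors are Uniform(0, k·s_y) on each SD with k = 100,
and Gaussian on the fixed-effect vector centred at the least-squares
estimates with variance v·s_y² per coefficient, v = 10⁶ (both
configurable; the uniform-SD prior follows standard weakly-informative
practice for hierarchical scale parameters). The sampler is
Metropolis-within-Gibbs: exact Gaussian conjugate updates for the fixed
effects given the covariance, and adaptive random-walk Metropolis on each
SD against the marginal (random-effects-integrated) blockwise likelihood,
with step sizes tuned toward ~44% acceptance during burn-in only.
Split-chain R-hat is reported for every SD; values above 1.05 warn rather
than fail, and a prior-only mode exists to validate the sampler against
its priors.

**Decomposition.** Per posterior draw, the SNP-explained variance is
beta_g² times the *empirical* dosage variance (sample variance, ddof = 1)
across subjects — robust to HWE departures, unlike 2p(1−p). Biological
variance is the SNP term plus the familial, individual-environment,
individual-visit and common-visit variances; experimental variance is
excluded so that decompositions are comparable across measurement
platforms. Proportions are summarised by posterior mean, quartiles and
2.5/97.5 percentiles, rendered as "mean% (lo–hi)". Draws with zero
biological variance are excluded and counted. The familial component pools
genetics and common environment — a twin design cannot separate them — and
is labelled accordingly.

**Replication mode.** Cohorts without technical replication are tested by
covariate-adjusted OLS (age, sex) on inverse-normal phenotypes with
Bonferroni thresholds alpha/m. Their effect sizes are estimated as
Var(beta_hat·g)/Var(y), rescaled to the biological scale by dividing by
(1 − experimental fraction) taken from a replicated cohort.

## Power

Power of the two-sided per-test slope test at level alpha_family/m uses
the noncentral F(1, n−2) distribution with noncentrality
lambda = n·rho²/(1−rho²) (the asymptotic form absorbing regressor
variance; the (n−2) variant differs negligibly at relevant n). Detectable
rho² inverts the power function by bisection to 1e-6.

## Problem sizes used in validation

The test suite and acceptance script validate these claims at the
following scales, chosen to make Monte-Carlo error bands tight relative to
the assertions: permutation-null calibration with B = 199 over 4,000
(suite) / 2,000 (script) exchangeable-null cohorts of 12 MZ + 8 DZ pairs +
2 singletons against the exact rate 1/200 with 3-SE binomial tolerance;
dense-likelihood agreement on ≤ 15-record cohorts to 1e-8; posterior
recovery of biological proportions (0.40/0.30/0.10/0.15/0.05, 20%
experimental share) on 70 MZ + 30 DZ pairs × 2 visits × 2 aliquots,
averaged over 20 seeds, to ±0.07; LRT null uniformity over 500 replicates
(KS at 0.01); power-formula agreement with simulation at five (n, rho²)
grid points; preprocessing linearity and PQN invariance to 1e-6; and HWE
exactness against enumeration to 1e-12 for totals up to 200.

## Known limitations

* The discovery scan has no covariate adjustment by design; covariates
  enter only the replication and mixed-model stages.
* No mixed-model scan at genome scale: the mixed model is reserved for
  hit regions, the permutation null handles kinship genome-wide.
* No dominance modelling (the additive dosage model is used throughout),
  no separation of additive-genetic from common-environment variance, no
  X-chromosome handling, and no imputation engine (probability triples
  are inputs).
* The MCMC sampler is a single-site random-walk scheme: adequate for the
  5-SD models here, but slow mixing should be expected if the model is
  extended with many more variance parameters.
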