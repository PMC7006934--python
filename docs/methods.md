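# Methods

`diallelgp` analyses single-cross (F1) hybrid populations from two-group
partial diallels: phenotype adjustment from unreplicated augmented-block
trials, marker quality control with in-silico hybrid genotypes, genomic
prediction by marker-assisted selection (MAS), GBLUP, RKHS and BayesB, and
additive-dominance association mapping with permutation-based family-wise
thresholds.  This note records the statistical models, the defaults and why
they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical decisions a maintainer would want to know.

## Phenotype adjustment and heritability

Plot yields are modelled per nitrogen regime as

    y = X b + V u + e,    u ~ N(0, I s2_b),   e ~ N(0, I s2_e),

with fixed effects for entries (checks and hybrids), environments
(site x year) under sum-to-zero contrasts, and check x environment; blocks
within environment are random.  Because hybrids are unreplicated, the
replicated checks carry the information separating s2_b from s2_e.  REML
uses the block-diagonal structure of the marginal covariance: the ratio
s2_b/s2_e is profiled with per-block Sherman-Morrison closed forms, and the
residual variance has a closed-form maximizer, so each evaluation is
O(n p^2).  A hybrid's adjusted mean is its GLS entry coefficient, which the
contrasts place on the average-environment baseline.  The fit is checked
against lme4 (`Rscript`) in the test suite.

Heritabilities come from a second model with hybrid, environment and
check x environment random (checks keep fixed entry effects, so the
genotypic variance refers to hybrids).  This crossed model is solved by
dense average-information REML with a monotone line search and a
multiplicative EM fallback (convergence 1e-8 on the restricted
log-likelihood, at most 200 iterations, components floored at 1e-8 times
the phenotypic variance and reported as 0 when pinned).  The two levels are

    plot:        H2 = s2_g / (s2_g + s2_ga + s2_e)
    entry mean:  H2 = s2_g / (s2_g + s2_ga/a + s2_e/(a r))

with `a` environments (default: the observed count) and `r` replications
(default 1).  The low-nitrogen tolerance index per hybrid is
LNTI = (1 - GY_LN / GY_IN) x 100; entries with non-positive GY_IN are
flagged and excluded, and an optional absolute band can flag extreme values
(none by default).

## Marker QC and hybrid genotypes

The chain for an inbred parent panel, in order: (1) drop markers with call
rate < 0.95; (2) drop loci with any heterozygous call; (3) impute the
remaining missing calls by seeded draws from each marker's observed
homozygote frequencies (never introducing heterozygotes, reproducible by
seed); (4) LD-prune; (5) build hybrid dosages as the parental mean —
deterministic for fixed lines, so (d1+d2)/2 in {0,1,2}; (6) drop hybrid
markers with MAF < 0.05.  A per-step report conserves marker counts.

The prune targets a **mean adjacent-pair r^2** of the retained panel: a
pairwise-r^2 cut drives a PLINK-style greedy sliding-window prune (the
lower-MAF member of an offending pair is removed; window 50, step 25 by
default), and the cut is found by bisection as the largest value whose
pruned panel meets the target — so pruning is as light as the constraint
allows.  Near-duplicate pairs (r^2 > 0.99) are always resolved.  r^2 is the
squared dosage correlation (composite LD), exact for homozygous parents
where phase is trivial.  "Target mean LD" has no canonical tool equivalent,
so this operationalization is one defensible reading; the achieved mean and
the cut are recorded in the report.

## Kinship matrices and kernels

* `grm_trace_norm` (G_Z / G_W): G = ZZ' n / trace(ZZ') on the raw
  {-1,0,1} coding, uncentered because the defining formula shows no
  centering; a `centered` flag exists for sensitivity checks.
* `grm_additive` (G_A): VanRaden — dosages centered at 2p_j, denominator
  2 sum p_j(1-p_j).
* `grm_dominance` (G_D): heterozygote indicators centered at 2p_j q_j,
  denominator sum 2 p_j q_j (1 - p_j q_j).
* `gaussian_kernel`: K_ij = exp(-h d_ij / median(d)) with
  d_ij = G_ii + G_jj - 2G_ij from an additive GRM; h defaults to 1 with
  median scaling since the exact original recipe is not reproduced here.

Allele frequencies for centering always come from the sample set the matrix
is built on (the hybrids), not the parents.  All builders are checked
against naive double-loop oracles to 1e-10.

## Prediction models

With `g` the vector of adjusted phenotypes:

    MAS        g = mu + M f + e            (f fixed; A, D or stacked AD coding)
    BayesB     g = mu + Z b + e            (spike-and-slab b)
    GBLUP/RKHS g = mu + h + e,             h ~ N(0, s2_g G)
    MAS|GP     g = mu + M f + s + e,       s ~ N(0, s2_s G_W)

M holds the "line-significant" markers, W their complement, and G_W is
built from W only.  Two engines solve the kernel models and cross-validate
each other: an exact path (eigen-profile REML, then BLUP) and a Gibbs
sampler with scaled-inverse-chi-square priors (df 5, scales from the R2
rule with prior R2 = 0.5), mirroring the Bayesian software such analyses
typically use.  The Gibbs sampler works in the eigenbasis of the training
kernel where the genetic-value conditional is diagonal.  Chain defaults are
30,000 iterations / 5,000 burn-in / thinning 5; tests and the bundled desk
profile use 1,200-3,000 / 300-500 / 2, which on these problem sizes gives
Monte-Carlo error well below the replicate-to-replicate spread.  The Gibbs
engine is the default: at the low heritabilities this package targets,
REML frequently estimates s2_g = 0 on a training split (degenerating to a
constant predictor) while the proper priors keep the Bayesian fit usable —
the exact path remains available (`engine="reml"`) and anchors the tests.

BayesB gives each marker an exactly-zero effect with probability pi
(pi ~ Beta, prior counts (5,5)) or a draw from a normal slab whose
per-marker variance has a scaled-inverse-chi-square prior (a scaled-t slab
marginally).  The inner Gibbs loop is numba-compiled; a plain-numpy
reference chain ships alongside and the two are compared statistically in
the tests.  Divergent (non-finite) residual variances raise with the
iteration number.

Test-set genetic values use the joint-model-with-missing-responses
convention: the conditional expectation of the held-out genetic values
given the training records through the kernel (for REML this is
s2_g K_te,tr Sigma_tr^-1 residuals; for Gibbs, K_te,tr K_tr^+ applied to
the posterior-mean training values).  Predictive ability is the Pearson
correlation between observed and predicted values on the held-out 25%,
over 50 (default) seeded random splits; replicate k derives its split from
seed + k so single replicates can be re-run.  Replicates with constant
predictions are recorded as missing and excluded from the mean with a
warning.  A one-sample t-test against zero reproduces the reporting
convention of flagging methods whose mean ability is indistinguishable
from zero.

## GWAS

Single-marker GLS under the polygenic null

    g = X mu + S m + [v + o] + eps,   v ~ N(0, G_A s2_a),  o ~ N(0, G_D s2_d)

with X = intercept + 0-3 dosage principal components (deterministic sign
convention), and S the additive ({-1,0,1}), dominance ({0,1,0}) or stacked
coding.  Variance components are estimated once on the marker-free model
(exact eigen-profile REML for one kinship; AI-REML then one spectral
decomposition for two) and reused for every marker — the standard P3D
choice, which also makes permutations exact replays.  After whitening by
the inverse square root of the fitted covariance, each marker test is
ordinary least squares: effects get marginal 1-df t-tests (in AD scans the
additive and dominance coefficients are tested separately, so a marker can
be significant for either).  Markers whose coding has no variance after
projection are skipped with a recorded reason.  With no kinship and no PCs
the scan reproduces plain OLS p-values to 1e-8 (tested against
statsmodels).

The family-wise threshold permutes the phenotype vector (covariate and
kinship rows stay put), replays the whitened scan for each of n_perm
(default 400) seeded permutations, and takes the ceil(alpha x n_perm)-th
smallest of the per-permutation minimum p-values — the 20th smallest of
400 at alpha = 0.05.  Permuting the phenotype is valid under the global
null; it ignores polygenic structure under the alternative, which is the
usual trade-off.  Calibration is verified empirically in the acceptance
tests (family-wise rate 0.05 +/- 0.02 over 1000 null data sets).  Model
choice across codings/kinships/PC counts picks the scan whose genomic
inflation factor lambda = median(chi^2)/0.4549 is closest to 1, ties going
to fewer PCs — a numerical stand-in for choosing the best-behaved QQ plot.

Significant markers are decomposed via the allele-substitution effect
alpha = a + d(q-p):

    additive scan:       H2 = 2pq alpha^2 / Var(g)
    AD scan, additive:   H2 = 2pq [a + d(q-p)]^2 / Var(g)
    AD scan, dominance:  H2 = 4 p^2 q^2 d^2 / Var(g)

with Var(g) defaulting to the sample variance of the adjusted phenotype.
Reported betas refer to the allele coded +1 (the higher-dosage allele);
MAF is reported for the minor allele.

## Synthetic data

The generator emulates a tropical single-cross program: two heterotic
groups of fully homozygous inbreds (Balding-Nichols divergence, default
Fst 0.2), a partial diallel (intra-group crosses allowed by default, since
906 crosses from 35+15 parents exceed the 525 inter-group pairs), and
augmented-block trials at 2 sites x 2 years x 2 nitrogen regimes with
blocks of 16 entries plus 2 replicated checks.  Linkage disequilibrium is
induced by a Gaussian-copula block model (blocks of 10 markers sharing a
latent factor, correlation 0.7), which preserves each marker's marginal
frequency exactly — enough LD to exercise pruning and tagging, not a
coalescent model.

The trait has additive effects on the {-1,0,1} coding and positive-mean
dominance deviations on the heterozygote indicator, rescaled so the
realized Var_D/Var_A among the hybrids equals `dominance_ratio` (inf = pure
dominance, a = 0) and the total genotypic SD equals `genetic_sd`
(0.55 Mg/ha — chosen once as a realistic genetic CV of ~8% at a 7 Mg/ha
yield level).  LN and IN values share QTL with effects correlated at
`genetic_corr` (default 0.8: strong but imperfect, the index contrast being
the least heritable piece).  Defaults follow the emulated design where it
states values: 35+15 parents, 906 hybrids, 34,571 markers, regime gap
0.87 Mg/ha around a 6.935 Mg/ha grand mean (7.37 vs 6.50), target plot
heritability 0.25, line-trait heritability 0.13.  Environment, block and
check x environment SDs (0.5, 0.55, 0.22 Mg/ha) are realistic field-trial
magnitudes chosen once.  Parent per-se values express additive QTL
contributions only — homozygous lines never show dominance — plus noise at
the line heritability.

What passing tests on these data do and do not show: the generator has no
genotype-by-environment interaction beyond check x environment, no spatial
field trends, no selection or pedigree depth, and LD without recombination
history.  Recovery of variance components, calibration of permutation
thresholds and the qualitative ordering of prediction methods therefore
validate the estimators under the stated model, not their behaviour under
every field reality.

## Problem sizes in the shipped tests

The test suite and acceptance checks run the full pipeline at reduced
scale, chosen as the smallest sizes at which the estimators are
well-conditioned: 100-350 hybrids, 400-2,000 markers, 100-400
permutations, Gibbs chains of 1,200-8,000 iterations, 8-10 CV replicates,
20 seeds for the stochastic ordering checks.  The `paper` pipeline profile
retains the full-scale settings (906 hybrids, 34,571 markers, 50
replicates, 30,000 iterations, 400 permutations).

## Known limitations

* The prediction kernels are additive-coded; dominance enters prediction
  only through MAS codings and the Gaussian kernel's nonlinearity (matching
  the analysis this package reproduces, not best practice for hybrids).
* AI-REML is dense O(n^3) per iteration; plot tables beyond ~5,000 rows
  get slow.
* The two-kinship GWAS null assumes the fitted covariance is correct for
  all markers (P3D); an exact per-marker path exists only for the
  single-kinship case via refitting.
* Stochastic imputation is marginal per marker; no haplotype information
  is used.
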