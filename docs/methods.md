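# Methods

## The model

`memgrowth` estimates an *intrinsic* per-cell-line phenotype from replicated
measurements that are confounded by experimental batch.  A measurement of
line *i* under experimental condition *j* (replicate *k*) is modeled as

    y_ijk = x_i' beta + u_i + v_j + e_ijk

where `x_i` holds treatment-coded line-level covariates (gender and
population by default), `u_i ~ N(0, sigma2_line)` is the line's intrinsic
deviation, `v_j ~ N(0, sigma2_cond)` is the condition (batch/"technician")
effect, and `e_ijk ~ N(0, sigma2_resid)` is residual noise.  Lines and
conditions are **crossed**, not nested: any line may appear in any
condition, with arbitrary and unbalanced coverage.  The response is used
untransformed; growth readouts on the assay scale are close to Gaussian,
and an optional log2 flag exists at the I/O layer for data where
multiplicative noise dominates.

The intrinsic phenotype of line *i* is defined as

    igrowth_i = intercept + beta_gender(i) + beta_population(i) + BLUP_i

i.e. the best linear unbiased prediction of `u_i` plus the estimated
fixed-effect contributions, *including the intercept*, so values stay on
the measurement scale (a cohort with grand mean ~7.5e4 yields intrinsic
values near 7.5e4).  Because the BLUP is a shrinkage estimator, the
across-line variance of `igrowth` is never larger than the variance of raw
per-line means — pooling replicated, batch-confounded data buys a strictly
less noisy phenotype.

## Estimation

Variance components are estimated by REML (ML on request; likelihood-ratio
tests always refit both models with ML).  The criterion is profiled: for
variance ratios `gamma_f = sigma2_f / sigma2_resid` the fixed effects and
the residual variance have closed-form optima, leaving a 2-parameter (in
the default spec) optimization over `log gamma`.  Each evaluation solves
Henderson's mixed-model equations

    C = [[X'X, X'Z], [Z'X, Z'Z + diag(1/gamma)]]

by Cholesky factorization; the same factor yields the GLS `beta`, the
BLUPs, the penalized residual sum of squares (equal to the GLS quadratic
form), and the log-determinants entering the restricted likelihood.  With
q total random-effect levels the cost per evaluation is O((p+q)^3), about
0.5 s per fit at the default study size (500 lines x 10 conditions,
~3,500 observations), independent of n beyond the one-time cross-products.

Numerical choices:

- optimization over `log gamma` in [-15, 15] (ratios ~3e-7..3e6), L-BFGS-B
  with numerical gradients followed by a Nelder-Mead polish
  (`fatol = 1e-10`); boundary estimates (a component indistinguishable
  from zero) are legitimate outcomes, reported as ~0 variance;
- starting values from an ANOVA-flavoured moment estimate (between-group
  share of the OLS residual variance), clipped to [1e-3, 1e3];
- treatment coding with the lexicographically first level as reference;
  intrinsic-value *differences* between lines are invariant to this
  choice;
- rank-deficient fixed designs are rejected with the aliased columns
  named (pivoted QR); a degenerate zero-residual fit collapses cleanly
  (sigma2_resid -> 0, BLUPs -> unshrunk deviations);
- fits are deterministic; shift-invariance (adding a constant moves only
  the intercept) holds to ~1e-4 relative on the variance components,
  limited by the optimizer's criterion tolerance.

The fitter was validated against R's lme4 on simulated crossed designs
(variance components, coefficients, BLUPs, and REML log-likelihood agree
to ~1e-6 relative); the test suite retains that comparison as an
independent oracle along with a dense-marginal-covariance grid search.

Lines observed only once are retained — their BLUP is strongly shrunk —
and listed in a warning.  Family/trio structure is ignored.

## Expression association

Per-gene OLS of log2 expression on `[1, igrowth, population, gender,
(surrogate variables)]`, vectorized across genes; p-values from the
two-sided t distribution on the `igrowth` coefficient.  Zero-variance
genes get p = 1 with a `constant` flag rather than being dropped, keeping
the number of tests stable for FDR.  False discovery rates are Storey
q-values with a single fixed lambda = 0.5:

    pi0 = min(1, #{p > 0.5} / (0.5 m));  q(p_(i)) = min_{j>=i} pi0 m p_(j)/j

which reduces to Benjamini-Hochberg when pi0 caps at 1.

Expression heterogeneity is adjusted with a deliberately simple two-step
surrogate-variable estimator: residualize expression against the full
primary model, decompose the residuals by singular values, and keep
components while the observed variance share exceeds the 95th percentile
of shares from row-wise permutations of the residuals (each permutation is
re-residualized so the null spectrum lives in the same rank-reduced
subspace; the ceil-rank quantile makes the keep decision err toward
k = 0).  This is not the full iteratively reweighted SVA algorithm; it
recovers planted orthogonal batch factors with |r| > 0.9 and selects k = 0
on pure noise ~95% of the time, which is all the downstream analyses
require of it.

The permutation-null generator shuffles the phenotype across samples
(covariates stay attached to their samples) and tests randomly sampled
genes, yielding the reference cloud for QQ plots.  The power comparison
(`compare_power`) runs the identical association once per phenotype source
— the intrinsic value and each single condition's raw per-line value — and
returns aligned p columns plus sorted -log10 p curves.  The headline
comparison is heterogeneity-adjusted: without it, chance correlation
between a single condition's phenotype and the latent expression factors
adds a seed-dependent offset to the whole null bulk of the QQ curve.

## SNP scan and enrichment

The scan is OLS of `igrowth` on additive dosage plus covariates, computed
via Frisch-Waugh residualization so 5,000 SNPs test in a few matrix
products.  Missing dosages are mean-imputed per SNP inside the scan only;
SNPs with MAF below the floor (default 0.05) or zero variance are skipped
and logged.  Under a permuted phenotype the scan's type-I rate is 5% and
genomic-control lambda is ~1.

Three enrichment procedures ask whether eQTL targets of top
growth-associated SNPs are enriched for growth-associated genes:

1. **Fisher/hypergeometric** — exact one-sided tail on the overlap; assumes
   genes are independent draws from the universe.
2. **Phenotype permutation, fixed growth set** — rerun scan -> top SNPs ->
   eQTL targets per permutation against the observed growth-gene set;
   empirical p = proportion of permutation Fisher p-values <= observed.
   Respects correlation among target genes and the composition of the eQTL
   map.
3. **Shared permutation** — as method 2, but the growth-gene set is
   recomputed from the *same* permuted phenotype (unadjusted association,
   q < threshold), so the reuse of the same individuals in both the SNP
   and the expression association is reflected in the null.

Conventions: ties (permutation p exactly equal to observed) count as
at-least-as-extreme; the raw proportion is the headline empirical p (it
can be exactly 0) with the `(r+1)/(n+1)` correction reported alongside; a
permutation with an empty target set records Fisher p = 1; target genes
outside the association universe are dropped with a logged count; the
target set is a plain union over top SNPs (no per-SNP weighting).

A structural property worth knowing: under a permuted phenotype a
q-thresholded gene set is *empty* with probability roughly `1 - alpha`
(FDR control at work), so method 3's permutation trace has a large atom at
Fisher p = 1 and its empirical p is far from uniformly distributed under a
global null.  The test is still valid — exchangeability guarantees
P(empirical p <= a) <= a — but conservative and discrete.  Method 2, whose
growth set is fixed and large, produces an essentially continuous,
uniform empirical p under the null.  Both behaviors are pinned down in the
test suite, and the confounded scenario (below) shows the flip side:
when the same individuals drive both associations, the naive Fisher test
and method 2 become strongly anti-conservative while method 3 retains
type-I control.

`signature_overlap` draws random gene sets of a signature's size from the
universe (uniform, without replacement) and reports the proportion of
draws containing at least as many growth genes as the signature; it agrees
with the exact hypergeometric tail to Monte-Carlo accuracy.

## The synthetic-data generator

The generator emulates a replicated LCL growth study and is the package's
test bed; every dataset carries its full ground truth.  Defaults
(`scenario("paper_like")`) describe the study conditions: 500 lines drawn
from four populations (1/3 CEU, 1/3 YRI, 1/6 ASN, 1/6 ASW) with equal
gender frequencies; grand mean 7.5e4 assay units; fractional population
offsets (+5.7% ASW, +2.6% YRI, +2.0% ASN, -4.4% CEU) and a -7% female
effect; sigma_line = 12,000, sigma_cond = 8,000, sigma_resid = 16,000
(raw per-measurement variance ~2.2x the intrinsic variance, so single
experiments are visibly noisier than the pooled estimate); 10 conditions
with independent 0.7 Bernoulli coverage per line x condition (every line
keeps at least one observation); 10,748 genes of which 27.6% depend
linearly on the standardized true intrinsic value with N(0.2, 0.3^2)
log2-units-per-SD effects (~75% positive), plus 10 latent heterogeneity
factors (loading sd 0.3) and unit-variance noise; 5,000 Hardy-Weinberg
SNPs with MAF ~ U(0.05, 0.5); 300 eQTLs at 0.8 log2 units per allele,
half targeting growth genes.

Presets for specific study questions:

- `null` — no fixed, growth-gene, or genetic effects; real eQTLs in the
  expression (harmless under the null) so permutation pipelines are
  non-degenerate; used for calibration checks.
- `planted_growth` — 200 lines, 6 conditions, sigma_resid = 30,000 (the
  heavy-replicate-noise regime where pooling pays most), 30% growth genes
  with stronger effects, and 6 eQTL SNPs whose dosages add 12,000 assay
  units/allele to the intrinsic value — a true SNP -> expression ->
  growth chain detectable by the enrichment procedures.
- `confounded` — an ancestry-like confounder modulates allele frequencies
  (+/-30% per SD) and loads on expression (sd 0.4) but has *zero* effect
  on the phenotype; all 300 SNPs are strong eQTLs.  The
  no-genetic-effect null holds exactly, yet the naive Fisher test is
  wildly anti-conservative because top SNPs' chance correlation with the
  phenotype leaks into their targets' expression — the scenario method 3
  exists for.

Determinism: one `numpy.random.default_rng(seed)` stream with a fixed draw
order (line labels, line effects, confounder, condition effects, MAFs,
dosages, gene effects, eQTL assignment, phenotype noise, expression
terms), so a seed reproduces every table byte-for-byte.

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: linkage disequilibrium (an optional concern
the permutation procedures sidestep by preserving whatever correlation the
input genotypes carry), non-Gaussian assay noise, batch effects that
interact with line identity (the model's additivity assumption is true in
simulation by construction), array-level expression preprocessing,
relatedness/trio structure, and EBV copy-number biology.

## Problem sizes and thresholds in the tests

The paper-scale analyses (500 lines, 10,748 genes, 5,000 SNPs) run in
seconds, so the acceptance checks use them directly where a single fit
suffices.  Repeated-fit studies use the generator's smaller presets
(180-200 lines, 1,000-2,000 genes, 300-500 SNPs) with 50-100 seeds and
99-200 permutations per run — sizes chosen so each study completes in a
few minutes while Monte-Carlo error stays well inside the asserted
margins.  The top-SNP p threshold and growth-gene FDR threshold are
mandatory, logged parameters (defaults 1e-4 and 0.05); tests use looser
values (1e-3 to 0.2) scaled to the smaller simulated cohorts.

## Known limitations

- One grouping column per random effect; composite experimental-condition
  factors must be pre-combined into a single label.
- Gaussian responses only (no GLMM extension).
- The SVA step is the simplified two-step estimator described above.
- Population-structure control in the scan is covariate-based only.
- Method 3's empirical p is conservative and discrete under sparse
  growth-gene sets (see above); interpret it as a validity-preserving
  bound, not a uniform p-value.
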